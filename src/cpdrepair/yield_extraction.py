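"""Quantum-yield and photostationary-level extraction from dose-response data.

At low absorbed doses the recovery of the 266 nm absorption band is linear in
the absorbed energy, and the slope is proportional to the self-repair quantum
yield:

    Phi = slope[OD/J] * V * N_A * E_ph_mean / (delta_eps_266 * l)

i.e. (molecules repaired per joule) divided by (photons absorbed per joule).
At high doses the response saturates as the photostationary state (PSS) is
approached; the plateau level and the dose needed to reach it are estimated
by fitting a saturating exponential f(D) = f_pss * (1 - exp(-D / D0)).

Reported quantum yields carry an absolute uncertainty of 40% of the value,
the empirical error estimate for this irradiation/HPLC setup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .constants import AVOGADRO_PER_MOL
from .photokinetics import TimeCourse
from .spectra import AbsorptionPartition, SampleCell

#: Relative uncertainty applied to every reported quantum yield.
RELATIVE_UNCERTAINTY = 0.40

#: "Equilibrium reached" convention: first dose within 5% (relative) of the
#: plateau, i.e. D_eq = -D0 * ln(0.05).
EQUILIBRIUM_REL_TOL = 0.05


@dataclass(frozen=True)
class DoseResponse:
    """Probe-absorbance change vs cumulative absorbed energy dose."""

    doses_J: np.ndarray
    delta_A_266: np.ndarray
    probe_nm: float = 266.0

    def __post_init__(self):
        d = np.asarray(self.doses_J, dtype=float)
        a = np.asarray(self.delta_A_266, dtype=float)
        object.__setattr__(self, "doses_J", d)
        object.__setattr__(self, "delta_A_266", a)
        if d.size != a.size:
            raise ValueError("doses and absorbance changes must have equal length")
        if d.size and d[0] != 0:
            raise ValueError("dose axis must start at 0")
        if np.any(np.diff(d) < 0):
            raise ValueError("doses must be non-decreasing")

    @property
    def n(self) -> int:
        return self.doses_J.size


@dataclass(frozen=True)
class LinearRange:
    """Index span [start, stop) of the initial linear regime."""

    start: int
    stop: int
    fallback: bool = False
    plateau_estimate_OD: float | None = None

    def __len__(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True)
class QuantumYieldEstimate:
    phi: float
    slope_OD_per_J: float
    linear_range: LinearRange
    fit_intercept: float
    fit_r_squared: float
    flags: tuple[str, ...] = ()

    @property
    def phi_percent(self) -> float:
        return self.phi * 100.0

    @property
    def abs_uncertainty_percent(self) -> float:
        return RELATIVE_UNCERTAINTY * self.phi_percent


@dataclass(frozen=True)
class PssEstimate:
    plateau_fraction: float
    characteristic_dose_J: float
    dose_to_equilibrium_J: float

    def __post_init__(self):
        if not 0.0 <= self.plateau_fraction <= 1.0:
            raise ValueError("plateau fraction must lie in [0, 1]")


def _saturating_exp(D, f_pss, D0):
    return f_pss * (1.0 - np.exp(-D / D0))


def _try_plateau_estimate(doses: np.ndarray, y: np.ndarray) -> float | None:
    """Plateau of a saturating-exponential fit, or None when unidentifiable."""
    ymax = float(np.max(np.abs(y)))
    if ymax <= 0 or doses[-1] <= 0:
        return None
    sign = 1.0 if y[np.argmax(np.abs(y))] >= 0 else -1.0
    try:
        popt, _ = curve_fit(
            _saturating_exp,
            doses,
            sign * y,
            p0=[ymax, max(doses[-1] / 3.0, 1e-12)],
            maxfev=5000,
        )
    except RuntimeError:
        return None
    f_pss, D0 = popt
    # unidentifiable when the data never bend (D0 beyond the data) or the
    # fit is degenerate
    if not np.isfinite(f_pss) or not np.isfinite(D0) or D0 <= 0 or f_pss <= 0:
        return None
    if D0 > 5.0 * doses[-1]:
        return None
    return float(f_pss)


def select_linear_range(dr: DoseResponse, alpha: float = 0.05) -> LinearRange:
    """Longest initial prefix statistically consistent with a straight line.

    A prefix qualifies when the curvature term of a quadratic fit is not
    significantly different from zero (t-test at ``alpha``).  Points beyond
    25% of the estimated plateau are excluded outright; when no prefix of at
    least 4 points qualifies, the first 4 points are used and the result is
    flagged as a fallback.
    """
    if dr.n < 4:
        raise ValueError("linear-range selection needs at least 4 points")
    D, y = dr.doses_J, dr.delta_A_266
    plateau = _try_plateau_estimate(D, y)
    k_max = dr.n
    if plateau is not None:
        within = np.abs(y) <= 0.25 * plateau + 1e-15
        # longest prefix satisfying the cap
        bad = np.nonzero(~within)[0]
        if bad.size:
            k_max = max(int(bad[0]), 0)
    scale = max(float(np.max(np.abs(y))), 1e-12)
    for k in range(min(k_max, dr.n), 3, -1):
        X = np.column_stack([np.ones(k), D[:k], D[:k] ** 2])
        beta, res, rank, _ = np.linalg.lstsq(X, y[:k], rcond=None)
        dof = k - 3
        if dof <= 0:
            continue
        rss = float(res[0]) if res.size else float(np.sum((y[:k] - X @ beta) ** 2))
        if rss < (1e-10 * scale) ** 2 * k:
            # numerically perfect quadratic fit: exactly linear data fall
            # here too (curvature coefficient ~ 0)
            if abs(beta[2]) * D[k - 1] ** 2 < 1e-8 * scale:
                return LinearRange(0, k, plateau_estimate_OD=plateau)
            continue
        sigma2 = rss / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        t_stat = beta[2] / np.sqrt(cov[2, 2])
        p = 2.0 * stats.t.sf(abs(t_stat), dof)
        if p > alpha:
            return LinearRange(0, k, plateau_estimate_OD=plateau)
    return LinearRange(0, 4, fallback=True, plateau_estimate_OD=plateau)


def mean_absorbed_photon_energy_J(partition: AbsorptionPartition) -> float:
    """Mean energy per absorbed photon, energy rate over photon rate."""
    rate = partition.total_absorbed_photon_rate
    if rate <= 0:
        raise ValueError("no absorption: mean photon energy undefined")
    return partition.energy_dose_rate_W / rate


def _saturation_correction(
    D_sel: np.ndarray, dr: DoseResponse
) -> tuple[float, bool]:
    """Multiplicative factor restoring the true initial slope from an OLS
    slope over doses that already bend towards the plateau.

    A saturating exponential is fitted to the full dose response; the factor
    is the ratio of the model's initial slope to the OLS slope the model
    would produce over the selected points.  When the data never bend the
    fit is unidentifiable and the factor is 1 (no correction).
    """
    D_all, y_all = dr.doses_J, dr.delta_A_266
    ymax = float(np.max(np.abs(y_all)))
    if ymax <= 0 or D_all[-1] <= 0:
        return 1.0, False
    sign = 1.0 if y_all[np.argmax(np.abs(y_all))] >= 0 else -1.0
    try:
        popt, _ = curve_fit(
            _saturating_exp,
            D_all,
            sign * y_all,
            p0=[ymax, max(D_all[-1] / 3.0, 1e-12)],
            maxfev=5000,
        )
    except RuntimeError:
        return 1.0, False
    A_pss, D0 = float(popt[0]), float(popt[1])
    if not (np.isfinite(A_pss) and np.isfinite(D0)) or A_pss <= 0 or D0 <= 0:
        return 1.0, False
    if D0 > 5.0 * D_all[-1]:
        return 1.0, False
    Dbar = D_sel.mean()
    denom = float(np.sum((D_sel - Dbar) ** 2))
    if denom <= 0:
        return 1.0, False
    w = (D_sel - Dbar) / denom
    slope_model = float(np.sum(w * _saturating_exp(D_sel, A_pss, D0)))
    slope0_model = A_pss / D0
    if slope_model <= 0:
        return 1.0, False
    factor = slope0_model / slope_model
    if not 1.0 <= factor <= 3.0:
        # wilder ratios mean the selected range is not an initial regime at
        # all; fall back to the raw slope rather than extrapolate
        return 1.0, False
    return factor, factor > 1.0 + 1e-9


def quantum_yield_from_dose_response(
    dr: DoseResponse,
    delta_eps_266: float,
    cell: SampleCell,
    mean_photon_energy_J: float,
    linear_range: LinearRange | None = None,
    saturation_correction: bool = True,
) -> QuantumYieldEstimate:
    """Quantum yield from the initial slope of delta-A(266 nm) vs dose.

    ``delta_eps_266`` is the molar absorption gain (repaired minus damaged)
    at the probe, M^-1 cm^-1.  The slope comes from ordinary least squares
    with a free intercept over the selected linear range; when the data
    visibly approach the photostationary plateau the measured slope is
    rescaled to the initial (zero-dose) slope of a fitted saturating
    exponential, removing the saturation bias a straight line would carry.
    """
    if delta_eps_266 <= 0:
        raise ValueError("delta_eps_266 must be positive")
    if mean_photon_energy_J <= 0:
        raise ValueError("mean photon energy must be positive")
    if linear_range is None:
        linear_range = select_linear_range(dr)
    sl = slice(linear_range.start, linear_range.stop)
    D, y = dr.doses_J[sl], dr.delta_A_266[sl]
    res = stats.linregress(D, y)
    slope, intercept = float(res.slope), float(res.intercept)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
    flags = ("linear_range_fallback",) if linear_range.fallback else ()
    if saturation_correction and slope > 0:
        factor, applied = _saturation_correction(D, dr)
        if applied:
            slope *= factor
            flags = flags + ("saturation_corrected",)
    if slope < 0:
        return QuantumYieldEstimate(
            phi=0.0,
            slope_OD_per_J=slope,
            linear_range=linear_range,
            fit_intercept=intercept,
            fit_r_squared=r2,
            flags=flags + ("net damage regime",),
        )
    phi = (
        slope
        * cell.volume_L
        * AVOGADRO_PER_MOL
        * mean_photon_energy_J
        / (delta_eps_266 * cell.path_length_cm)
    )
    if phi > 1.0:
        flags = flags + ("phi_exceeds_unity",)
        phi = min(phi, 1.0)
    return QuantumYieldEstimate(
        phi=phi,
        slope_OD_per_J=slope,
        linear_range=linear_range,
        fit_intercept=intercept,
        fit_r_squared=r2,
        flags=flags,
    )


def fit_pss_approach(
    timecourse_or_doses: TimeCourse | np.ndarray,
    fraction: np.ndarray | None = None,
) -> PssEstimate:
    """Fit f(D) = f_pss (1 - exp(-D/D0)) to a long-dose repair trajectory.

    Accepts a :class:`TimeCourse` (uses its dose and repair-fraction arrays)
    or explicit ``(doses_J, fraction)`` arrays.  Raises when the data do not
    span at least 80% of the fitted plateau.
    """
    if isinstance(timecourse_or_doses, TimeCourse):
        D = np.asarray(timecourse_or_doses.cumulative_dose_J, float)
        f = np.asarray(timecourse_or_doses.repair_fraction, float)
    else:
        if fraction is None:
            raise ValueError("need fraction values alongside the dose array")
        D = np.asarray(timecourse_or_doses, float)
        f = np.asarray(fraction, float)
    if D.size < 4:
        raise ValueError("plateau fit needs at least 4 points")
    fmax = float(np.max(f))
    if fmax <= 0:
        raise ValueError("plateau not reached in data")
    popt, _ = curve_fit(
        _saturating_exp, D, f, p0=[fmax, max(D[-1] / 3.0, 1e-12)], maxfev=10000
    )
    f_pss, D0 = float(popt[0]), float(popt[1])
    if not (np.isfinite(f_pss) and np.isfinite(D0)) or D0 <= 0:
        raise ValueError("plateau not reached in data")
    if fmax < 0.8 * f_pss:
        raise ValueError("plateau not reached in data")
    # mOD-scale noise can push a fitted plateau marginally outside [0, 1]
    f_pss = float(np.clip(f_pss, 0.0, 1.0))
    return PssEstimate(
        plateau_fraction=f_pss,
        characteristic_dose_J=D0,
        dose_to_equilibrium_J=-D0 * np.log(EQUILIBRIUM_REL_TOL),
    )


def rounded_uncertainty_percent(phi_percent: float, ndigits: int = 2) -> float:
    """The 40% uncertainty rule with conventional decimal rounding."""
    return round(RELATIVE_UNCERTAINTY * phi_percent, ndigits)
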
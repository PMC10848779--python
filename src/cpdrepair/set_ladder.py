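"""Sequential-electron-transfer (SET) energy ladders.

Typed, validated energy diagrams for the excited-state cascade that drives
CPD self-repair in damaged purine-containing tetranucleotides: photoexcited
guanine (G*) hands an electron to adenine (A-/G+ charge-transfer minimum),
which hands it on to the thymine dimer (TT-/AG+), from where an S1/S0
minimum-energy crossing point (MECP) splits the cyclobutane ring.  Competing
direct photorelaxation channels are MECPs reachable from the intermediate
minima; a channel is classified accessible when its barrier is at or below a
threshold (default 0.1 eV).

Energies are in eV.  Ladders referenced to the ground-state minimum store
absolute excitation energies; ladders for which only relative gaps are
published are referenced to their own G* S1 minimum (G* = 0, points below it
negative).  Every stationary point carries a provenance tag: values printed
verbatim, values derived by chaining printed gaps, and upper bounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .constants import EV_NM

GROUND_REFERENCE = "ground-state minimum"
GSTAR_REFERENCE = "S1 G* minimum"

POINT_NAMES = ("FC", "G*", "A-G+", "TT-AG+", "MECP_G", "MECP_AG", "MECP_CPD")
POINT_KINDS = ("minimum", "MECP")
PROVENANCE_TAGS = ("printed", "derived-from-text", "upper-bound-from-text")

#: Packaged dataset keys -> resource file names.
PACKAGED_LADDERS = {
    "ttag_ag_anti": "ttag_ag_anti.json",
    "gatt_ga_syn": "gatt_ga_syn.json",
    "gatt_ga_anti": "gatt_ga_anti.json",
}

_WAVELENGTH_TOL_NM = 0.5


def energy_wavelength_convert(value: float) -> float:
    """eV <-> nm conversion, lambda = 1239.84198 / E (involutive)."""
    if not value > 0:
        raise ValueError("energy/wavelength must be positive")
    return EV_NM / value


@dataclass(frozen=True)
class ElectronicState:
    """A vertical excitation at the Franck-Condon geometry."""

    label: str
    character: str  # LE | CT
    transition_note: str
    energy_eV: float
    oscillator_strength: float | None = None
    wavelength_nm: float | None = None

    def __post_init__(self):
        if self.character not in ("LE", "CT"):
            raise ValueError("state character must be LE or CT")
        if not self.energy_eV > 0:
            raise ValueError("excitation energy must be positive")
        if self.oscillator_strength is not None and self.oscillator_strength < 0:
            raise ValueError("oscillator strength must be nonnegative")
        if self.wavelength_nm is None:
            object.__setattr__(self, "wavelength_nm", energy_wavelength_convert(self.energy_eV))

    @property
    def wavelength_consistent(self) -> bool:
        return abs(self.wavelength_nm - EV_NM / self.energy_eV) <= _WAVELENGTH_TOL_NM


@dataclass(frozen=True)
class StationaryPoint:
    """An S1 minimum or S1/S0 MECP, energy relative to the ladder reference."""

    name: str
    kind: str
    energy_eV: float
    provenance: str = "printed"
    geometry_notes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in POINT_NAMES:
            raise ValueError(f"point name must be one of {POINT_NAMES}")
        if self.kind not in POINT_KINDS:
            raise ValueError(f"point kind must be one of {POINT_KINDS}")
        if self.provenance not in PROVENANCE_TAGS:
            raise ValueError(f"provenance must be one of {PROVENANCE_TAGS}")


@dataclass(frozen=True)
class SetLadder:
    system_label: str
    states: tuple[ElectronicState, ...]
    points: tuple[StationaryPoint, ...]
    bright_state_energy_eV: float | None = None
    reference: str = GROUND_REFERENCE
    floating_gaps: tuple[dict, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "points", tuple(self.points))
        object.__setattr__(self, "floating_gaps", tuple(self.floating_gaps))
        names = [p.name for p in self.points]
        if len(names) != len(set(names)):
            raise ValueError("duplicate stationary-point names")
        n_fc = names.count("FC")
        if self.reference == GROUND_REFERENCE and n_fc != 1:
            raise ValueError("a ground-state-referenced ladder needs exactly one FC entry")
        if n_fc > 1:
            raise ValueError("at most one FC entry")

    def point(self, name: str) -> StationaryPoint:
        for p in self.points:
            if p.name == name:
                return p
        raise KeyError(
            f"unknown point {name!r}; available: {[p.name for p in self.points]}"
        )

    def has_point(self, name: str) -> bool:
        return any(p.name == name for p in self.points)


def gap(ladder: SetLadder, from_point: str, to_point: str) -> float:
    """Signed energy gap (to - from) in eV between two stationary points."""
    return ladder.point(to_point).energy_eV - ladder.point(from_point).energy_eV


def classify_channel(
    ladder: SetLadder, from_min: str, to_mecp: str, threshold_eV: float = 0.1
) -> str:
    """'accessible' when the barrier from a minimum to an MECP is <= threshold."""
    a = ladder.point(from_min)
    b = ladder.point(to_mecp)
    if a.kind != "minimum":
        raise ValueError(f"{from_min!r} is a {a.kind}, not a minimum")
    if b.kind != "MECP":
        raise ValueError(f"{to_mecp!r} is a {b.kind}, not an MECP")
    return "accessible" if gap(ladder, from_min, to_mecp) <= threshold_eV else "hindered"


@dataclass(frozen=True)
class ValidationCheck:
    name: str
    passed: bool
    detail: str


def validate_ladder(ladder: SetLadder) -> list[ValidationCheck]:
    """Consistency checks; failures are report entries, never exceptions."""
    checks: list[ValidationCheck] = []
    if not ladder.points:
        checks.append(ValidationCheck("has_points", False, "empty points list"))
        return checks
    checks.append(ValidationCheck("has_points", True, f"{len(ladder.points)} points"))

    for st in ladder.states:
        ok = st.wavelength_consistent
        checks.append(
            ValidationCheck(
                f"wavelength_consistency:{st.label}",
                ok,
                f"{st.energy_eV} eV vs {st.wavelength_nm} nm "
                f"(|delta| <= {_WAVELENGTH_TOL_NM} nm required)",
            )
        )

    if ladder.reference == GROUND_REFERENCE:
        for p in ladder.points:
            checks.append(
                ValidationCheck(
                    f"positive_energy:{p.name}",
                    p.energy_eV > 0,
                    f"{p.energy_eV} eV above the ground-state minimum",
                )
            )

    if (
        ladder.bright_state_energy_eV is not None
        and ladder.reference == GROUND_REFERENCE
        and ladder.has_point("MECP_AG")
    ):
        e = ladder.point("MECP_AG").energy_eV
        checks.append(
            ValidationCheck(
                "mecp_ag_above_bright_state",
                e > ladder.bright_state_energy_eV,
                f"MECP_AG at {e:.2f} eV vs bright state {ladder.bright_state_energy_eV:.2f} eV",
            )
        )

    cascade = [n for n in ("G*", "A-G+", "TT-AG+") if ladder.has_point(n)]
    if len(cascade) >= 2:
        energies = [ladder.point(n).energy_eV for n in cascade]
        ok = all(energies[i] >= energies[i + 1] for i in range(len(energies) - 1))
        checks.append(
            ValidationCheck(
                "monotone_set_cascade",
                ok,
                " >= ".join(f"{n}:{e:.2f}" for n, e in zip(cascade, energies)),
            )
        )
    return checks


# ------------------------------------------------------------------- I/O


def ladder_from_dict(data: dict) -> SetLadder:
    states = tuple(ElectronicState(**s) for s in data.get("states", []))
    points = tuple(StationaryPoint(**p) for p in data.get("points", []))
    return SetLadder(
        system_label=data["system_label"],
        states=states,
        points=points,
        bright_state_energy_eV=data.get("bright_state_energy_eV"),
        reference=data.get("reference", GROUND_REFERENCE),
        floating_gaps=tuple(data.get("floating_gaps", [])),
    )


def load_ladder(path: str | Path) -> SetLadder:
    with open(path) as fh:
        return ladder_from_dict(json.load(fh))


def load_packaged_ladder(key: str) -> SetLadder:
    """Load one of the packaged datasets: ttag_ag_anti, gatt_ga_syn, gatt_ga_anti."""
    if key not in PACKAGED_LADDERS:
        raise KeyError(f"unknown ladder {key!r}; available: {sorted(PACKAGED_LADDERS)}")
    ref = resources.files("cpdrepair.data").joinpath(PACKAGED_LADDERS[key])
    return ladder_from_dict(json.loads(ref.read_text()))
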
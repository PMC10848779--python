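"""Glycosidic torsion, syn/anti classification and base-stacking overlap.

These operators quantify the conformational features that control interbase
electron transfer in stacked DNA: the glycosidic torsion chi (base
orientation relative to the sugar), its syn/anti class, and the geometric
overlap of adjacent base ring systems projected onto a common plane (a proxy
for electronic coupling between stacked bases).

Torsion convention: chi = O4'-C1'-N9-C4 for purines, O4'-C1'-N1-C2 for
pyrimidines, signed dihedral in (-180, 180].  Classification: syn for chi in
(-90, +90], anti otherwise.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon

PURINES = ("A", "G")
PYRIMIDINES = ("C", "T")

#: Ordered heavy-atom cycles defining the base ring polygons.
RING_ATOMS = {
    "six": {
        "A": ("N1", "C2", "N3", "C4", "C5", "C6"),
        "G": ("N1", "C2", "N3", "C4", "C5", "C6"),
        "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
        "T": ("N1", "C2", "N3", "C4", "C5", "C6"),
    },
    "five": {
        "A": ("C4", "C5", "N7", "C8", "N9"),
        "G": ("C4", "C5", "N7", "C8", "N9"),
    },
}

CHI_ATOMS = {
    "A": ("O4'", "C1'", "N9", "C4"),
    "G": ("O4'", "C1'", "N9", "C4"),
    "C": ("O4'", "C1'", "N1", "C2"),
    "T": ("O4'", "C1'", "N1", "C2"),
}


@dataclass(frozen=True)
class NucleotideStructure:
    """One nucleotide: base type plus named heavy-atom coordinates (Angstrom)."""

    residue_id: int
    base_type: str
    atoms: dict[str, np.ndarray]

    def __post_init__(self):
        if self.base_type not in CHI_ATOMS:
            raise ValueError(f"unknown base type {self.base_type!r}")
        object.__setattr__(
            self,
            "atoms",
            {k: np.asarray(v, dtype=float) for k, v in self.atoms.items()},
        )

    def coords(self, names) -> np.ndarray:
        missing = [n for n in names if n not in self.atoms]
        if missing:
            raise KeyError(
                f"residue {self.residue_id} ({self.base_type}) missing atoms: "
                + ", ".join(missing)
            )
        return np.array([self.atoms[n] for n in names])

    def ring_names(self) -> list[tuple[str, tuple[str, ...]]]:
        rings = [("six", RING_ATOMS["six"][self.base_type])]
        if self.base_type in PURINES:
            rings.append(("five", RING_ATOMS["five"][self.base_type]))
        return rings


@dataclass(frozen=True)
class StackMetrics:
    """Per-pair stacking summary: torsions, classes, overlap and rise."""

    chi1_deg: float
    orientation1: str
    chi2_deg: float
    orientation2: str
    overlap_area_A2: float
    rise_A: float


@dataclass(frozen=True)
class ConformerCensus:
    counts: dict[tuple[str, str], int]
    fractions: dict[tuple[str, str], float]
    n_frames: int
    n_skipped: int


def dihedral_deg(p0, p1, p2, p3) -> float:
    """Signed dihedral angle of four points, degrees in (-180, 180]."""
    b1 = np.asarray(p1, float) - np.asarray(p0, float)
    b2 = np.asarray(p2, float) - np.asarray(p1, float)
    b3 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2n))
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def chi_torsion(nuc: NucleotideStructure) -> float:
    """Glycosidic torsion chi in degrees, (-180, 180]."""
    pts = nuc.coords(CHI_ATOMS[nuc.base_type])
    return dihedral_deg(*pts)


def classify_glycosidic(chi_deg: float) -> str:
    """syn for chi in (-90, +90], anti otherwise (total partition)."""
    if not -180.0 <= chi_deg <= 180.0:
        raise ValueError("chi must lie in [-180, 180] degrees")
    return "syn" if -90.0 < chi_deg <= 90.0 else "anti"


def _ring_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane: (centroid, orthonormal basis [e1, e2, normal])."""
    centroid = points.mean(axis=0)
    _, s, vt = np.linalg.svd(points - centroid)
    if s[1] < 1e-8:
        raise ValueError("degenerate (collinear) ring atoms")
    return centroid, vt


def _base_polygon_2d(nuc: NucleotideStructure, centroid: np.ndarray, basis: np.ndarray) -> Polygon:
    """Project a base's ring cycle(s) onto a plane; union for fused rings."""
    poly = None
    for _, names in nuc.ring_names():
        pts = nuc.coords(names)
        uv = (pts - centroid) @ basis[:2].T
        p = Polygon(uv)
        if not p.is_valid:
            p = p.buffer(0)
        if p.area < 1e-6:
            raise ValueError("degenerate (collinear) ring atoms")
        poly = p if poly is None else poly.union(p)
    return poly


def _overlap_in_plane(a: NucleotideStructure, b: NucleotideStructure) -> float:
    ring_a = a.coords([n for _, names in a.ring_names() for n in names])
    centroid, basis = _ring_plane(ring_a)
    pa = _base_polygon_2d(a, centroid, basis)
    pb = _base_polygon_2d(b, centroid, basis)
    return float(pa.intersection(pb).area)


def stacking_overlap_area(a: NucleotideStructure, b: NucleotideStructure) -> float:
    """Projected ring-polygon intersection area (Angstrom^2), symmetrised.

    B's ring system is projected onto the least-squares plane of A's rings
    and intersected with A's ring polygon; the result is averaged with the
    reverse projection so the metric is symmetric in its arguments.
    """
    return 0.5 * (_overlap_in_plane(a, b) + _overlap_in_plane(b, a))


def stacking_overlap_components(
    a: NucleotideStructure, b: NucleotideStructure
) -> dict[tuple[str, str], float]:
    """Per-ring overlap areas (e.g. six-membered vs six-membered), symmetrised."""
    out: dict[tuple[str, str], float] = {}
    for ra, names_a in a.ring_names():
        for rb, names_b in b.ring_names():
            sub_a = NucleotideStructure(a.residue_id, a.base_type, {n: a.atoms[n] for n in names_a})
            sub_b = NucleotideStructure(b.residue_id, b.base_type, {n: b.atoms[n] for n in names_b})
            # restrict ring_names to the single cycle via a direct projection
            def one(x, y, names_x, names_y):
                pts = x.coords(names_x)
                centroid, basis = _ring_plane(pts)
                px = Polygon((pts - centroid) @ basis[:2].T)
                py = Polygon((y.coords(names_y) - centroid) @ basis[:2].T)
                if not px.is_valid:
                    px = px.buffer(0)
                if not py.is_valid:
                    py = py.buffer(0)
                return float(px.intersection(py).area)

            out[(ra, rb)] = 0.5 * (
                one(sub_a, sub_b, names_a, names_b) + one(sub_b, sub_a, names_b, names_a)
            )
    return out


def rise(a: NucleotideStructure, b: NucleotideStructure) -> float:
    """Inter-plane distance: centroid separation along the mean ring normal."""
    ring_a = a.coords([n for _, names in a.ring_names() for n in names])
    ring_b = b.coords([n for _, names in b.ring_names() for n in names])
    ca, basis_a = _ring_plane(ring_a)
    cb, basis_b = _ring_plane(ring_b)
    na, nb = basis_a[2], basis_b[2]
    if np.dot(na, nb) < 0:
        nb = -nb
    n_mean = na + nb
    n_mean /= np.linalg.norm(n_mean)
    return float(abs(np.dot(cb - ca, n_mean)))


def stack_metrics(a: NucleotideStructure, b: NucleotideStructure) -> StackMetrics:
    chi1, chi2 = chi_torsion(a), chi_torsion(b)
    return StackMetrics(
        chi1_deg=chi1,
        orientation1=classify_glycosidic(chi1),
        chi2_deg=chi2,
        orientation2=classify_glycosidic(chi2),
        overlap_area_A2=stacking_overlap_area(a, b),
        rise_A=rise(a, b),
    )


def conformer_census(
    frames: list[tuple[NucleotideStructure, NucleotideStructure]],
) -> ConformerCensus:
    """Classify each frame's (base1, base2) syn/anti pair and tally fractions.

    Frames missing a torsion-defining atom are skipped and counted."""
    if len(frames) == 0:
        raise ValueError("census needs at least one frame")
    counts: Counter = Counter()
    skipped = 0
    for a, b in frames:
        try:
            c1 = classify_glycosidic(chi_torsion(a))
            c2 = classify_glycosidic(chi_torsion(b))
        except KeyError:
            skipped += 1
            continue
        counts[(c1, c2)] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("all frames were skipped (missing atoms)")
    fractions = {k: v / total for k, v in counts.items()}
    return ConformerCensus(dict(counts), fractions, n_frames=len(frames), n_skipped=skipped)


# ---------------------------------------------------------------- PDB I/O

_BASE_FROM_RESNAME = {
    "DA": "A", "DG": "G", "DC": "C", "DT": "T",
    "A": "A", "G": "G", "C": "C", "T": "T", "U": "T",
}


def nucleotides_from_atom_array(atom_array) -> list[NucleotideStructure]:
    """Convert one biotite AtomArray model into NucleotideStructure records."""
    import biotite.structure as struc

    out = []
    for res in struc.residue_iter(atom_array):
        resname = str(res.res_name[0])
        base = _BASE_FROM_RESNAME.get(resname)
        if base is None:
            continue
        atoms = {str(name): coord for name, coord in zip(res.atom_name, res.coord)}
        out.append(NucleotideStructure(int(res.res_id[0]), base, atoms))
    return out


def read_pdb_ensemble(path: str | Path) -> list[list[NucleotideStructure]]:
    """Read a (multi-model) PDB file into per-model nucleotide lists."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()
    models = []
    for i in range(stack.stack_depth()):
        models.append(nucleotides_from_atom_array(stack[i]))
    return models
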
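"""Glycosidic torsion, syn/anti classes, stacking overlap, census."""

import numpy as np
import pytest
from shapely import contains_xy

import cpdrepair.stack_geometry as sg
from cpdrepair.stack_geometry import (
    NucleotideStructure,
    chi_torsion,
    classify_glycosidic,
    conformer_census,
    dihedral_deg,
    rise,
    stacking_overlap_area,
    stacking_overlap_components,
)
from cpdrepair.synthetic_data import build_idealized_purine, generate_stacked_frames


def random_rigid_motion(rng):
    # QR of a random matrix -> uniform-ish rotation; fix determinant to +1
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.normal(scale=20.0, size=3)
    return q, t


def transform(nuc, q, t):
    return NucleotideStructure(
        nuc.residue_id, nuc.base_type, {k: q @ v + t for k, v in nuc.atoms.items()}
    )


class TestDihedral:
    def test_cis_is_zero(self):
        pts = [(1, 1, 0), (1, 0, 0), (0, 0, 0), (0, 1, 0)]
        assert dihedral_deg(*pts) == pytest.approx(0.0, abs=1e-12)

    def test_trans_is_180(self):
        pts = [(1, 1, 0), (1, 0, 0), (0, 0, 0), (0, -1, 0)]
        assert abs(dihedral_deg(*pts)) == pytest.approx(180.0, abs=1e-12)


class TestChiTorsion:
    @pytest.mark.parametrize("chi", [-175.0, -120.0, -90.01, 0.0, 60.0, 90.0, 180.0])
    def test_builder_realises_requested_chi(self, chi):
        nuc = build_idealized_purine("G", chi)
        assert chi_torsion(nuc) == pytest.approx(chi, abs=1e-9)

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(3)
        nuc = build_idealized_purine("A", -120.0)
        for _ in range(20):
            q, t = random_rigid_motion(rng)
            assert chi_torsion(transform(nuc, q, t)) == pytest.approx(-120.0, abs=1e-9)

    def test_missing_atom_named_in_error(self):
        nuc = build_idealized_purine("G", 60.0)
        atoms = {k: v for k, v in nuc.atoms.items() if k != "O4'"}
        broken = NucleotideStructure(1, "G", atoms)
        with pytest.raises(KeyError, match="O4'"):
            chi_torsion(broken)


class TestClassification:
    @pytest.mark.parametrize(
        "chi,expected",
        [(0.0, "syn"), (90.0, "syn"), (90.01, "anti"), (-90.0, "anti"),
         (-90.01, "anti"), (180.0, "anti"), (-120.0, "anti"), (60.0, "syn")],
    )
    def test_partition_of_the_circle(self, chi, expected):
        assert classify_glycosidic(chi) == expected


class TestOverlap:
    def test_eclipsed_equals_ring_polygon_area(self):
        """Same purine translated along its normal: overlap = full ring area.

        Regular hexagon + fused regular pentagon of side 1.39 A."""
        s = 1.39
        hexagon = 1.5 * np.sqrt(3.0) * s**2
        pentagon = 0.25 * np.sqrt(5.0 * (5.0 + 2.0 * np.sqrt(5.0))) * s**2
        a = build_idealized_purine("G", -120.0)
        b = NucleotideStructure(
            2, "G", {k: v + np.array([0.0, 0.0, 3.4]) for k, v in a.atoms.items()}
        )
        assert stacking_overlap_area(a, b) == pytest.approx(hexagon + pentagon, rel=1e-9)
        comps = stacking_overlap_components(a, b)
        assert comps[("six", "six")] == pytest.approx(hexagon, rel=1e-9)
        assert comps[("five", "five")] == pytest.approx(pentagon, rel=1e-9)
        assert comps[("six", "five")] == pytest.approx(0.0, abs=1e-9)

    def test_far_lateral_displacement_zero(self):
        a = build_idealized_purine("G", -120.0)
        b = NucleotideStructure(
            2, "G", {k: v + np.array([20.0, 0.0, 3.4]) for k, v in a.atoms.items()}
        )
        assert stacking_overlap_area(a, b) == 0.0

    def test_symmetric_in_arguments(self):
        ens = generate_stacked_frames(1, {("anti", "syn"): 1.0}, twist_deg=25.0, rng=9)
        a, b = ens.frames[0]
        assert stacking_overlap_area(a, b) == pytest.approx(
            stacking_overlap_area(b, a), rel=1e-12
        )

    @pytest.mark.parametrize("twist,seed", [(30.0, 3), (70.0, 4)])
    def test_matches_monte_carlo_point_sampling(self, twist, seed):
        """Polygon intersection vs 10^6-point rejection sampling, within 2%."""
        ens = generate_stacked_frames(1, {("anti", "anti"): 1.0}, twist_deg=twist, rng=seed)
        a, b = ens.frames[0]
        ring = a.coords([n for _, names in a.ring_names() for n in names])
        cen, basis = sg._ring_plane(ring)
        pa = sg._base_polygon_2d(a, cen, basis)
        pb = sg._base_polygon_2d(b, cen, basis)
        minx, miny, maxx, maxy = pa.union(pb).bounds
        rng = np.random.default_rng(0)
        pts = rng.uniform([minx, miny], [maxx, maxy], (1_000_000, 2))
        inside = contains_xy(pa, pts[:, 0], pts[:, 1]) & contains_xy(pb, pts[:, 0], pts[:, 1])
        mc_area = inside.mean() * (maxx - minx) * (maxy - miny)
        assert sg._overlap_in_plane(a, b) == pytest.approx(mc_area, rel=0.02)

    def test_invariant_under_joint_rigid_motion(self):
        rng = np.random.default_rng(5)
        ens = generate_stacked_frames(1, {("anti", "anti"): 1.0}, twist_deg=30.0, rng=2)
        a, b = ens.frames[0]
        ref_overlap = stacking_overlap_area(a, b)
        ref_rise = rise(a, b)
        for _ in range(10):
            q, t = random_rigid_motion(rng)
            ta, tb = transform(a, q, t), transform(b, q, t)
            assert stacking_overlap_area(ta, tb) == pytest.approx(ref_overlap, rel=1e-9)
            assert rise(ta, tb) == pytest.approx(ref_rise, abs=1e-9)

    def test_degenerate_ring_rejected(self):
        line = {
            n: np.array([float(i), 0.0, 0.0])
            for i, n in enumerate(["N1", "C2", "N3", "C4", "C5", "C6"])
        }
        line.update({"O4'": np.array([0.0, 1.0, 0.0]), "C1'": np.array([0.0, 2.0, 0.0])})
        bad = NucleotideStructure(1, "T", line)
        good = build_idealized_purine("G", 60.0)
        with pytest.raises(ValueError, match="degenerate"):
            stacking_overlap_area(bad, good)


class TestCensus:
    def test_all_identical_frames(self):
        ens = generate_stacked_frames(50, {("anti", "anti"): 1.0}, rng=1)
        cen = conformer_census(ens.frames)
        assert cen.fractions[("anti", "anti")] == 1.0

    def test_constructed_60_40_mixture_exact(self):
        a_ens = generate_stacked_frames(60, {("anti", "anti"): 1.0}, rng=1)
        s_ens = generate_stacked_frames(40, {("syn", "anti"): 1.0}, rng=2)
        cen = conformer_census(a_ens.frames + s_ens.frames)
        assert cen.fractions[("anti", "anti")] == pytest.approx(0.6)
        assert cen.fractions[("syn", "anti")] == pytest.approx(0.4)

    def test_recovers_generator_probabilities_within_binomial(self):
        n = 10_000
        ens = generate_stacked_frames(
            n, {("anti", "anti"): 0.5, ("syn", "anti"): 0.5},
            geometry_noise_deg=12.0, rng=8,
        )
        cen = conformer_census(ens.frames)
        three_sigma = 3.0 * np.sqrt(0.25 / n)
        assert abs(cen.fractions[("anti", "anti")] - 0.5) < three_sigma

    def test_frames_missing_atoms_are_skipped(self):
        ens = generate_stacked_frames(10, {("anti", "anti"): 1.0}, rng=1)
        a, b = ens.frames[0]
        broken = NucleotideStructure(
            1, "A", {k: v for k, v in a.atoms.items() if k != "O4'"}
        )
        cen = conformer_census(ens.frames + [(broken, b)])
        assert cen.n_skipped == 1
        assert sum(cen.fractions.values()) == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            conformer_census([])
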
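"""Structural descriptors: reaction coordinate, tilt angle, hydration
spheres, named distances, distributions and summary tables."""
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from claypmf import descriptors as desc
from claypmf.geometry import AtomRecord, GeometryError, Snapshot, build_cell
from claypmf.synthetic import toy_snapshot


def _box(a=30.0, b=30.0, c=40.0):
    return build_cell(a, b, c, 90, 90, 90)


def _base_snapshot(extra_atoms, cell=None):
    """A flat Ob sheet at z=0 plus caller-supplied atoms."""
    atoms = [AtomRecord("O", "Ob", (x, y, 0.0))
             for x in (8.0, 12.0, 16.0) for y in (8.0, 12.0, 16.0)]
    atoms.extend(extra_atoms)
    return Snapshot(cell=cell or _box(), atoms=atoms)


def _cl_n3(cl_pos, n3_pos):
    return _base_snapshot([
        AtomRecord("Cl", "atrazine:Cl", cl_pos),
        AtomRecord("N", "atrazine:N3", n3_pos),
    ])


class TestReactionCoordinate:
    def test_prescribed_height(self):
        snap = toy_snapshot(0.0, 2, 1, 1, 1, xi_target=3.5, seed=0)
        assert desc.reaction_coordinate(snap) == pytest.approx(3.5, abs=0.01)

    def test_invariant_under_joint_translation(self):
        snap = toy_snapshot(10.0, 3, 1, 2, 0, xi_target=4.2, seed=1)
        xi0 = desc.reaction_coordinate(snap)
        for at in snap.atoms:
            at.position = at.position + np.array([0.0, 0.0, 2.0])
        assert desc.reaction_coordinate(snap) == pytest.approx(xi0, abs=1e-9)

    def test_second_maximum_position_as_fixture(self):
        snap = toy_snapshot(48.7, 5, 2, 3, 1, xi_target=5.35, seed=2)
        assert desc.reaction_coordinate(snap) == pytest.approx(5.35, abs=0.01)

    def test_missing_adsorbate_is_error(self):
        snap = _base_snapshot([])
        with pytest.raises(GeometryError, match="atrazine"):
            desc.reaction_coordinate(snap)


class TestThetaAngle:
    def test_level_ring_is_zero(self):
        snap = _cl_n3((10, 10, 5.0), (12, 10, 5.0))
        assert desc.theta_angle(snap) == pytest.approx(0.0, abs=1e-12)

    def test_forced_plus_45(self):
        snap = _cl_n3((10, 10, 5.0), (11, 10, 6.0))
        assert desc.theta_angle(snap) == pytest.approx(45.0)

    def test_forced_minus_45(self):
        snap = _cl_n3((10, 10, 5.0), (11, 10, 4.0))
        assert desc.theta_angle(snap) == pytest.approx(-45.0)

    def test_vertical_alignment_uses_sign_convention(self):
        up = _cl_n3((10, 10, 5.0), (10, 10, 7.0))
        down = _cl_n3((10, 10, 5.0), (10, 10, 3.0))
        assert desc.theta_angle(up) == pytest.approx(90.0)
        assert desc.theta_angle(down) == pytest.approx(-90.0)

    def test_coincident_atoms_error(self):
        snap = _cl_n3((10, 10, 5.0), (10, 10, 5.0))
        with pytest.raises(GeometryError):
            desc.theta_angle(snap)

    @given(st.floats(-3, 3), st.floats(0.1, 3), st.floats(-3, 3))
    def test_antisymmetric_under_z_reflection(self, dz, dx, dy):
        cl = (10.0, 10.0, 5.0)
        plus = _cl_n3(cl, (10 + dx, 10 + dy, 5.0 + dz))
        minus = _cl_n3(cl, (10 + dx, 10 + dy, 5.0 - dz))
        assert desc.theta_angle(plus) == pytest.approx(
            -desc.theta_angle(minus), abs=1e-12)

    def test_toy_snapshot_round_trips_theta(self):
        for theta in (-60.0, -7.5, 0.0, 13.1, 48.7, 90.0):
            snap = toy_snapshot(theta, 4, 1, 2, 1, xi_target=5.0,
                                seed=int(abs(theta)))
            assert desc.theta_angle(snap) == pytest.approx(theta, abs=0.1)


class TestHydrationSphere:
    def test_no_waters_empty_set(self):
        snap = _base_snapshot([AtomRecord("Ca", "Ca2", (10, 10, 3.0))])
        assert desc.hydration_sphere(snap, "Ca2") == frozenset()

    def test_constructed_shell_count(self):
        ca2 = np.array([15.0, 15.0, 6.0])
        extra = [AtomRecord("Ca", "Ca2", ca2)]
        for i in range(4):  # inside the 3.0 Å cutoff
            d = np.array([np.cos(i), np.sin(i), 0.3]) / np.linalg.norm(
                [np.cos(i), np.sin(i), 0.3])
            extra.append(AtomRecord("O", "Ow", ca2 + 2.5 * d))
        for i in range(2):  # outside
            extra.append(AtomRecord("O", "Ow", ca2 + [3.5, 0, i]))
        snap = _base_snapshot(extra)
        assert len(desc.hydration_sphere(snap, "Ca2", cutoff=3.0)) == 4

    def test_cutoff_monotonicity(self):
        snap = toy_snapshot(20.0, 8, 2, 3, 1, xi_target=5.0, seed=9)
        small = desc.hydration_sphere(snap, "Atra", cutoff=3.0)
        large = desc.hydration_sphere(snap, "Atra", cutoff=4.5)
        assert small <= large

    def test_unknown_entity_rejected(self):
        snap = toy_snapshot(0.0, 1, 1, 1, 1, xi_target=4.0, seed=0)
        with pytest.raises(GeometryError):
            desc.hydration_sphere(snap, "Na1")


class TestHydrationReport:
    def test_disjoint_spheres_inclusion_exclusion(self):
        snap = toy_snapshot(0.0, 20, 0, 4, 0, xi_target=5.0, seed=3)
        rep = desc.hydration_report(snap)
        assert (len(rep.hs_atra), len(rep.hs_ca1), len(rep.hs_ca2)) == \
            (20, 0, 4)
        assert rep.shared_atra_ca1 == 0
        assert rep.hs_tot == 24

    def test_p1_modal_state(self):
        # Most frequent configuration near the first minimum: one water on
        # Ca1 (shared with the adsorbate sphere), four on Ca2.
        snap = toy_snapshot(7.1, 20, 1, 4, 1, xi_target=3.41, seed=4)
        rep = desc.hydration_report(snap)
        assert len(rep.hs_ca1) == 1 and len(rep.hs_ca2) == 4
        assert rep.ca1_subset_of_atra
        assert rep.hs_atra_ca1 == len(rep.hs_atra) == 20
        assert rep.hs_tot == 20 + 4

    def test_ca1_included_in_atra_regime(self):
        snap = toy_snapshot(20.8, 24, 2, 5, 2, xi_target=4.24, seed=5)
        rep = desc.hydration_report(snap)
        assert rep.ca1_subset_of_atra
        assert rep.hs_atra_ca1 == 24 and rep.shared_atra_ca1 == 2

    @pytest.mark.parametrize("seed", range(25))
    def test_random_prescriptions_round_trip(self, seed):
        rng = np.random.default_rng(1000 + seed)
        hs_ca1 = int(rng.integers(0, 5))
        hs_atra = int(rng.integers(hs_ca1, 30))
        shared = int(rng.integers(0, min(hs_atra, hs_ca1) + 1))
        hs_ca2 = int(rng.integers(0, 7))
        theta = float(rng.uniform(-80, 80))
        xi = float(rng.uniform(3.3, 8.5))
        snap = toy_snapshot(theta, hs_atra, hs_ca1, hs_ca2, shared, xi,
                            seed=seed)
        rep = desc.hydration_report(snap)
        assert len(rep.hs_atra) == hs_atra
        assert len(rep.hs_ca1) == hs_ca1
        assert len(rep.hs_ca2) == hs_ca2
        assert rep.shared_atra_ca1 == shared
        assert rep.hs_atra_ca1 == hs_atra + hs_ca1 - shared
        assert rep.hs_tot == hs_atra + hs_ca1 - shared + hs_ca2
        assert desc.theta_angle(snap) == pytest.approx(theta, abs=0.1)
        assert desc.reaction_coordinate(snap) == pytest.approx(xi, abs=0.01)


class TestNamedDistances:
    def test_toy_cation_contact(self):
        # The generator binds Ca1 at the monodentate contact distance.
        snap = toy_snapshot(6.1, 20, 1, 4, 1, xi_target=3.41, seed=6)
        d = desc.named_distances(snap)
        assert d["Ca1-N1"] == pytest.approx(2.411, abs=1e-6)

    def test_atom_on_surface_plane(self):
        snap = _base_snapshot([
            AtomRecord("Cl", "atrazine:Cl", (10, 10, 0.0)),
            AtomRecord("N", "atrazine:N1", (11, 10, 2.0)),
            AtomRecord("N", "atrazine:N3", (12, 10, 2.0)),
            AtomRecord("C", "atrazine:Ce", (13, 10, 3.0)),
            AtomRecord("C", "atrazine:Ci", (14, 10, 3.0)),
            AtomRecord("Ca", "Ca1", (11, 12, 1.0)),
            AtomRecord("Ca", "Ca2", (20, 20, 1.0)),
        ])
        d = desc.named_distances(snap)
        assert d["Cl-surf"] == pytest.approx(0.0, abs=1e-12)
        assert d["Ce-surf"] == pytest.approx(3.0)

    def test_cation_pair_uses_minimum_image(self):
        cell = _box()
        a_vec = cell.lattice_vectors[0]
        ca1 = np.array([2.0, 10.0, 5.0])
        ca2 = ca1 + a_vec + np.array([1.0, 0.0, 0.0])
        snap = _base_snapshot([
            AtomRecord("Cl", "atrazine:Cl", (10, 10, 4.0)),
            AtomRecord("N", "atrazine:N1", (11, 10, 4.0)),
            AtomRecord("N", "atrazine:N3", (12, 10, 4.0)),
            AtomRecord("C", "atrazine:Ce", (13, 10, 4.0)),
            AtomRecord("C", "atrazine:Ci", (14, 10, 4.0)),
            AtomRecord("Ca", "Ca1", ca1),
            AtomRecord("Ca", "Ca2", ca2),
        ], cell=cell)
        assert desc.named_distances(snap)["Ca1-Ca2"] == pytest.approx(1.0)

    def test_missing_named_atom_reported(self):
        snap = _base_snapshot([
            AtomRecord("Cl", "atrazine:Cl", (10, 10, 4.0)),
            AtomRecord("Ca", "Ca1", (11, 12, 1.0)),
            AtomRecord("Ca", "Ca2", (20, 20, 1.0)),
        ])
        with pytest.raises(GeometryError, match="atrazine:N1"):
            desc.named_distances(snap)


class TestNormalizedDistribution:
    def test_degenerate_values_single_bin(self):
        centers, density = desc.normalized_distribution(
            [2.0] * 10, n_bins=1, range=(1.5, 2.5))
        assert density[0] == pytest.approx(1.0)  # 1 / bin width

    def test_unit_area_for_random_input(self):
        rng = np.random.default_rng(8)
        centers, density = desc.normalized_distribution(
            rng.normal(size=5000), n_bins=37)
        width = centers[1] - centers[0]
        assert density.sum() * width == pytest.approx(1.0, abs=1e-9)

    def test_uniform_density_level(self):
        rng = np.random.default_rng(9)
        _, density = desc.normalized_distribution(
            rng.uniform(0, 1, size=100_000), n_bins=10, range=(0.0, 1.0))
        assert np.allclose(density, 1.0, atol=0.05)

    def test_empty_input_is_error(self):
        with pytest.raises(GeometryError):
            desc.normalized_distribution([], n_bins=5)


class TestSummaryTable:
    def _records(self, seeds_and_xi):
        out = []
        for seed, xi in seeds_and_xi:
            rng = np.random.default_rng(seed)
            snap = toy_snapshot(float(rng.uniform(-20, 60)),
                                int(rng.integers(10, 30)), 1, 4, 1, xi,
                                seed=seed)
            out.append(desc.describe_snapshot(snap))
        return out

    def test_single_record_group(self):
        (rec,) = self._records([(21, 3.41)])
        table = desc.summary_table({"P1": [rec]})
        assert table.loc["P1", "theta_mean"] == pytest.approx(rec.theta)
        assert table.loc["P1", "HSAtra_min"] == len(rec.hydration.hs_atra)

    def test_min_max_mean_bounds(self):
        recs = self._records([(22, 3.4), (23, 3.45)])
        h0 = len(recs[0].hydration.hs_atra)
        h1 = len(recs[1].hydration.hs_atra)
        table = desc.summary_table({"P1": recs})
        assert table.loc["P1", "HSAtra_min"] == min(h0, h1)
        assert table.loc["P1", "HSAtra_max"] == max(h0, h1)
        assert table.loc["P1", "HSAtra_mean"] == pytest.approx((h0 + h1) / 2)

    def test_reorder_invariance(self):
        recs = self._records([(24, 6.0), (25, 6.1), (26, 5.9)])
        t0 = desc.summary_table({"z6": recs})
        t1 = desc.summary_table({"z6": recs[::-1]})
        assert np.allclose(t0.values.astype(float), t1.values.astype(float))

    def test_empty_group_warns_and_is_omitted(self):
        recs = self._records([(27, 7.0)])
        with pytest.warns(UserWarning, match="empty"):
            table = desc.summary_table({"z7": recs, "z8": []})
        assert list(table.index) == ["z7"]
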
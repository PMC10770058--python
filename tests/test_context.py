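import numpy as np
import pytest

from conftest import brute_force_representation
from mender.data import SpatialDataset
from mender.context import (
    build_rings,
    compute_representation,
    default_params,
    estimate_radius,
)
from mender.states import set_cell_states
from mender.synthetic import generate_poisson_points


def _line_dataset(xs, slices=None, states=None):
    n = len(xs)
    return SpatialDataset(
        expression=np.ones((n, 2)),
        coordinates=np.array([[x, 0.0] for x in xs]),
        slice_id=np.array(slices if slices is not None else ["s"] * n),
        cell_state=np.array(states) if states is not None else None,
    )


class TestRadiusRings:
    def test_three_cell_line_rings(self):
        ds = _line_dataset([0.0, 10.0, 25.0])
        rings = build_rings(ds, mode="radius", R=15.0, S=2)
        assert set(rings.ring(0, 1)) == {0, 1}
        assert set(rings.ring(0, 2)) == {2}
        assert set(rings.ring(2, 1)) == {2}
        assert set(rings.ring(2, 2)) == {0, 1}

    def test_slice_separation_empties_cross_slice_rings(self):
        ds = _line_dataset([0.0, 10.0, 25.0], slices=["s1", "s1", "s2"])
        rings = build_rings(ds, mode="radius", R=15.0, S=2)
        assert set(rings.ring(0, 1)) == {0, 1}
        assert set(rings.ring(0, 2)) == set()

    def test_rings_disjoint_and_self_exclusion(self):
        rng = np.random.default_rng(0)
        ds = _line_dataset(rng.uniform(0, 200, 40))
        rings = build_rings(ds, R=20.0, S=3, self_in_first_ring=False)
        for i in range(ds.n_cells):
            assert i not in rings.neighbors[i]
            all_js = np.concatenate([rings.ring(i, s) for s in (1, 2, 3)])
            assert len(all_js) == len(set(all_js.tolist()))

    def test_boundary_distance_goes_to_outer_ring(self):
        # Dist = exactly R must land in ring 2 by the half-open rule
        ds = _line_dataset([0.0, 15.0])
        rings = build_rings(ds, R=15.0, S=2)
        assert 1 in rings.ring(0, 2)
        assert 1 not in rings.ring(0, 1)


class TestKnnRings:
    @staticmethod
    def _hex_lattice(rows=9, cols=9, spacing=10.0):
        pts = []
        for r in range(rows):
            for c in range(cols):
                pts.append((c * spacing + (r % 2) * spacing / 2, r * spacing * np.sqrt(3) / 2))
        return np.array(pts)

    def test_hex_lattice_shell_sizes(self):
        pts = self._hex_lattice()
        ds = SpatialDataset(
            expression=np.ones((len(pts), 2)),
            coordinates=pts,
            slice_id=np.array(["s"] * len(pts)),
        )
        rings = build_rings(ds, mode="knn", nn=6, S=2)
        center = np.argmin(((pts - pts.mean(0)) ** 2).sum(1))
        assert len(rings.ring(center, 1)) == 7  # self + 6
        assert len(rings.ring(center, 2)) == 12

    def test_small_slice_rejected(self):
        ds = _line_dataset([0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="spots"):
            build_rings(ds, mode="knn", nn=6, S=2)


class TestRepresentation:
    def test_worked_micro_example(self, three_cell_dataset):
        rings = build_rings(three_cell_dataset, R=15.0, S=2)
        rep = compute_representation(
            rings, set_cell_states(three_cell_dataset, three_cell_dataset.cell_state)
        )
        M = rep.M.toarray()
        np.testing.assert_array_equal(M[0], [2, 0, 0, 1])
        np.testing.assert_array_equal(M[1], [2, 0, 0, 1])
        np.testing.assert_array_equal(M[2], [0, 1, 2, 0])

    @pytest.mark.parametrize("self_in", [True, False])
    def test_matches_brute_force_oracle_on_random_instances(self, self_in):
        rng = np.random.default_rng(123)
        for _ in range(10):
            n = int(rng.integers(20, 120))
            n_slices = int(rng.integers(1, 4))
            C = int(rng.integers(2, 6))
            S = int(rng.integers(1, 5))
            R = float(rng.uniform(5, 30))
            coords = rng.uniform(0, 150, size=(n, 2))
            slices = rng.integers(0, n_slices, n).astype(str)
            states = rng.integers(0, C, n).astype(str)
            ds = SpatialDataset(
                expression=np.ones((n, 2)), coordinates=coords,
                slice_id=slices, cell_state=states,
            )
            rings = build_rings(ds, R=R, S=S, self_in_first_ring=self_in)
            rep = compute_representation(rings, set_cell_states(ds, states))
            expected, alphabet = brute_force_representation(
                coords, slices, states, R, S, self_in
            )
            assert list(rep.states) == alphabet
            np.testing.assert_array_equal(rep.M.toarray(), expected)

    def test_single_range_reduces_to_window_histogram(self):
        rng = np.random.default_rng(5)
        xs = rng.uniform(0, 50, 30)
        states = rng.choice(["A", "B", "C"], 30)
        ds = _line_dataset(xs, states=states)
        rings = build_rings(ds, R=1e6, S=1)
        rep = compute_representation(rings, set_cell_states(ds, states))
        hist = [(states == g).sum() for g in rep.states]
        np.testing.assert_array_equal(rep.M.toarray(), np.tile(hist, (30, 1)))

    def test_single_cell_one_hot(self):
        ds = _line_dataset([0.0], states=["A"])
        rep = compute_representation(
            build_rings(ds, R=15.0, S=2), set_cell_states(ds, ds.cell_state)
        )
        np.testing.assert_array_equal(rep.M.toarray(), [[1, 0]])

    def test_slice_translation_leaves_other_slices_unchanged(self):
        rng = np.random.default_rng(9)
        n = 60
        coords = rng.uniform(0, 100, size=(n, 2))
        slices = np.array(["a"] * 30 + ["b"] * 30)
        states = rng.choice(["X", "Y"], n)
        ds1 = SpatialDataset(np.ones((n, 2)), coords, slices, cell_state=states)
        coords2 = coords.copy()
        coords2[30:] += 1e4  # translate slice b far away
        ds2 = SpatialDataset(np.ones((n, 2)), coords2, slices, cell_state=states)
        rep1 = compute_representation(build_rings(ds1, R=10, S=3), set_cell_states(ds1, states))
        rep2 = compute_representation(build_rings(ds2, R=10, S=3), set_cell_states(ds2, states))
        np.testing.assert_array_equal(rep1.M.toarray(), rep2.M.toarray())

    def test_row_sums_grow_monotonically_with_S(self):
        rng = np.random.default_rng(11)
        ds = _line_dataset(rng.uniform(0, 300, 50), states=rng.choice(["A", "B"], 50))
        sums = []
        for S in (1, 2, 4):
            rep = compute_representation(
                build_rings(ds, R=20, S=S), set_cell_states(ds, ds.cell_state)
            )
            sums.append(np.asarray(rep.M.sum(axis=1)).ravel())
        assert (sums[1] >= sums[0]).all() and (sums[2] >= sums[1]).all()


class TestEstimateRadius:
    def test_regular_grid_spacing_recovered_exactly(self):
        xx, yy = np.meshgrid(np.arange(5) * 15.0, np.arange(5) * 15.0)
        coords = np.stack([xx.ravel(), yy.ravel()], axis=1)
        ds = SpatialDataset(np.ones((25, 2)), coords, np.array(["s"] * 25))
        report = estimate_radius(ds)
        s = report.per_slice["s"]
        assert s["Q1"] == s["median"] == s["Q3"] == 15.0
        assert report.recommended_radius == 15.0

    def test_poisson_process_matches_closed_form_median(self):
        lam = 0.01
        pts = generate_poisson_points(lam, (1000.0, 1000.0), seed=4)
        ds = SpatialDataset(
            np.ones((len(pts), 2)), pts, np.array(["s"] * len(pts))
        )
        report = estimate_radius(ds)
        expected = np.sqrt(np.log(2) / (np.pi * lam))
        assert abs(report.pooled_median - expected) / expected < 0.05

    def test_duplicate_coordinates_warn_not_raise(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 0.0]])
        ds = SpatialDataset(np.ones((3, 2)), coords, np.array(["s"] * 3))
        report = estimate_radius(ds)
        assert report.warnings
        assert report.per_slice["s"]["distances"].min() == 0.0


class TestDefaultParams:
    @pytest.mark.parametrize(
        "tech,expected",
        [
            ("visium", ("knn", 6, 2)),
            ("st", ("knn", 4, 2)),
            ("slide_seq", ("radius", 15.0, 4)),
            ("merfish", ("radius", 15.0, 6)),
            ("starmap", ("radius", 15.0, 6)),
        ],
    )
    def test_technology_conventions(self, tech, expected):
        assert default_params(tech) == expected

    def test_unknown_technology_suggests_estimate_radius(self):
        with pytest.raises(ValueError, match="estimate_radius"):
            default_params("seqmagic")
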
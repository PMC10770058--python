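import numpy as np
import pytest

from mender.data import SpatialDataset
from mender.synthetic import TissueSpec, generate_layered_tissue


@pytest.fixture
def tiny_dataset():
    """10 cells, 5 genes, 2 slices — the smallest useful dataset."""
    rng = np.random.default_rng(42)
    return SpatialDataset(
        expression=rng.integers(0, 10, size=(10, 5)),
        coordinates=rng.uniform(0, 100, size=(10, 2)),
        slice_id=np.array(["a"] * 5 + ["b"] * 5),
        cell_state=np.array(list("AABBA" * 2)),
        var_names=np.array([f"gene{i}" for i in range(5)]),
    )


@pytest.fixture
def three_cell_dataset():
    """Cells at (0,0), (10,0), (25,0) with states A, A, B on one slice."""
    return SpatialDataset(
        expression=np.ones((3, 2)),
        coordinates=np.array([[0.0, 0.0], [10.0, 0.0], [25.0, 0.0]]),
        slice_id=np.array(["s0"] * 3),
        cell_state=np.array(["A", "A", "B"]),
    )


@pytest.fixture(scope="session")
def small_tissue():
    """A fast 2-slice, 3-layer tissue for pipeline-level tests."""
    spec = TissueSpec(
        n_slices=2,
        layer_thickness=(400.0, 400.0, 400.0),
        width=600.0,
        cells_per_layer=230,
        seed=7,
    )
    ds, truth_domain, truth_states = generate_layered_tissue(spec)
    return ds, truth_domain, truth_states


def brute_force_representation(coords, slice_id, states, R, S, self_in_first_ring):
    """Independent O(N^2) oracle applying the ring-count definition literally."""
    states = np.asarray(states)
    alphabet = sorted(set(states.tolist()))
    C = len(alphabet)
    state_idx = {g: c for c, g in enumerate(alphabet)}
    n = len(states)
    M = np.zeros((n, S * C), dtype=np.int64)
    for i in range(n):
        for j in range(n):
            if slice_id[j] != slice_id[i]:
                continue
            if j == i and not self_in_first_ring:
                continue
            d = float(np.sqrt(((coords[j] - coords[i]) ** 2).sum()))
            for s in range(1, S + 1):
                if (s - 1) * R <= d < s * R:
                    M[i, (s - 1) * C + state_idx[states[j]]] += 1
    return M, alphabet
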
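import numpy as np
import pytest
import scipy.sparse as sp

from mender.data import SpatialDataset
from mender.domains import (
    MenderParams,
    cluster_domains,
    embed_representation,
    res_search,
    run_mender,
    umap_embed,
)
from mender.metrics import nmi


def _clouds(k, n_per=60, sep=100.0, dim=3, seed=0):
    rng = np.random.default_rng(seed)
    return np.vstack([rng.normal(i * sep, 1.0, size=(n_per, dim)) for i in range(k)])


class TestEmbedRepresentation:
    def test_identical_rows_identical_embeddings(self):
        M = np.array([[1, 2, 0], [1, 2, 0], [4, 0, 1], [0, 5, 5]])
        emb = embed_representation(M, n_components=2)
        np.testing.assert_allclose(emb[0], emb[1], atol=1e-12)

    def test_integer_multiple_rows_collapse(self):
        M = np.array([[1, 2, 0], [3, 6, 0], [4, 0, 1], [0, 5, 5]])
        emb = embed_representation(M, n_components=2)
        np.testing.assert_allclose(emb[0], emb[1], atol=1e-12)

    def test_bitwise_determinism(self):
        rng = np.random.default_rng(1)
        M = sp.csr_matrix(rng.integers(0, 5, size=(50, 12)))
        a = embed_representation(M, seed=3)
        b = embed_representation(M, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_zero_rows_pass_through(self):
        M = np.array([[0, 0, 0], [1, 2, 3], [2, 1, 0], [0, 3, 1]])
        emb = embed_representation(M, n_components=2)
        assert np.isfinite(emb).all()


class TestClusterDomains:
    def test_two_separated_clouds(self):
        emb = _clouds(2)
        result = cluster_domains(emb, resolution=0.5, seed=0)
        truth = np.repeat([0, 1], 60)
        assert result.n_domains == 2
        assert nmi(result.labels, truth) == pytest.approx(1.0)

    def test_vanishing_resolution_gives_one_domain(self):
        rng = np.random.default_rng(2)
        emb = rng.normal(size=(80, 3))  # one connected blob
        result = cluster_domains(emb, resolution=0.01, seed=0)
        assert result.n_domains == 1

    def test_seeded_determinism_and_label_names(self):
        emb = _clouds(3, seed=5)
        r1 = cluster_domains(emb, seed=4)
        r2 = cluster_domains(emb, seed=4)
        np.testing.assert_array_equal(r1.labels, r2.labels)
        assert set(r1.labels) == {"D0", "D1", "D2"}

    def test_nonpositive_resolution_rejected(self):
        with pytest.raises(ValueError, match="resolution"):
            cluster_domains(_clouds(2), resolution=0.0)


class TestResSearch:
    @pytest.mark.parametrize("k", [1, 2, 3, 5])
    def test_attains_requested_k_on_separable_fixture(self, k):
        emb = _clouds(k, seed=k)
        res, result = res_search(emb, target_k=k, seed=0)
        assert result.n_domains == k
        assert result.inexact is False
        if k > 1:
            truth = np.repeat(np.arange(k), 60)
            assert nmi(result.labels, truth) == pytest.approx(1.0)

    def test_unattainable_k_sets_inexact_flag(self):
        # resolution capped far below what 40 singleton domains would need
        emb = _clouds(2, n_per=20, seed=3)
        res, result = res_search(
            emb, target_k=40, n_neighbors=5, seed=0, res_bounds=(0.01, 0.2)
        )
        assert result.inexact is True
        assert result.n_domains < 40

    def test_target_beyond_n_rejected(self):
        with pytest.raises(ValueError, match="target_k"):
            res_search(np.zeros((10, 2)), target_k=11)


class TestUMAP:
    def test_deterministic_and_separates_clouds(self):
        emb = _clouds(2, n_per=40, seed=9)
        a = umap_embed(emb, seed=1)
        b = umap_embed(emb, seed=1)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (80, 2)
        ca, cb = a[:40].mean(0), a[40:].mean(0)
        ra = np.quantile(np.linalg.norm(a[:40] - ca, axis=1), 0.95)
        rb = np.quantile(np.linalg.norm(a[40:] - cb, axis=1), 0.95)
        gap = np.linalg.norm(ca - cb)
        assert gap > ra and gap > rb

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3"):
            umap_embed(np.zeros((2, 2)))


class TestRunMender:
    def test_recovers_layers_on_small_tissue(self, small_tissue):
        ds, truth_domain, _ = small_tissue
        result = run_mender(ds, MenderParams(target_k=3, seed=0))
        assert result.n_domains == 3
        assert nmi(result.labels, truth_domain) > 0.8

    def test_cross_slice_label_agreement(self, small_tissue):
        import pandas as pd

        ds, truth_domain, _ = small_tissue
        result = run_mender(ds, MenderParams(target_k=3, seed=0))
        for layer in np.unique(truth_domain):
            majors = set()
            for s in ds.slices:
                m = (truth_domain == layer) & (ds.slice_id == s)
                majors.add(pd.Series(result.labels[m]).mode()[0])
            assert len(majors) == 1

    def test_duplicated_slice_gets_identical_labels(self, small_tissue):
        ds, _, _ = small_tissue
        one = ds.slice_id == ds.slices[0]
        n = one.sum()
        dup = SpatialDataset(
            expression=np.vstack([ds.expression[one]] * 2),
            coordinates=np.vstack([ds.coordinates[one]] * 2),
            slice_id=np.array(["c1"] * n + ["c2"] * n),
            cell_state=np.concatenate([ds.cell_state[one]] * 2),
        )
        result = run_mender(
            dup, MenderParams(target_k=3, seed=0, state_source="provided")
        )
        np.testing.assert_array_equal(result.labels[:n], result.labels[n:])

    def test_pipeline_determinism(self, small_tissue):
        ds, _, _ = small_tissue
        p = MenderParams(target_k=3, seed=2, state_source="provided")
        r1 = run_mender(ds, p)
        r2 = run_mender(ds, p)
        np.testing.assert_array_equal(r1.labels, r2.labels)
        assert r1.resolution_used == r2.resolution_used

    def test_conflicting_k_and_resolution_rejected(self):
        with pytest.raises(ValueError, match="exactly one"):
            MenderParams(resolution=0.5, target_k=3)
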
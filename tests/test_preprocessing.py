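"""Signature construction, smoothing, HVG selection and normalization."""

import numpy as np
import pytest

from gist import (
    ExpressionMatrix,
    SingleCellReference,
    SmoothingConfig,
    ValidationError,
    build_signature,
    knn_smooth,
    normalize,
    select_shared_hvgs,
)
from gist.preprocessing import align_genes


def _expr(values, layer="counts"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"g{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        layer=layer,
    )


class TestBuildSignature:
    def test_mean_of_normalized_cells(self):
        # two type-A cells with normalized values (1,3) and (2,2) -> (2, 2)...
        # wait: per gene means of {1,2} and {3,2} -> (1.5, 2.5)
        ref = SingleCellReference(
            np.array([[1.0, 2.0], [3.0, 2.0]]), ["A", "A"], ["g0", "g1"]
        )
        W = build_signature(ref, normalizer=lambda x: x)
        np.testing.assert_allclose(W.values[:, 0], [1.5, 2.5])

    def test_single_cell_per_type_is_that_profile(self):
        ref = SingleCellReference(
            np.array([[1.0, 9.0], [3.0, 7.0]]), ["A", "B"], ["g0", "g1"]
        )
        W = build_signature(ref, normalizer=lambda x: x)
        np.testing.assert_allclose(W.values, [[1, 9], [3, 7]])
        assert W.cell_type_ids == ["A", "B"]

    def test_permutation_invariant_in_cell_order(self):
        rng = np.random.default_rng(0)
        vals = rng.poisson(5.0, (10, 20)).astype(float) + 1
        labels = list("AB") * 10
        ref = SingleCellReference(vals, labels, [f"g{i}" for i in range(10)])
        perm = rng.permutation(20)
        ref_p = SingleCellReference(
            vals[:, perm], [labels[i] for i in perm], [f"g{i}" for i in range(10)]
        )
        np.testing.assert_allclose(
            build_signature(ref).values, build_signature(ref_p).values
        )


class TestKnnSmooth:
    def test_identity_when_k_zero(self):
        em = _expr(np.arange(12.0).reshape(3, 4) + 1)
        out = knn_smooth(em, SmoothingConfig(k_neighbors=0, n_components=2))
        np.testing.assert_array_equal(out.values, em.values)
        assert out.layer == "smoothed"

    def test_identical_spots_aggregate_to_double(self):
        col = np.array([3.0, 1.0, 4.0])
        em = _expr(np.column_stack([col, col]))
        out = knn_smooth(em, SmoothingConfig(k_neighbors=1, n_components=1))
        np.testing.assert_allclose(out.values, 2 * em.values)

    def test_k_must_be_below_n_spots(self):
        em = _expr(np.ones((3, 4)))
        with pytest.raises(ValidationError, match="smaller"):
            knn_smooth(em, SmoothingConfig(k_neighbors=4, n_components=2))

    def test_aggregates_are_sums_of_input_profiles(self):
        rng = np.random.default_rng(1)
        em = _expr(rng.poisson(8.0, (15, 12)).astype(float))
        out, neighbors = knn_smooth(
            em, SmoothingConfig(k_neighbors=3, n_components=4), return_neighbors=True
        )
        expected = em.values[:, neighbors].sum(axis=2)
        np.testing.assert_allclose(out.values, expected)
        assert neighbors.shape == (12, 4)

    def test_within_block_variance_decreases(self):
        # 20 spots in two blocks of identical expected profiles
        rng = np.random.default_rng(2)
        mean_a = rng.uniform(2, 30, 25)
        mean_b = rng.uniform(2, 30, 25)
        block_a = rng.poisson(mean_a[:, None], (25, 10))
        block_b = rng.poisson(mean_b[:, None], (25, 10))
        em = _expr(np.concatenate([block_a, block_b], axis=1).astype(float))
        out = knn_smooth(em, SmoothingConfig(k_neighbors=5, n_components=2))

        def within_block_var(values):
            frac = values / values.sum(axis=0)
            return frac[:, :10].var(axis=1).mean() + frac[:, 10:].var(axis=1).mean()

        assert within_block_var(out.values) < within_block_var(em.values)


class TestSelectSharedHvgs:
    def test_identical_datasets_give_top_set(self):
        rng = np.random.default_rng(3)
        vals = rng.poisson(5.0, (30, 15)).astype(float) + 1
        em = _expr(vals)
        ref = SingleCellReference(vals, ["A"] * 15, em.gene_ids)
        got = select_shared_hvgs(em, ref, top_n=10)
        assert len(got) == 10
        assert got == [g for g in em.gene_ids if g in set(got)]  # st order

    def test_disjoint_gene_ids_error(self):
        em = _expr(np.ones((3, 4)))
        ref = SingleCellReference(np.ones((3, 4)), ["A"] * 4, ["x0", "x1", "x2"])
        with pytest.raises(ValidationError, match="share no gene"):
            select_shared_hvgs(em, ref)

    def test_inflated_dispersion_genes_are_selected(self):
        rng = np.random.default_rng(4)
        m, n = 60, 40
        st = rng.poisson(10.0, (m, n)).astype(float)
        sc = rng.poisson(10.0, (m, n)).astype(float)
        hot = rng.choice(m, 10, replace=False)
        # bimodal 0/100 pattern inflates the variance-stabilized dispersion
        st[hot] = rng.choice([0.0, 100.0], (10, n))
        sc[hot] = rng.choice([0.0, 100.0], (10, n))
        got = select_shared_hvgs(_expr(st), SingleCellReference(sc, ["A"] * n, _expr(sc).gene_ids), top_n=10)
        assert set(got) == {f"g{i}" for i in hot}

    def test_full_top_n_returns_shared_universe(self):
        rng = np.random.default_rng(5)
        vals = rng.poisson(5.0, (20, 10)).astype(float) + 1
        em = _expr(vals)
        ref = SingleCellReference(vals, ["A"] * 10, em.gene_ids)
        assert set(select_shared_hvgs(em, ref, top_n=20)) == set(em.gene_ids)


class TestNormalize:
    def test_proportional_spots_become_equal(self):
        col = np.array([2.0, 5.0, 1.0, 9.0])
        em = _expr(np.column_stack([col, 3 * col]))
        out = normalize(em)
        np.testing.assert_allclose(out.values[:, 0], out.values[:, 1], atol=1e-6)
        assert out.layer == "normalized"

    def test_constant_matrix_gives_constant_output(self):
        out = normalize(_expr(np.full((4, 3), 7.0)))
        assert np.ptp(out.values) == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_spot_is_named(self):
        vals = np.ones((3, 2))
        vals[:, 1] = 0
        with pytest.raises(ValidationError, match="s1"):
            normalize(_expr(vals))

    def test_depth_gradient_removed(self):
        # Poisson counts with a 10x depth gradient: after normalization the
        # spot depth no longer predicts per-gene values (mean per-gene
        # correlation ~ 0), whereas it strongly predicts the raw counts
        rng = np.random.default_rng(6)
        m, n = 200, 30
        base = rng.uniform(1, 20, m)
        depth_factor = np.geomspace(1, 10, n)
        counts = rng.poisson(base[:, None] * depth_factor[None, :]).astype(float)
        depths = counts.sum(axis=0)

        def mean_gene_corr(values):
            centered_d = depths - depths.mean()
            cv = values - values.mean(axis=1, keepdims=True)
            num = cv @ centered_d
            den = np.sqrt((cv**2).sum(axis=1) * (centered_d**2).sum()) + 1e-12
            return float(np.mean(num / den))

        out = normalize(_expr(counts), method="depth")
        assert abs(mean_gene_corr(out.values)) <= 0.05
        assert mean_gene_corr(counts) > 0.5

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            normalize(_expr(np.ones((2, 2))), method="quantile")


class TestAlignGenes:
    def test_alignment_is_by_id_not_position(self):
        from gist import SignatureMatrix

        em = ExpressionMatrix(np.array([[1.0], [2.0], [3.0]]), ["a", "b", "c"], ["s1"],
                              layer="normalized")
        W = SignatureMatrix(np.array([[30.0], [10.0]]), ["c", "a"], ["t"])
        Y2, W2 = align_genes(em, W)
        assert Y2.gene_ids == ["a", "c"] == W2.gene_ids
        np.testing.assert_array_equal(W2.values[:, 0], [10.0, 30.0])

    def test_too_few_shared_genes(self):
        from gist import SignatureMatrix

        em = ExpressionMatrix(np.ones((2, 1)), ["a", "b"], ["s1"], layer="normalized")
        W = SignatureMatrix(np.ones((2, 1)), ["a", "x"], ["t"])
        with pytest.raises(ValidationError, match="shared genes"):
            align_genes(em, W)
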
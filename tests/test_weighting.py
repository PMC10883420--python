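import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stwmd.data_model import tensor_from_long
from stwmd.errors import ConfigurationError, DomainError
from stwmd.weighting import (
    adjust_weights,
    compute_fold_change,
    normalize_regions,
    prescreen_genes,
    region_mean_baseline,
    weight_expression,
)
from stwmd.synthetic import GeneClassSpec, SyntheticSpec, generate_tensor

from conftest import long_frame, random_tensor


def single_gene_tensor(stage_values):
    """stage_values: {stage: {sample: [per-region values]}} for one gene."""
    rows = []
    for stage, samples in stage_values.items():
        for sample, values in samples.items():
            for r, v in enumerate(values):
                rows.append((stage, sample, f"r{r}", "g", float(v)))
    return tensor_from_long(long_frame(rows))


class TestNormalization:
    def test_forced_example(self):
        tensor = single_gene_tensor({"t0": {"a": [2, 4, 6]}})
        norm = normalize_regions(tensor, a=3)
        np.testing.assert_allclose(norm.values[0, 0, :, 0], [1.0, 2.5, 4.0])

    def test_varying_input_attains_printed_range(self):
        rng = np.random.default_rng(5)
        tensor = random_tensor(rng)
        norm = normalize_regions(tensor, a=3)
        per_cell = norm.values  # (S, I, R, G)
        assert np.nanmax(per_cell) == pytest.approx(4.0)
        assert np.nanmin(per_cell) == pytest.approx(1.0)
        # every regionally varying (t, i, g) attains both endpoints
        assert np.allclose(np.nanmax(per_cell, axis=2), 4.0)
        assert np.allclose(np.nanmin(per_cell, axis=2), 1.0)

    def test_constant_profile_maps_to_one(self):
        tensor = single_gene_tensor({"t0": {"a": [5, 5, 5]}})
        norm = normalize_regions(tensor)
        np.testing.assert_allclose(norm.values[0, 0, :, 0], 1.0)

    def test_nonpositive_a_rejected(self, toy_tensor):
        with pytest.raises(DomainError):
            normalize_regions(toy_tensor, a=0)

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(
        b=st.floats(0.1, 50),
        c=st.floats(0, 100),
        values=st.lists(st.floats(0.5, 100), min_size=3, max_size=6, unique=True),
    )
    def test_affine_invariance(self, b, c, values):
        base = single_gene_tensor({"t0": {"a": values}})
        scaled = single_gene_tensor({"t0": {"a": [b * v + c for v in values]}})
        np.testing.assert_allclose(
            normalize_regions(base).values[0, 0, :, 0],
            normalize_regions(scaled).values[0, 0, :, 0],
            atol=1e-8,
        )


class TestFoldChange:
    def _two_stage(self):
        # region means: t0 -> 2, t1 -> 3 after construction below
        return single_gene_tensor(
            {"t0": {"a": [2, 8], "b": [2, 8]}, "t1": {"a": [3, 8], "b": [3, 8]}}
        )

    def test_ratio_of_stage_means(self):
        tensor = single_gene_tensor(
            {"t0": {"a": [1, 2], "b": [3, 2]}, "t1": {"a": [3, 2], "b": [3, 2]}}
        )
        norm = normalize_regions(tensor)
        wt = compute_fold_change(norm)
        m0 = np.nanmean(norm.values[0, :2, :, 0], axis=0)
        m1 = np.nanmean(norm.values[1, :2, :, 0], axis=0)
        np.testing.assert_allclose(wt.fc[1, :, 0], m1 / m0)
        np.testing.assert_allclose(wt.log2fc[1, :, 0], np.log2(m1 / m0))

    def test_reference_stage_is_unity(self):
        rng = np.random.default_rng(11)
        norm = normalize_regions(random_tensor(rng))
        wt = compute_fold_change(norm)
        np.testing.assert_allclose(wt.fc[0][wt.observed[0]], 1.0)
        np.testing.assert_allclose(wt.log2fc[0][wt.observed[0]], 0.0)

    def test_identical_means_give_unit_fc(self):
        tensor = single_gene_tensor(
            {"t0": {"a": [2, 4], "b": [2, 4]}, "t1": {"a": [2, 4], "b": [2, 4]}}
        )
        wt = compute_fold_change(normalize_regions(tensor))
        np.testing.assert_allclose(wt.fc[1][wt.observed[1]], 1.0)

    def test_requires_normalized_tensor(self, toy_tensor):
        with pytest.raises(ConfigurationError):
            compute_fold_change(toy_tensor)

    def test_denominator_never_zero_on_normalized_data(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            norm = normalize_regions(random_tensor(rng, n_genes=5))
            wt = compute_fold_change(norm)
            assert np.all(np.isfinite(wt.fc[wt.observed]))
            assert np.all(wt.fc[wt.observed] > 0)


class TestAdjustWeights:
    def test_branch_grid(self):
        rng = np.random.default_rng(1)
        norm = normalize_regions(random_tensor(rng))
        wt = compute_fold_change(norm)
        cut = np.log2(1.5)
        grid = np.concatenate(
            [np.linspace(-3, 3, 121), [-cut, cut, -cut - 1e-12, cut - 1e-12]]
        )
        wt.log2fc = np.resize(grid, wt.log2fc.shape)
        wt.observed = np.ones_like(wt.observed)
        adj = adjust_weights(wt, f=1.5).adjusted
        lfc = wt.log2fc
        expected = np.where(lfc >= cut, lfc, np.where(lfc < -cut, -lfc, 0.0))
        np.testing.assert_allclose(adj, expected)
        assert np.all(adj >= 0)
        assert np.all((adj == 0) == (np.abs(lfc) < cut) | ((lfc == -cut)))

    def test_sign_flip_and_passthrough(self):
        tensor = single_gene_tensor(
            {"t0": {"a": [2, 4], "b": [2, 4]}, "t1": {"a": [4, 2], "b": [4, 2]}}
        )
        wt = adjust_weights(compute_fold_change(normalize_regions(tensor)), f=1.5)
        lfc = wt.log2fc[1, :, 0]
        adj = wt.adjusted[1, :, 0]
        assert lfc[0] > np.log2(1.5) and adj[0] == pytest.approx(lfc[0])
        assert lfc[1] < -np.log2(1.5) and adj[1] == pytest.approx(-lfc[1])

    def test_subthreshold_zeroed(self):
        tensor = single_gene_tensor(
            {"t0": {"a": [2, 4], "b": [2, 4]}, "t1": {"a": [2.2, 4], "b": [2.2, 4]}}
        )
        wt = adjust_weights(compute_fold_change(normalize_regions(tensor)), f=1.5)
        assert abs(wt.log2fc[1, 0, 0]) < np.log2(1.5)
        assert wt.adjusted[1, 0, 0] == 0.0

    def test_threshold_must_exceed_one(self):
        rng = np.random.default_rng(2)
        wt = compute_fold_change(normalize_regions(random_tensor(rng)))
        with pytest.raises(DomainError):
            adjust_weights(wt, f=1.0)

    def test_idempotent_above_threshold(self):
        rng = np.random.default_rng(4)
        wt = adjust_weights(
            compute_fold_change(normalize_regions(random_tensor(rng))), f=1.5
        )
        again = adjust_weights(
            type(wt)(
                stages=wt.stages, regions=wt.regions, genes=wt.genes,
                reference_stage=wt.reference_stage, fc=wt.fc,
                log2fc=wt.adjusted,  # rectified values as input
                observed=wt.observed,
            ),
            f=1.5,
        )
        above = wt.observed & (wt.adjusted >= np.log2(1.5))
        np.testing.assert_allclose(again.adjusted[above], wt.adjusted[above])


class TestWeightedAggregation:
    def test_forced_arithmetic(self):
        # weights (1, 2), values (2, 3) -> (1*2 + 2*3) / 3 = 8/3
        tensor = single_gene_tensor({"t0": {"a": [2, 3]}, "t1": {"a": [2, 3]}})
        norm = normalize_regions(tensor)
        wt = adjust_weights(compute_fold_change(norm), f=1.5)
        wt.adjusted[1] = np.array([[1.0], [2.0]])
        weighted = weight_expression(norm, wt)
        v = norm.values[1, 0, :, 0]
        assert weighted.values[1, 0, 0] == pytest.approx((1 * v[0] + 2 * v[1]) / 3)

    def test_single_nonzero_weight_selects_that_region(self):
        tensor = single_gene_tensor({"t0": {"a": [2, 3]}, "t1": {"a": [2, 3]}})
        norm = normalize_regions(tensor)
        wt = adjust_weights(compute_fold_change(norm), f=1.5)
        wt.adjusted[1] = np.array([[0.0], [3.0]])
        weighted = weight_expression(norm, wt)
        assert weighted.values[1, 0, 0] == pytest.approx(norm.values[1, 0, 1, 0])

    def test_all_zero_weights_fall_back_to_mean(self):
        tensor = single_gene_tensor(
            {"t0": {"a": [2, 4], "b": [2, 4]}, "t1": {"a": [2, 4], "b": [2, 4]}}
        )
        norm = normalize_regions(tensor)
        wt = adjust_weights(compute_fold_change(norm), f=1.5)  # all FC = 1 -> all 0
        weighted = weight_expression(norm, wt)
        np.testing.assert_allclose(
            weighted.values[weighted.observed],
            np.nanmean(norm.values, axis=2)[weighted.observed],
        )
        assert weighted.fallback_count == weighted.observed.sum()

    def test_convex_combination_bound(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            norm = normalize_regions(random_tensor(rng, n_genes=6))
            wt = adjust_weights(compute_fold_change(norm), f=1.2)
            weighted = weight_expression(norm, wt)
            lo = np.nanmin(norm.values, axis=2)
            hi = np.nanmax(norm.values, axis=2)
            obs = weighted.observed
            assert np.all(weighted.values[obs] >= lo[obs] - 1e-9)
            assert np.all(weighted.values[obs] <= hi[obs] + 1e-9)

    def test_equal_positive_weights_match_region_mean(self):
        rng = np.random.default_rng(10)
        norm = normalize_regions(random_tensor(rng))
        wt = adjust_weights(compute_fold_change(norm), f=1.5)
        wt.adjusted = np.where(wt.observed, 1.0, np.nan)
        weighted = weight_expression(norm, wt)
        baseline = region_mean_baseline(norm)
        np.testing.assert_allclose(
            weighted.values[weighted.observed],
            baseline.values[baseline.observed],
        )

    def test_region_mean_examples(self):
        tensor = single_gene_tensor({"t0": {"a": [2, 4]}})
        base = region_mean_baseline(tensor)
        assert base.values[0, 0, 0] == pytest.approx(3.0)
        single = single_gene_tensor({"t0": {"a": [7]}})
        assert region_mean_baseline(single).values[0, 0, 0] == pytest.approx(7.0)


class TestCounterbalance:
    """A gene up-regulated in half the regions and down-regulated in the other
    half carries real signal that signed log2FC weights cancel out."""

    def _fixture(self):
        # every region carries the effect, half up and half down; samples
        # miss 20% of regions, so each sample sees a different (and for the
        # signed scheme, near-cancelling) weight subset
        spec = SyntheticSpec(
            stages=("ctrl", "case"),
            samples_per_stage=(15, 15),
            n_regions=8,
            n_genes=40,
            classes=(
                GeneClassSpec(
                    "balanced", 40, (0.0, 2.0),
                    carrier_fraction=1.0, opposite_fraction=0.5,
                ),
            ),
            noise_sigma=0.1,
            missing_prob=0.2,
            seed=77,
        )
        tensor, _ = generate_tensor(spec)
        return normalize_regions(tensor)

    def test_adjusted_weights_beat_signed_weights(self):
        norm = self._fixture()
        wt = adjust_weights(compute_fold_change(norm), f=1.5)
        adj = weight_expression(norm, wt)
        signed = weight_expression(norm, wt, signed=True)

        def separation(w):
            # standardized stage separation: |mean difference| / pooled spread
            m0 = np.nanmean(w.values[0], axis=0)
            m1 = np.nanmean(w.values[1], axis=0)
            sd = np.sqrt(
                (np.nanvar(w.values[0], axis=0) + np.nanvar(w.values[1], axis=0)) / 2
            )
            return float(np.mean(np.abs(m1 - m0) / np.maximum(sd, 1e-12)))

        sep_adj, sep_signed = separation(adj), separation(signed)
        assert sep_adj > sep_signed
        assert sep_adj > 1.0  # stages clearly separate under adjusted weights
        # the signed aggregate escapes the convex hull of the regional values
        # (exploding denominators), which adjusted weights make impossible
        assert np.nanmax(np.abs(signed.values)) > 4.0 + 1e-6
        assert np.nanmax(adj.values) <= 4.0 + 1e-9
        assert np.nanmin(adj.values) >= 1.0 - 1e-9


class TestPrescreen:
    def test_top_fraction_q_one_returns_all(self, toy_tensor):
        assert prescreen_genes(toy_tensor, "top_fraction", q=1.0) == toy_tensor.genes

    def test_invalid_q_rejected(self, toy_tensor):
        with pytest.raises(DomainError):
            prescreen_genes(toy_tensor, "top_fraction", q=0.0)

    def test_per_region_de_finds_planted_genes_only(self):
        spec = SyntheticSpec(
            stages=("t0", "t1"),
            samples_per_stage=(10, 10),
            n_regions=3,
            n_genes=30,
            classes=(
                GeneClassSpec("hit", 2, (0.0, 3.0), carrier_fraction=1.0),
            ),
            noise_sigma=0.1,
            seed=5,
        )
        tensor, truth = generate_tensor(spec)
        hits = prescreen_genes(tensor, "per_region_de", alpha=0.01, f=1.5)
        assert set(hits) == set(truth.effect_genes)

    def test_top_fraction_union_size_bounds(self):
        # top-5% per stage pair, union over 3 pairs
        rng = np.random.default_rng(8)
        tensor = random_tensor(rng, n_stages=3, n_samples=4, n_regions=3, n_genes=200)
        hits = prescreen_genes(tensor, "top_fraction", q=0.05)
        per_pair = int(np.ceil(0.05 * 200))
        assert per_pair <= len(hits) <= 3 * per_pair
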
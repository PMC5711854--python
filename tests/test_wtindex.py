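"""RDA variance-explained, key-OTU selection, WT-index and ROC validation."""

import numpy as np
import pandas as pd
import pytest

from microkit import (
    SyntheticSpec,
    TransformedTable,
    bootstrap_auc_ci,
    generate,
    hellinger,
    loocv_auc,
    rda_two_group,
    roc_auc,
    select_key_otus,
    wt_index,
)
from microkit.wtindex import KeyOtuSet, KeySelectionError
from conftest import make_metadata

PAIR = ("WT", "MUT")


def _transformed(values, otu_ids=None):
    n = len(values)
    values = np.asarray(values, dtype=float)
    otu_ids = otu_ids or [f"o{j + 1}" for j in range(values.shape[1])]
    return TransformedTable([f"s{i + 1}" for i in range(n)], otu_ids, values)


def _meta_for(a, split):
    groups = ["WT"] * split + ["MUT"] * (len(a.sample_ids) - split)
    return make_metadata(a.sample_ids, groups)


class TestRdaTwoGroup:
    def test_equal_group_means_zero_varexp(self):
        a = _transformed([[0.2, 0.5], [0.4, 0.5], [0.2, 0.1], [0.4, 0.1]])
        meta = _meta_for(a, 2)
        _, varexp = rda_two_group(a, meta, PAIR)
        assert varexp["o1"] == pytest.approx(0.0)

    def test_perfect_separation_varexp_one(self):
        a = _transformed([[0.8, 0.1], [0.8, 0.3], [0.2, 0.1], [0.2, 0.3]])
        meta = _meta_for(a, 2)
        _, varexp = rda_two_group(a, meta, PAIR)
        assert varexp["o1"] == pytest.approx(1.0)
        assert varexp["o2"] == pytest.approx(0.0)

    def test_varexp_equals_univariate_regression_r2(self, rng):
        # brute-force oracle: per-OTU least-squares R^2 on the group indicator
        values = rng.uniform(0.0, 0.5, size=(8, 10))
        a = _transformed(values)
        meta = _meta_for(a, 4)
        _, varexp = rda_two_group(a, meta, PAIR)
        g = np.array([1.0] * 4 + [0.0] * 4)
        x = np.column_stack([np.ones(8), g])
        for j, otu in enumerate(a.otu_ids):
            y = values[:, j]
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            resid = y - x @ beta
            r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
            assert varexp[otu] == pytest.approx(r2, abs=1e-10)

    def test_constrained_proportion_is_between_over_total_ss(self, rng):
        values = rng.uniform(0.0, 0.5, size=(10, 6))
        a = _transformed(values)
        meta = _meta_for(a, 5)
        ordn, _ = rda_two_group(a, meta, PAIR)
        y = values - values.mean(axis=0)
        fitted = np.vstack([np.tile(y[:5].mean(axis=0), (5, 1)),
                            np.tile(y[5:].mean(axis=0), (5, 1))])
        assert ordn.proportion_explained[0] == pytest.approx(
            (fitted**2).sum() / (y**2).sum(), rel=1e-10
        )

    def test_small_group_rejected(self):
        a = _transformed([[0.1, 0.2], [0.3, 0.4], [0.5, 0.1]])
        meta = make_metadata(a.sample_ids, ["WT", "MUT", "MUT"])
        with pytest.raises(ValueError, match=">= 2 samples"):
            rda_two_group(a, meta, PAIR)


class TestSelectKeyOtus:
    def _setup(self):
        # o1 strongly WT-enriched, o2 strongly MUT-enriched, o3 uninformative
        a = _transformed(
            [[0.6, 0.1, 0.30], [0.7, 0.2, 0.31], [0.1, 0.6, 0.31], [0.2, 0.7, 0.30]]
        )
        meta = _meta_for(a, 2)
        _, varexp = rda_two_group(a, meta, PAIR)
        return a, meta, varexp

    def test_threshold_and_direction(self):
        a, meta, varexp = self._setup()
        keys = select_key_otus(varexp, a, meta, PAIR, threshold=0.10)
        assert keys.reference_enriched == ["o1"]
        assert keys.contrast_enriched == ["o2"]
        assert all(v > 0.10 for v in keys.variance_explained.values())

    def test_all_below_threshold_errors(self):
        a, meta, varexp = self._setup()
        with pytest.raises(KeySelectionError):
            select_key_otus(varexp, a, meta, PAIR, threshold=0.999)

    def test_planted_sets_recovered_on_synthetic_data(self):
        table, meta, truth = generate(SyntheticSpec(seed=11))
        a = hellinger(table)
        _, varexp = rda_two_group(a, meta, PAIR)
        keys = select_key_otus(varexp, a, meta, PAIR)
        planted_n = set(truth.reference_enriched)
        planted_m = set(truth.contrast_enriched)
        # recovered sets are dominated by the planted OTUs and directions agree
        assert len(set(keys.reference_enriched) & planted_n) >= 0.8 * len(planted_n)
        assert len(set(keys.contrast_enriched) & planted_m) >= 0.8 * len(planted_m)
        assert not set(keys.reference_enriched) & planted_m
        assert not set(keys.contrast_enriched) & planted_n


class TestWtIndex:
    def test_direct_formula(self):
        a = _transformed([[0.6, 0.2]])
        keys = KeyOtuSet(["o1"], ["o2"], {"o1": 0.5, "o2": 0.4}, 0.1)
        res = wt_index(a, keys)
        assert res.index[0] == pytest.approx(0.4)

    def test_set_size_normalisation(self):
        a = _transformed([[0.6, 0.2, 0.8]])
        keys = KeyOtuSet(["o1", "o3"], ["o2"], {"o1": 0.5, "o2": 0.4, "o3": 0.6}, 0.1)
        res = wt_index(a, keys)
        assert res.index[0] == pytest.approx(0.7 - 0.2)
        assert res.reference_component[0] == pytest.approx(1.4)
        assert res.contrast_component[0] == pytest.approx(0.2)

    def test_zero_abundance_on_keys_gives_zero(self):
        a = _transformed([[0.0, 0.0, 0.9]])
        keys = KeyOtuSet(["o1"], ["o2"], {"o1": 0.5, "o2": 0.4}, 0.1)
        assert wt_index(a, keys).index[0] == 0.0

    def test_missing_key_otu_listed(self):
        a = _transformed([[0.6, 0.2]])
        keys = KeyOtuSet(["o1"], ["zz"], {"o1": 0.5, "zz": 0.4}, 0.1)
        with pytest.raises(ValueError, match="zz"):
            wt_index(a, keys)

    def test_linear_in_reference_abundances(self):
        base = np.array([[0.2, 0.1, 0.3], [0.4, 0.2, 0.1]])
        keys = KeyOtuSet(["o1", "o3"], ["o2"], {"o1": 0.5, "o2": 0.4, "o3": 0.6}, 0.1)
        r1 = wt_index(_transformed(base), keys)
        scaled = base.copy()
        scaled[:, [0, 2]] *= 0.5
        r2 = wt_index(_transformed(scaled), keys)
        np.testing.assert_allclose(r2.reference_component, 0.5 * r1.reference_component)

    def test_index_bounded_on_hellinger_input(self, rng):
        counts = rng.integers(0, 100, size=(12, 20))
        counts[:, 0] += 1
        from microkit import OtuTable

        a = hellinger(OtuTable([f"s{i}" for i in range(12)],
                               [f"o{j + 1}" for j in range(20)], counts))
        keys = KeyOtuSet(["o1", "o2"], ["o3"], {"o1": 1, "o2": 1, "o3": 1}, 0.5)
        res = wt_index(a, keys)
        assert np.all(res.index >= -1) and np.all(res.index <= 1)


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert res.auc == 1.0

    def test_all_ties_half(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]).auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_pairwise_oracle(self, rng):
        # exhaustive oracle: wins + half-ties over all positive/negative pairs
        scores = np.round(rng.uniform(size=20), 1)  # rounding forces some ties
        labels = rng.integers(0, 2, size=20)
        labels[:2] = [0, 1]
        pos, neg = scores[labels == 1], scores[labels == 0]
        oracle = np.mean([(p > q) + 0.5 * (p == q) for p in pos for q in neg])
        assert roc_auc(scores, labels).auc == pytest.approx(oracle, abs=1e-12)

    def test_negated_scores_complement(self, rng):
        scores = rng.normal(size=15)  # continuous, tie-free
        labels = np.array([1] * 7 + [0] * 8)
        assert roc_auc(scores, labels).auc + roc_auc(-scores, labels).auc == pytest.approx(1.0)


class TestBootstrapCi:
    def test_perfectly_separated_ci_degenerate(self):
        lo, hi = bootstrap_auc_ci([3, 4, 1, 2], [1, 1, 0, 0], n_boot=200, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_single_pair(self):
        lo, hi = bootstrap_auc_ci([1.0, 0.0], [1, 0], n_boot=50, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_interval_brackets_point_auc_mostly(self, rng):
        # coverage of the point estimate on overlapping score distributions
        hits = 0
        for rep in range(40):
            pos = rng.normal(0.5, 1, size=12)
            neg = rng.normal(0.0, 1, size=12)
            scores = np.concatenate([pos, neg])
            labels = np.array([1] * 12 + [0] * 12)
            auc = roc_auc(scores, labels).auc
            lo, hi = bootstrap_auc_ci(scores, labels, n_boot=200, seed=rep)
            hits += lo <= auc <= hi
        assert hits >= 36  # >= 90%


class TestLoocv:
    def test_too_few_samples(self):
        table, meta, _ = generate(
            SyntheticSpec(p_otus=10, n_per_group=1, n_ref_enriched=2,
                          n_contrast_enriched=2, seed=0)
        )
        with pytest.raises(ValueError):
            loocv_auc(table, meta, PAIR)

    def test_strong_effect_high_auc(self):
        table, meta, _ = generate(
            SyntheticSpec(p_otus=100, n_per_group=15, n_ref_enriched=20,
                          n_contrast_enriched=20, effect_log2fc=2.0, seed=5)
        )
        res = loocv_auc(table, meta, PAIR, seed=5, n_boot=100)
        assert res.auc >= 0.95
        assert res.cv_mode == "loocv"
        assert res.ci_low <= res.ci_high

    def test_null_effect_auc_near_half(self):
        aucs = []
        for seed in range(3):
            table, meta, _ = generate(
                SyntheticSpec(p_otus=50, n_per_group=15, n_ref_enriched=0,
                              n_contrast_enriched=0, effect_log2fc=0.0, seed=seed)
            )
            aucs.append(loocv_auc(table, meta, PAIR, seed=seed, n_boot=50).auc)
        assert 0.3 <= np.mean(aucs) <= 0.7
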
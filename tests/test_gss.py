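import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from cfgi.gss import (
    cv_select,
    gene_z,
    gss_apply,
    rank_genes,
    score_genes,
    score_external,
)


def _bins(n, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom,
                         "start": np.arange(n) * 1_000_000 + 1,
                         "end": np.arange(1, n + 1) * 1_000_000,
                         "gc": 0.4, "usable": True})


class TestGeneZ:
    def test_gene_inside_one_bin(self):
        bins = _bins(3)
        genes = pd.DataFrame({"symbol": ["G"], "chrom": ["chr1"],
                              "start": [1_200_000], "end": [1_400_000]})
        gz = gene_z(np.array([1.0, 3.0, 5.0]), genes, bins)
        assert gz["G"] == pytest.approx(3.0)

    def test_two_bin_weighted_mean(self):
        bins = _bins(2)
        # 250 kb in bin 1 (z=2), 750 kb in bin 2 (z=4) -> 2*0.25 + 4*0.75
        genes = pd.DataFrame({"symbol": ["G"], "chrom": ["chr1"],
                              "start": [750_001], "end": [1_750_000]})
        gz = gene_z(np.array([2.0, 4.0]), genes, bins)
        assert gz["G"] == pytest.approx(3.5)

    def test_matches_brute_force_overlap(self):
        rng = np.random.default_rng(4)
        bins = _bins(30)
        z = rng.normal(size=30)
        genes = pd.DataFrame({
            "symbol": [f"G{i}" for i in range(10)],
            "chrom": "chr1",
            "start": rng.integers(1, 29_000_000, 10),
        })
        genes["end"] = genes["start"] + rng.integers(10_000, 3_000_000, 10)
        gz = gene_z(z, genes, bins)
        for _, g in genes.iterrows():
            num = den = 0.0
            for j in range(30):
                s, e = bins.loc[j, "start"], bins.loc[j, "end"]
                ov = min(e, g["end"]) - max(s, g["start"]) + 1
                if ov > 0:
                    num += z[j] * ov
                    den += ov
            assert gz[g["symbol"]] == pytest.approx(num / den, rel=1e-9)

    def test_gene_outside_usable_bins_missing(self):
        bins = _bins(2)
        bins.loc[1, "usable"] = False
        genes = pd.DataFrame({"symbol": ["G"], "chrom": ["chr1"],
                              "start": [1_100_000], "end": [1_200_000]})
        assert np.isnan(gene_z(np.array([1.0, 2.0]), genes, bins)["G"])


class TestScoreGenes:
    def _mat(self, values):
        return pd.DataFrame({"G": values})

    @pytest.mark.parametrize("region, z, expected", [
        ("amp", 2.2, 1),
        ("amp", 2.0, 0),     # strict: exactly 2 scores 0
        ("amp", -3.0, 0),    # wrong direction for an amplification region
        ("del", -2.1, 1),
        ("del", -2.0, 0),
        ("del", 3.0, 0),
    ])
    def test_direction_aware_thresholds(self, region, z, expected):
        scores = score_genes(self._mat([z]), pd.Series({"G": region}))
        assert scores.loc[0, "G"] == expected

    def test_missing_z_scores_zero_with_warning(self):
        with pytest.warns(UserWarning, match="missing"):
            scores = score_genes(self._mat([np.nan]), pd.Series({"G": "amp"}))
        assert scores.loc[0, "G"] == 0

    def test_untagged_gene_rejected(self):
        with pytest.raises(ValueError, match="region type"):
            score_genes(self._mat([1.0]), pd.Series(dtype=object))


class TestRankGenes:
    def test_perfectly_separating_gene_ranks_first(self):
        rng = np.random.default_rng(0)
        n = 20
        times = np.concatenate([rng.uniform(1, 5, 10), rng.uniform(20, 30, 10)])
        events = np.ones(n, dtype=int)
        scores = pd.DataFrame({
            "SEP": np.r_[np.ones(10, int), np.zeros(10, int)],  # early deaths score 1
            "NOISE1": rng.binomial(1, 0.5, n),
            "NOISE2": rng.binomial(1, 0.5, n),
        })
        ranked = rank_genes(scores, times, events)
        assert ranked.iloc[0]["symbol"] == "SEP"

    def test_constant_column_gets_sentinel(self):
        times = np.arange(1, 11.0)
        events = np.ones(10, int)
        scores = pd.DataFrame({"ZERO": np.zeros(10, int),
                               "VAR": np.r_[np.ones(5, int), np.zeros(5, int)]})
        ranked = rank_genes(scores, times, events)
        assert ranked.set_index("symbol").loc["ZERO", "p"] == 1.0
        assert ranked.iloc[-1]["symbol"] == "ZERO"

    def test_logrank_matches_independent_implementation(self):
        # printed 6-subject toy: times 1..6, all events, groups 0,0,0,1,1,1
        times = np.arange(1, 7.0)
        events = np.ones(6, int)
        scores = pd.DataFrame({"G": [0, 0, 0, 1, 1, 1]})
        p = rank_genes(scores, times, events).iloc[0]["p"]
        ref = logrank_test(times[:3], times[3:], events[:3], events[3:]).p_value
        assert p == pytest.approx(ref, rel=1e-9)
        assert p == pytest.approx(0.0246023, abs=1e-6)


def _planted_cv_cohort(seed, n=200, n_genes=30, n_sig=10, gene_hr=1.8, prev=0.3):
    """Each planted gene multiplies the hazard by ``gene_hr`` when scored 1."""
    rng = np.random.default_rng(seed)
    scores = pd.DataFrame(rng.binomial(1, prev, size=(n, n_genes)),
                          columns=[f"G{i:02d}" for i in range(n_genes)])
    loghaz = np.log(gene_hr) * scores.iloc[:, :n_sig].sum(axis=1).to_numpy()
    lam = 0.05 * np.exp(loghaz)
    t = rng.exponential(1 / lam)
    c = rng.uniform(0, 40, size=n)
    return scores, np.minimum(t, c), (t <= c).astype(int)


class TestCvSelect:
    def test_forced_single_gene_choice(self):
        scores, times, events = _planted_cv_cohort(1)
        model = cv_select(scores, times, events, k=5, n_range=range(1, 2), seed=1)
        for fold in model.folds:
            assert fold["top_n"] == 1
            assert len(fold["selected_genes"]) == 1

    def test_planted_genes_recovered_in_union(self):
        hits = []
        for seed in range(5):
            scores, times, events = _planted_cv_cohort(seed)
            model = cv_select(scores, times, events, k=5, seed=seed)
            planted = {f"G{i:02d}" for i in range(10)}
            hits.append(len(planted & set(model.union_genes)))
        assert sum(h >= 8 for h in hits) >= 4

    def test_overlap_subset_of_union_and_folds(self):
        scores, times, events = _planted_cv_cohort(7)
        model = cv_select(scores, times, events, k=5, seed=7)
        for fold in model.folds:
            assert set(model.overlap_genes) <= set(fold["selected_genes"])
            assert set(fold["selected_genes"]) <= set(model.union_genes)

    def test_reproducible_given_seed(self):
        scores, times, events = _planted_cv_cohort(3)
        a = cv_select(scores, times, events, k=5, seed=11)
        b = cv_select(scores, times, events, k=5, seed=11)
        assert a.folds == b.folds
        assert a.union_genes == b.union_genes

    def test_cohort_too_small_rejected(self):
        scores, times, events = _planted_cv_cohort(1, n=20)
        with pytest.raises(ValueError, match="too small"):
            cv_select(scores, times, events, k=5)


class TestGssApply:
    def test_all_zero_sample_is_low(self):
        scores = pd.DataFrame({"A": [0, 1], "B": [0, 1]})
        out = gss_apply(scores, ["A", "B"], cutoff=0)
        assert out.loc[0, "gss"] == 0 and out.loc[0, "group"] == "low"
        assert out.loc[1, "gss"] == 2 and out.loc[1, "group"] == "high"

    def test_nine_positive_genes_cutoff_eight_is_high(self):
        genes = [f"G{i}" for i in range(79)]
        row = {g: 0 for g in genes}
        for g in genes[:9]:
            row[g] = 1
        scores = pd.DataFrame([row])
        out = gss_apply(scores, genes, cutoff=8)
        assert out.loc[0, "gss"] == 9 and out.loc[0, "group"] == "high"

    def test_missing_genes_contribute_zero(self):
        scores = pd.DataFrame({"A": [1]})
        with pytest.warns(UserWarning, match="absent"):
            out = gss_apply(scores, ["A", "MISSING"], cutoff=0)
        assert out.loc[0, "gss"] == 1
        assert out.loc[0, "n_missing_genes"] == 1

    def test_monotone_in_scores(self):
        rng = np.random.default_rng(2)
        scores = pd.DataFrame(rng.binomial(1, 0.3, (20, 5)),
                              columns=list("ABCDE"))
        base = gss_apply(scores, list("ABCDE"), cutoff=2)["gss"]
        bumped = scores.copy()
        bumped.loc[bumped.index[0], "A"] = 1
        after = gss_apply(bumped, list("ABCDE"), cutoff=2)["gss"]
        assert (after >= base).all()

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError):
            gss_apply(pd.DataFrame({"A": [1]}), [], cutoff=0)


class TestScoreExternal:
    def test_only_high_level_calls_score(self):
        calls = pd.DataFrame({"s1": [2, 1, 0, -1, -2]},
                             index=["A", "B", "C", "D", "E"])
        scored = score_external(calls)
        assert scored.loc["s1"].tolist() == [1, 0, 0, 0, 1]

    def test_non_gistic_values_rejected(self):
        with pytest.raises(ValueError):
            score_external(pd.DataFrame({"s1": [3]}, index=["A"]))
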
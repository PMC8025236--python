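"""Ranked-bin de-repression inference: shift, binning, enrichment, consensus."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mirstem import derepression as dr
from mirstem.synthetic import SyntheticConfig, simulate_derepression_profiles


def _annot(targets, universe):
    scores = pd.Series(
        {g: (-0.3 if g in targets else np.nan) for g in universe}, name="context_score"
    )
    return dr.make_annotation(scores)


class TestGlobalShift:
    def test_direct_median_difference(self):
        universe = list("abcdef")
        profile = pd.Series([1.0, 2.0, 3.0, 0.0, 1.0, 2.0], index=universe)
        res = dr.global_shift(profile, _annot({"a", "b", "c"}, universe), n_bootstrap=50)
        assert res.median_shift == pytest.approx(1.0)

    def test_null_same_values(self):
        universe = [f"g{i}" for i in range(200)]
        rng = np.random.default_rng(0)
        vals = rng.normal(size=200)
        profile = pd.Series(vals, index=universe)
        res = dr.global_shift(profile, _annot(set(universe[::2]), universe), n_bootstrap=50)
        assert abs(res.median_shift) < 0.3
        assert res.wilcoxon_p > 0.01

    def test_bootstrap_seeded(self):
        universe = [f"g{i}" for i in range(100)]
        profile = pd.Series(np.random.default_rng(1).normal(size=100), index=universe)
        annot = _annot(set(universe[:30]), universe)
        r1 = dr.global_shift(profile, annot, seed=5)
        r2 = dr.global_shift(profile, annot, seed=5)
        assert r1.sem == r2.sem

    def test_empty_target_set_rejected(self):
        universe = list("abcd")
        profile = pd.Series([1.0, 2.0, 3.0, 4.0], index=universe)
        with pytest.raises(ValueError):
            dr.global_shift(profile, _annot(set(), universe))


class TestRankAndBin:
    def test_remainder_distribution(self):
        # oracle: enumeration of the remainder rule for N=25, B=10
        universe = [f"g{i:02d}" for i in range(25)]
        profile = pd.Series(np.arange(25, dtype=float), index=universe)
        bins = dr.rank_and_bin(profile, n_bins=10)
        sizes = bins.value_counts().sort_index().tolist()
        assert sizes == [3, 3, 3, 3, 3, 2, 2, 2, 2, 2]

    def test_one_gene_per_bin(self):
        universe = [f"g{i}" for i in range(10)]
        profile = pd.Series(np.arange(10, dtype=float), index=universe)
        bins = dr.rank_and_bin(profile, n_bins=10)
        assert bins.value_counts().eq(1).all()
        # most up-regulated gene lands in bin 1
        assert bins[profile.idxmax()] == 1

    def test_ties_broken_lexicographically(self):
        profile = pd.Series([0.0, 0.0, 0.0, 0.0], index=["d", "b", "a", "c"])
        bins = dr.rank_and_bin(profile, n_bins=2)
        assert bins["a"] == 1 and bins["b"] == 1 and bins["c"] == 2 and bins["d"] == 2

    def test_too_few_genes_rejected(self):
        profile = pd.Series([1.0], index=["a"])
        with pytest.raises(ValueError):
            dr.rank_and_bin(profile, n_bins=10)

    @settings(max_examples=40, deadline=None)
    @given(
        n=st.integers(min_value=10, max_value=200),
        n_bins=st.integers(min_value=2, max_value=10),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_partition_is_exact_and_total(self, n, n_bins, seed):
        rng = np.random.default_rng(seed)
        profile = pd.Series(rng.normal(size=n), index=[f"g{i:03d}" for i in range(n)])
        bins = dr.rank_and_bin(profile, n_bins=n_bins)
        sizes = bins.value_counts().sort_index()
        assert sizes.sum() == n
        assert sizes.max() - sizes.min() <= 1
        assert set(bins.index) == set(profile.index)


class TestBinEnrichment:
    def test_hand_computed_table(self):
        # N=100, 20 targets, top bin of 10 genes holds 6 of them
        universe = [f"g{i:03d}" for i in range(100)]
        values = np.zeros(100)
        targets = set(universe[:6]) | set(universe[40:54])  # 6 in top bin, 14 elsewhere
        values[:10] = np.linspace(10, 9, 10)  # top bin = first 10 genes
        values[10:] = np.linspace(5, 0, 90)
        profile = pd.Series(values, index=universe)
        bins = dr.rank_and_bin(profile, n_bins=10)
        table = dr.bin_enrichment(bins, _annot(targets, universe))
        row = table.loc[1]
        assert row["observed_targets"] == 6
        assert row["expected_targets"] == pytest.approx(2.0)
        assert row["log2_obs_exp"] == pytest.approx(np.log2(3.0))
        # hand Pearson chi2 on [[6,4],[14,76]] is 11.111...
        assert row["chi2"] == pytest.approx(100.0 / 9.0, rel=1e-9)
        # expected cell (2.0) < 5 so the p-value comes from Fisher's exact test
        assert row["method"] == "fisher"
        assert row["p_value"] == pytest.approx(
            stats.fisher_exact([[6, 4], [14, 76]])[1], rel=1e-9
        )

    def test_conservation_of_counts(self, small_derepression):
        profiles, annot, _ = small_derepression
        bins = dr.rank_and_bin(profiles["exp1"])
        table = dr.bin_enrichment(bins, annot)
        assert table["gene_count"].sum() == len(profiles["exp1"])
        assert table["observed_targets"].sum() == annot["is_predicted_target"].sum()
        assert table["expected_targets"].sum() == pytest.approx(
            annot["is_predicted_target"].sum()
        )

    def test_all_targets_in_one_bin(self):
        universe = [f"g{i:03d}" for i in range(100)]
        profile = pd.Series(-np.arange(100, dtype=float), index=universe)
        targets = set(universe[:10])  # exactly the top bin
        table = dr.bin_enrichment(dr.rank_and_bin(profile, 10), _annot(targets, universe))
        assert table["observed_targets"].tolist() == [10] + [0] * 9
        # empty bins get the pseudo-count and stay finite
        assert np.isfinite(table["log2_obs_exp"]).all()
        assert (table.loc[2:, "log2_obs_exp"] < 0).all()

    def test_no_targets_rejected(self):
        universe = [f"g{i}" for i in range(20)]
        profile = pd.Series(np.arange(20, dtype=float), index=universe)
        with pytest.raises(ValueError):
            dr.bin_enrichment(dr.rank_and_bin(profile, 2), _annot(set(), universe))

    def test_fisher_branch_matches_exhaustive_enumeration(self):
        # small universes: two-sided Fisher p equals summing all tables with
        # pmf <= the observed table's pmf at fixed margins
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(20):
            n = int(rng.integers(12, 50))
            universe = [f"g{i:02d}" for i in range(n)]
            t = int(rng.integers(2, n // 2))
            targets = set(rng.choice(universe, size=t, replace=False))
            profile = pd.Series(rng.normal(size=n), index=universe)
            table = dr.bin_enrichment(dr.rank_and_bin(profile, 4), _annot(targets, universe))
            for _, row in table.iterrows():
                if row["method"] != "fisher":
                    continue
                k, c = int(row["observed_targets"]), int(row["gene_count"])
                pmf_obs = stats.hypergeom.pmf(k, n, t, c)
                total = sum(
                    stats.hypergeom.pmf(x, n, t, c)
                    for x in range(0, min(t, c) + 1)
                    if stats.hypergeom.pmf(x, n, t, c) <= pmf_obs * (1 + 1e-9)
                )
                assert row["p_value"] == pytest.approx(total, rel=1e-7)
                checked += 1
        assert checked > 10


class TestSelection:
    def _table(self, l2, p):
        return pd.DataFrame(
            {"log2_obs_exp": l2, "p_value": p}, index=pd.RangeIndex(1, len(l2) + 1, name="bin")
        )

    def test_fixed_paper_split(self):
        table = self._table([0.5] * 10, [0.5] * 10)
        assert dr.select_bins(table, "fixed_paper") == ([1, 2, 3, 4], [7, 8, 9, 10])

    def test_fixed_paper_requires_ten_bins(self):
        with pytest.raises(ValueError):
            dr.select_bins(self._table([0.1] * 7, [0.5] * 7), "fixed_paper")

    def test_adaptive_null_empty(self):
        table = self._table([0.01, -0.01] * 5, [0.9] * 10)
        with pytest.warns(UserWarning):
            top, bottom = dr.select_bins(table, "adaptive")
        assert top == [] and bottom == []

    def test_adaptive_prefix_suffix(self):
        l2 = [0.8, 0.5, 0.3, 0.0, 0.0, 0.0, 0.0, -0.1, -0.5, -0.9]
        p = [0.001, 0.01, 0.04, 0.9, 0.9, 0.9, 0.9, 0.2, 0.01, 0.001]
        assert dr.select_bins(self._table(l2, p), "adaptive") == ([1, 2, 3], [9, 10])


class TestConsensusAndDirectTargets:
    def _setup(self, genes_by_exp):
        universe = sorted(set().union(*[set(g) for g in genes_by_exp.values()]))
        assignments, selections = {}, {}
        for exp, top_genes in genes_by_exp.items():
            bins = pd.Series(
                [1 if g in top_genes else 2 for g in universe], index=universe
            )
            assignments[exp] = bins
            selections[exp] = ([1], [])
        return assignments, selections

    def test_intersection(self):
        assignments, selections = self._setup(
            {"e1": {"a", "b", "c"}, "e2": {"b", "c", "d"}}
        )
        cons = dr.consensus_sets(assignments, selections)
        assert cons.up_genes == {"b", "c"}

    def test_idempotence(self):
        assignments, selections = self._setup({"e1": {"a", "b"}, "e2": {"a", "b"}})
        cons = dr.consensus_sets(assignments, selections)
        assert cons.up_genes == {"a", "b"}

    def test_mismatched_universe_rejected(self):
        a1 = pd.Series([1, 2], index=["a", "b"])
        a2 = pd.Series([1, 2], index=["a", "c"])
        with pytest.raises(ValueError, match="2 gene"):
            dr.consensus_sets({"e1": a1, "e2": a2}, {"e1": ([1], []), "e2": ([1], [])})

    def test_direct_target_intersection_and_chi2(self):
        universe = [f"g{i}" for i in range(9403)]
        targets = set(universe[:945])
        up = set(universe[724:724 + 1765])  # 221 targets inside the up-set
        annot = _annot(targets, universe)
        cons = dr.ConsensusSets(up_genes=up, down_genes=set())
        res = dr.direct_targets(cons, annot)
        assert len(res.genes) == 221
        # independent oracle: hand Pearson on [[221, 724], [1544, 6914]]
        table = np.array([[221, 724], [1544, 6914]], float)
        exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2_hand = ((table - exp) ** 2 / exp).sum()
        assert res.chi2 == pytest.approx(chi2_hand, rel=1e-12)
        assert res.p_value == pytest.approx(stats.chi2.sf(chi2_hand, 1), rel=1e-9)

    def test_empty_consensus_flagged(self):
        universe = list("abcd")
        res = dr.direct_targets(
            dr.ConsensusSets(up_genes=set(), down_genes=set()), _annot({"a"}, universe)
        )
        assert res.genes == set() and not res.chi2_defined

    def test_targets_absent_from_universe_rejected(self):
        universe = list("abcd")
        with pytest.raises(ValueError):
            dr.direct_targets(
                dr.ConsensusSets(up_genes={"a"}, down_genes=set()), _annot(set(), universe)
            )


class TestEndToEndRecovery:
    def test_strong_planted_signal_recovered(self):
        cfg = SyntheticConfig(
            n_genes=1000, n_targets=100, target_shift=2.0, background_sd=0.1,
            n_experiments=4, seed=3,
        )
        profiles, annot, truth = simulate_derepression_profiles(cfg)
        assignments = {e: dr.rank_and_bin(p) for e, p in profiles.items()}
        selections = {
            e: dr.select_bins(dr.bin_enrichment(b, annot)) for e, b in assignments.items()
        }
        cons = dr.consensus_sets(assignments, selections)
        recovered = cons.up_genes & set(truth.target_gene_ids)
        assert len(recovered) >= 0.95 * len(truth.target_gene_ids)

    def test_monotone_in_planted_shift(self):
        # expected shift estimate and bin-1 enrichment both grow with the
        # planted effect (averaged over seeds)
        means = {}
        for shift in (0.0, 0.5):
            shifts, l2s = [], []
            for seed in range(30):
                cfg = SyntheticConfig(
                    n_genes=1500, n_targets=150, target_shift=shift,
                    n_experiments=1, seed=seed,
                )
                profiles, annot, _ = simulate_derepression_profiles(cfg)
                res = dr.global_shift(profiles["exp1"], annot, n_bootstrap=10, seed=seed)
                shifts.append(res.median_shift)
                table = dr.bin_enrichment(dr.rank_and_bin(profiles["exp1"]), annot)
                l2s.append(table.loc[1, "log2_obs_exp"])
            means[shift] = (np.mean(shifts), np.mean(l2s))
        assert means[0.5][0] > means[0.0][0]
        assert means[0.5][1] > means[0.0][1]

    def test_null_overlap_matches_hypergeometric_expectation(self):
        # with zero planted shift the direct-target count behaves like a
        # random overlap between the consensus up-set and the target list
        diffs = []
        for seed in range(150):
            cfg = SyntheticConfig(
                n_genes=500, n_targets=50, target_shift=0.0, n_experiments=2, seed=seed
            )
            profiles, annot, _ = simulate_derepression_profiles(cfg)
            assignments = {e: dr.rank_and_bin(p) for e, p in profiles.items()}
            selections = {e: ([1, 2, 3, 4], [7, 8, 9, 10]) for e in assignments}
            cons = dr.consensus_sets(assignments, selections)
            res = dr.direct_targets(cons, annot)
            expected = len(cons.up_genes) * 50 / 500
            diffs.append(len(res.genes) - expected)
        # mean deviation from the conditional expectation ~ 0 within 3 SEM
        sem = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * sem + 0.05
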
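"""Detection of de-repressed direct miRNA targets from fold-change profiles.

The inference pursued here is tuned for the weak transcriptional footprint
of miRNA loss-of-function: predicted targets shift up only slightly
(~ +0.1 log2) after removing the repressing miRNA, so individual genes
rarely clear conventional fold-change cutoffs.  Instead the analysis

1. measures the global shift of predicted targets versus all other genes
   (median difference, bootstrap SEM, rank-sum p),
2. ranks every profile from most up- to most down-regulated and splits it
   into equal-count bins (default 10),
3. scores per-bin target enrichment as log2(observed/expected) with a
   contingency p-value,
4. selects enriched top bins and depleted bottom bins,
5. intersects the selected bins across independent experiments
   (consensus up-/down-regulated sets), and
6. intersects the consensus up-set with the predicted targets to call
   high-confidence direct targets, with a chi-square test against
   independence.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .profiling import overlap_test

__all__ = [
    "make_annotation",
    "global_shift",
    "ShiftResult",
    "rank_and_bin",
    "bin_enrichment",
    "select_bins",
    "consensus_sets",
    "ConsensusSets",
    "direct_targets",
    "DirectTargetSet",
]

DEFAULT_CONTEXT_THRESHOLD = -0.15


def make_annotation(
    scores: pd.Series, threshold: float = DEFAULT_CONTEXT_THRESHOLD
) -> pd.DataFrame:
    """Build a target annotation from context scores.

    A gene is a predicted target iff its context score is present and
    strictly below ``threshold`` (more negative = stronger predicted
    repression).  Genes missing from ``scores`` are non-targets.
    """
    annot = pd.DataFrame({"context_score": scores.astype(float)})
    annot["is_predicted_target"] = annot["context_score"].notna() & (
        annot["context_score"] < threshold
    )
    annot.index.name = "gene_id"
    return annot


def _target_mask(profile: pd.Series, annot: pd.DataFrame) -> np.ndarray:
    missing = profile.index.difference(annot.index)
    if len(missing):
        raise ValueError(f"{len(missing)} profile gene(s) missing from annotation")
    return annot.loc[profile.index, "is_predicted_target"].to_numpy(dtype=bool)


@dataclass
class ShiftResult:
    """Global de-repression shift of targets over the background."""

    median_shift: float  # median(log2FC | targets) - median(log2FC | others)
    sem: float  # bootstrap SEM of the median difference
    wilcoxon_p: float  # two-sided Mann-Whitney rank-sum p
    n_targets: int
    n_others: int


def global_shift(
    profile: pd.Series,
    annot: pd.DataFrame,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> ShiftResult:
    """Median log2FC shift of predicted targets versus non-targets.

    The SEM comes from a seeded bootstrap of the median difference; the
    p-value from a two-sided Mann-Whitney (Wilcoxon rank-sum) test.
    """
    mask = _target_mask(profile, annot)
    t = profile.to_numpy(dtype=float)[mask]
    o = profile.to_numpy(dtype=float)[~mask]
    if len(t) < 2 or len(o) < 2:
        raise ValueError("need at least 2 targets and 2 non-targets")
    shift = float(np.median(t) - np.median(o))
    rng = np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    for i in range(n_bootstrap):
        bt = rng.choice(t, size=len(t), replace=True)
        bo = rng.choice(o, size=len(o), replace=True)
        boots[i] = np.median(bt) - np.median(bo)
    p = float(stats.mannwhitneyu(t, o, alternative="two-sided").pvalue)
    return ShiftResult(
        median_shift=shift,
        sem=float(boots.std(ddof=1)),
        wilcoxon_p=p,
        n_targets=len(t),
        n_others=len(o),
    )


def rank_and_bin(profile: pd.Series, n_bins: int = 10) -> pd.Series:
    """Partition genes into equal-count bins ranked by log2FC.

    Bin 1 holds the most up-regulated genes.  Fold-change ties are broken
    by gene id (lexicographic) so the partition is deterministic.  Bin
    sizes are floor(N / n_bins), with the N mod n_bins remainder genes
    distributed one each to the lowest-index bins; the partition is exact
    and total.
    """
    n = len(profile)
    if n < n_bins:
        raise ValueError(f"universe size {n} < n_bins {n_bins}")
    if not np.isfinite(profile.to_numpy(dtype=float)).all():
        raise ValueError("log2fc values must all be finite")
    df = profile.rename("log2fc").rename_axis("gene_id").reset_index()
    df = df.sort_values(["log2fc", "gene_id"], ascending=[False, True], kind="mergesort")
    base, rem = divmod(n, n_bins)
    sizes = [base + 1 if b < rem else base for b in range(n_bins)]
    bins = np.repeat(np.arange(1, n_bins + 1), sizes)
    out = pd.Series(bins, index=df["gene_id"], name="bin")
    return out.loc[profile.index]  # restore caller's gene order


def bin_enrichment(bins: pd.Series, annot: pd.DataFrame) -> pd.DataFrame:
    """Per-bin enrichment of predicted targets, observed versus expected.

    For each bin, expected = gene_count * total_targets / N, and the
    reported effect is log2((observed + eps) / (expected + eps)) where a
    pseudo-count eps = 0.5 is applied only when observed = 0 (keeping the
    log finite).  The Pearson chi-square statistic is always reported for
    the 2x2 (in-bin vs rest) x (target vs non-target) table; the p-value
    switches to Fisher's exact test whenever any expected cell is < 5.
    """
    mask = annot.loc[bins.index, "is_predicted_target"].to_numpy(dtype=bool)
    n = len(bins)
    total_targets = int(mask.sum())
    if total_targets == 0:
        raise ValueError("annotation contains no predicted targets in the universe")

    rows = []
    for b in sorted(bins.unique()):
        in_bin = (bins == b).to_numpy()
        count = int(in_bin.sum())
        obs = int((in_bin & mask).sum())
        exp = count * total_targets / n
        eps = 0.5 if obs == 0 else 0.0
        l2 = float(np.log2((obs + eps) / (exp + eps)))
        table = np.array(
            [
                [obs, count - obs],
                [total_targets - obs, (n - count) - (total_targets - obs)],
            ]
        )
        expected_cells = np.outer(table.sum(1), table.sum(0)) / n
        chi2 = float(((table - expected_cells) ** 2 / expected_cells).sum())
        if (expected_cells < 5).any():
            p = float(stats.fisher_exact(table)[1])
            method = "fisher"
        else:
            p = float(stats.chi2.sf(chi2, df=1))
            method = "chi2"
        rows.append((b, count, obs, exp, l2, chi2, p, method))
    return pd.DataFrame(
        rows,
        columns=[
            "bin",
            "gene_count",
            "observed_targets",
            "expected_targets",
            "log2_obs_exp",
            "chi2",
            "p_value",
            "method",
        ],
    ).set_index("bin")


def select_bins(
    table: pd.DataFrame,
    mode: str = "fixed_paper",
    p_threshold: float = 0.05,
) -> tuple[list[int], list[int]]:
    """Choose enriched top bins and depleted bottom bins.

    ``fixed_paper`` returns the canonical (1-4, 7-10) split of a 10-bin
    table.  ``adaptive`` returns the maximal prefix of bins with
    log2_obs_exp > 0 and p < ``p_threshold``, and the maximal suffix with
    log2_obs_exp < 0 and p < ``p_threshold``; both may be empty (with a
    warning).
    """
    bins = list(table.index)
    if mode == "fixed_paper":
        if len(bins) != 10:
            raise ValueError("fixed_paper selection requires a 10-bin table")
        return [1, 2, 3, 4], [7, 8, 9, 10]
    if mode != "adaptive":
        raise ValueError(f"unknown selection mode {mode!r}")
    top: list[int] = []
    for b in bins:
        row = table.loc[b]
        if row["log2_obs_exp"] > 0 and row["p_value"] < p_threshold:
            top.append(b)
        else:
            break
    bottom: list[int] = []
    for b in reversed(bins):
        row = table.loc[b]
        if row["log2_obs_exp"] < 0 and row["p_value"] < p_threshold:
            bottom.append(b)
        else:
            break
    bottom.reverse()
    if not top and not bottom:
        warnings.warn("adaptive selection found no qualifying bins", stacklevel=2)
    return top, bottom


@dataclass
class ConsensusSets:
    """Genes consistently up-/down-ranked across all experiments."""

    up_genes: set
    down_genes: set
    pairwise_up_p: dict = field(default_factory=dict)
    pairwise_down_p: dict = field(default_factory=dict)


def consensus_sets(
    assignments: dict[str, pd.Series],
    selections: dict[str, tuple[list[int], list[int]]],
) -> ConsensusSets:
    """Intersect selected top/bottom bins across experiments.

    ``up_genes`` is the strict intersection over all experiments of the
    genes in each experiment's selected top bins; ``down_genes`` likewise
    for bottom bins.  Pairwise overlap significance (one-sided Fisher on
    the shared universe) is reported for each experiment pair.
    """
    if len(assignments) < 2:
        raise ValueError("need >= 2 experiments for a consensus")
    exp_ids = list(assignments)
    universe = set(assignments[exp_ids[0]].index)
    for e in exp_ids[1:]:
        other = set(assignments[e].index)
        if other != universe:
            raise ValueError(
                f"experiment {e!r} universe differs by "
                f"{len(other.symmetric_difference(universe))} gene(s)"
            )

    top_sets, bottom_sets = {}, {}
    for e in exp_ids:
        bins = assignments[e]
        top, bottom = selections[e]
        top_sets[e] = set(bins.index[bins.isin(top)])
        bottom_sets[e] = set(bins.index[bins.isin(bottom)])

    up = set.intersection(*top_sets.values()) if all(top_sets.values()) else set()
    down = set.intersection(*bottom_sets.values()) if all(bottom_sets.values()) else set()
    # A gene cannot be in both a top and bottom bin within one experiment,
    # so the intersections are disjoint by construction.

    pair_up, pair_down = {}, {}
    for e1, e2 in itertools.combinations(exp_ids, 2):
        if top_sets[e1] and top_sets[e2]:
            pair_up[(e1, e2)] = overlap_test(top_sets[e1], top_sets[e2], universe).p_value
        if bottom_sets[e1] and bottom_sets[e2]:
            pair_down[(e1, e2)] = overlap_test(
                bottom_sets[e1], bottom_sets[e2], universe
            ).p_value
    return ConsensusSets(
        up_genes=up, down_genes=down, pairwise_up_p=pair_up, pairwise_down_p=pair_down
    )


@dataclass
class DirectTargetSet:
    """Predicted targets consistently up-regulated across experiments."""

    genes: set
    chi2: float | None
    p_value: float | None
    n_consensus_up: int
    n_targets: int
    universe_size: int
    chi2_defined: bool = True


def direct_targets(consensus: ConsensusSets, annot: pd.DataFrame) -> DirectTargetSet:
    """Intersect the consensus up-set with predicted targets.

    The association test is the Pearson chi-square (df = 1) on the 2x2
    table of target status x consensus-up membership over the full
    annotated universe.
    """
    targets = set(annot.index[annot["is_predicted_target"]])
    universe = set(annot.index)
    if not targets:
        raise ValueError("no predicted targets in the annotated universe")
    up = consensus.up_genes
    if not up <= universe:
        raise ValueError("consensus up-set contains genes outside the universe")
    genes = up & targets
    if not up:
        return DirectTargetSet(
            genes=set(),
            chi2=None,
            p_value=None,
            n_consensus_up=0,
            n_targets=len(targets),
            universe_size=len(universe),
            chi2_defined=False,
        )
    n = len(universe)
    a = len(genes)  # target & up
    b = len(targets) - a  # target & not up
    c = len(up) - a  # non-target & up
    d = n - a - b - c
    table = np.array([[a, b], [c, d]], dtype=float)
    expected = np.outer(table.sum(1), table.sum(0)) / n
    chi2 = float(((table - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return DirectTargetSet(
        genes=genes,
        chi2=chi2,
        p_value=p,
        n_consensus_up=len(up),
        n_targets=len(targets),
        universe_size=n,
    )
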
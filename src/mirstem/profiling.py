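"""Ct-level qPCR miRNA analysis.

Detection filtering, housekeeping-median normalization, differential miRNA
calling on replicate dCt values, set-overlap testing, and the small protocol
arithmetic helpers (composite dilution factors, Ago2-RIP loading fraction).

Conventions
-----------
* A Ct value is kept only if present and strictly below the detection
  ceiling (default 28 cycles); equality is excluded.
* dCt = Ct - median(housekeeping Cts of the same sample); relative
  expression = 2**(-dCt), so lower dCt means higher expression.
* log2FC(A vs B) = mean(dCt, group B) - mean(dCt, group A): positive values
  mean higher expression in group A.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationError",
    "filter_detected",
    "normalize_expression",
    "differential_mirnas",
    "DifferentialResult",
    "overlap_test",
    "OverlapResult",
    "composite_dilution_factor",
    "rip_loading_fraction",
]

CT_COLUMNS = ["assay_id", "sample_id", "group", "replicate", "ct", "is_housekeeping"]


class NormalizationError(ValueError):
    """Raised when a sample has no detected housekeeping assay."""


def filter_detected(ct: pd.DataFrame, detection_ceiling: float = 28.0) -> pd.DataFrame:
    """Drop undetected measurements and assays unmeasurable in some group.

    Rows with missing Ct or Ct >= ``detection_ceiling`` are removed.  A
    non-housekeeping assay that then has no surviving measurement in one of
    the groups present in the input is dropped entirely (it cannot enter a
    fold-change comparison).  An empty result is returned with a warning,
    never an exception.
    """
    ct = ct.copy()
    detected = ct["ct"].notna() & (ct["ct"] < detection_ceiling)
    out = ct.loc[detected]

    groups = ct["group"].unique()
    dropped = []
    for assay, sub in out[~out["is_housekeeping"]].groupby("assay_id"):
        if set(sub["group"].unique()) != set(groups):
            dropped.append(assay)
    if dropped:
        out = out[~out["assay_id"].isin(dropped)]
        logger.info("filter_detected: dropped %d assays absent in a group", len(dropped))
    n_removed = len(ct) - len(out)
    logger.info("filter_detected: removed %d/%d rows", n_removed, len(ct))
    if out.empty:
        warnings.warn("detection filter removed every measurement", stacklevel=2)
    return out.reset_index(drop=True)


def normalize_expression(ct: pd.DataFrame) -> pd.DataFrame:
    """Normalize Cts over the per-sample median of housekeeping controls.

    Returns the non-housekeeping rows with ``delta_ct`` and
    ``rel_expr = 2**(-delta_ct)`` columns added.

    Raises
    ------
    NormalizationError
        naming the sample, if a sample has no detected housekeeping assay.
    """
    hk = ct[ct["is_housekeeping"]]
    hk_median = hk.groupby("sample_id")["ct"].median()
    samples = ct["sample_id"].unique()
    missing = [s for s in samples if s not in hk_median.index]
    if missing:
        raise NormalizationError(
            f"no detected housekeeping assay for sample(s): {', '.join(map(str, missing))}"
        )
    out = ct[~ct["is_housekeeping"]].copy()
    out["delta_ct"] = out["ct"].to_numpy() - hk_median.loc[out["sample_id"]].to_numpy()
    out["rel_expr"] = np.exp2(-out["delta_ct"])
    return out.reset_index(drop=True)


@dataclass
class DifferentialResult:
    """Per-assay differential statistics plus the thresholds used."""

    table: pd.DataFrame  # assay_id, log2fc, p_value, direction, regulated
    group_a: str
    group_b: str
    fc_threshold: float
    p_threshold: float
    test: str = "welch"
    skipped_assays: list = field(default_factory=list)

    @property
    def regulated(self) -> pd.DataFrame:
        return self.table[self.table["regulated"]]

    def regulated_ids(self) -> set:
        return set(self.regulated["assay_id"])


def differential_mirnas(
    norm: pd.DataFrame,
    group_a: str,
    group_b: str,
    fc_threshold: float = 0.5,
    p_threshold: float = 0.05,
    fdr: bool = False,
) -> DifferentialResult:
    """Call regulated miRNAs between two groups from normalized dCt values.

    Per assay, log2FC = mean(dCt in ``group_b``) - mean(dCt in ``group_a``)
    and the p-value comes from a two-sided Welch t-test on the replicate
    dCt values.  Membership in the regulated set requires strictly
    |log2FC| > ``fc_threshold`` and p < ``p_threshold`` (on raw p by
    default; set ``fdr`` for Benjamini-Hochberg adjusted calling).
    Assays with fewer than two replicates in either group are skipped with
    a warning.
    """
    rows = []
    skipped = []
    for assay, sub in norm.groupby("assay_id", sort=True):
        a = sub.loc[sub["group"] == group_a, "delta_ct"].to_numpy()
        b = sub.loc[sub["group"] == group_b, "delta_ct"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            skipped.append(assay)
            continue
        log2fc = float(b.mean() - a.mean())
        if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
            p = 1.0  # identical constant groups: no evidence of change
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        rows.append((assay, log2fc, p, "up" if log2fc > 0 else "down"))
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} assay(s) with <2 replicates per group", stacklevel=2
        )
    table = pd.DataFrame(rows, columns=["assay_id", "log2fc", "p_value", "direction"])
    if fdr and len(table):
        from statsmodels.stats.multitest import multipletests

        table["p_adj"] = multipletests(table["p_value"], method="fdr_bh")[1]
        crit = table["p_adj"]
    else:
        crit = table["p_value"] if len(table) else pd.Series(dtype=float)
    table["regulated"] = (table["log2fc"].abs() > fc_threshold) & (crit < p_threshold)
    return DifferentialResult(
        table=table,
        group_a=group_a,
        group_b=group_b,
        fc_threshold=fc_threshold,
        p_threshold=p_threshold,
        skipped_assays=skipped,
    )


@dataclass
class OverlapResult:
    overlap_count: int
    size_a: int
    size_b: int
    universe_size: int
    p_value: float


def overlap_test(set_a: Iterable, set_b: Iterable, universe: Iterable) -> OverlapResult:
    """One-sided (enrichment) Fisher's exact test for a set overlap.

    Under the hypergeometric null, reports P(X >= observed overlap) for two
    sets drawn from a shared universe.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    a, b = set(set_a), set(set_b)
    if not a <= universe or not b <= universe:
        raise ValueError("both sets must be subsets of the universe")
    k = len(a & b)
    n = len(universe)
    table = [[k, len(a) - k], [len(b) - k, n - len(a) - len(b) + k]]
    p = float(stats.fisher_exact(table, alternative="greater")[1])
    return OverlapResult(k, len(a), len(b), n, p)


def composite_dilution_factor(steps: Sequence[float]) -> float:
    """Product of serial dilution factors; the empty protocol dilutes 1x.

    E.g. a 1:4 post-preamplification dilution followed by a 1:20 PCR
    dilution gives a composite factor of 80.
    """
    factor = 1.0
    for s in steps:
        if s < 1:
            raise ValueError(f"dilution step {s} must be >= 1")
        factor *= float(s)
    return factor


def rip_loading_fraction(
    rip_copies: float, input_copies: float, input_fraction: float = 0.05
) -> float:
    """Percentage of total copies recovered in a RIP eluate.

    ``input_copies`` were measured on ``input_fraction`` of the lysate, so
    the total is input/fraction and the loading percentage is
    100 * rip / total.
    """
    if input_copies <= 0:
        raise ValueError("input_copies must be > 0")
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must be in (0, 1]")
    total = input_copies / input_fraction
    return 100.0 * rip_copies / total
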
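"""Synthetic data generators with planted ground truth.

Every pipeline input (Ct matrices, fold-change profiles, cohort expression
matrices, limiting-dilution take tables, dose-response curves) can be
generated here with a known planted signal, so each downstream estimator is
testable without any external download.

Noise families are the minimal ones the downstream statistics assume:
Normal for Ct, log2 fold-change and viability noise; Bernoulli/binomial for
limiting-dilution takes.  A single global seed is expanded into fixed
per-generator substreams, so adding a new generator never perturbs the
streams of existing ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "PlantedTruth",
    "simulate_derepression_profiles",
    "simulate_ct_experiment",
    "simulate_cohort",
    "simulate_ld_assay",
    "simulate_dose_response",
]

# Fixed substream offsets: the global seed is combined with one of these so
# that each generator draws from an independent, reproducible stream.
_STREAMS = {
    "derepression": 11,
    "ct": 23,
    "cohort": 37,
    "ld": 51,
    "dose": 67,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    # spawn_key-based substreams keep the seed ensemble well mixed; seeding
    # with a [seed, offset] entropy list instead leaves measurable
    # correlation across sequential seeds.
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    return np.random.default_rng(ss)


@dataclass
class SyntheticConfig:
    """Study-scale defaults for the fold-change and qPCR generators.

    The defaults mirror the scale of the source study: ~11,000 expressed
    genes, 945 predicted targets with a small (+0.10 log2) median
    de-repression over a null background, four independent expression
    profiles, and TaqMan-style Ct measurements with a detection ceiling of
    28 cycles.
    """

    n_genes: int = 11_000
    n_targets: int = 945
    target_shift: float = 0.10
    background_sd: float = 0.5
    n_experiments: int = 4
    ct_mean_hk: float = 20.0
    ct_tech_sd: float = 0.25
    detection_ceiling: float = 28.0
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        if self.n_targets > self.n_genes:
            raise ValueError(
                f"n_targets ({self.n_targets}) cannot exceed n_genes ({self.n_genes})"
            )
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.background_sd <= 0:
            raise ValueError("background_sd must be > 0")
        if self.ct_tech_sd < 0:
            raise ValueError("ct_tech_sd must be >= 0")
        if self.n_experiments < 1:
            raise ValueError("n_experiments must be >= 1")
        return self


@dataclass
class PlantedTruth:
    """Ground truth planted by a generator, serializable as a JSON sidecar."""

    target_gene_ids: list[str] | None = None
    true_shift: float | None = None
    regulated_assays: dict[str, float] | None = None
    true_frequency: float | None = None
    true_4pl: tuple[float, float, float, float] | None = None
    true_cluster_labels: list[int] | None = None

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=1, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _gene_ids(n: int) -> np.ndarray:
    width = max(5, len(str(n)))
    return np.array([f"g{i:0{width}d}" for i in range(1, n + 1)])


def simulate_derepression_profiles(
    config: SyntheticConfig,
) -> tuple[dict[str, pd.Series], pd.DataFrame, PlantedTruth]:
    """Generate per-experiment log2 fold-change profiles with planted targets.

    Non-target genes draw log2FC ~ Normal(0, background_sd); a designated
    subset of ``n_targets`` genes draws from the same distribution shifted
    by ``target_shift`` (de-repression upon miRNA loss).  The annotation
    assigns each planted target a context score uniform in [-0.60, -0.15),
    i.e. below the prediction threshold; non-targets carry no score.

    Returns
    -------
    profiles : dict mapping experiment id -> pd.Series (gene_id -> log2fc)
    annotation : DataFrame indexed by gene_id with columns
        ``context_score`` (NaN for non-targets) and ``is_predicted_target``
    truth : PlantedTruth
    """
    config.validate()
    rng = _rng(config.seed, "derepression")
    genes = _gene_ids(config.n_genes)
    target_idx = rng.choice(config.n_genes, size=config.n_targets, replace=False)
    is_target = np.zeros(config.n_genes, dtype=bool)
    is_target[target_idx] = True

    profiles: dict[str, pd.Series] = {}
    for e in range(1, config.n_experiments + 1):
        fc = rng.normal(0.0, config.background_sd, size=config.n_genes)
        fc[is_target] += config.target_shift
        profiles[f"exp{e}"] = pd.Series(fc, index=genes, name="log2fc")

    scores = np.full(config.n_genes, np.nan)
    scores[is_target] = rng.uniform(-0.60, -0.15, size=config.n_targets)
    annotation = pd.DataFrame(
        {"context_score": scores, "is_predicted_target": is_target}, index=genes
    )
    annotation.index.name = "gene_id"

    truth = PlantedTruth(
        target_gene_ids=sorted(genes[is_target].tolist()),
        true_shift=config.target_shift,
    )
    return profiles, annotation, truth


def simulate_ct_experiment(
    config: SyntheticConfig,
    n_assays: int = 40,
    n_regulated: int = 5,
    regulated_shift: float = 1.0,
    groups: tuple[str, str] = ("pos", "neg"),
    n_replicates: int = 3,
    n_housekeeping: int = 3,
    dropout_fraction: float = 0.0,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Generate a long-format qPCR Ct table with planted regulated assays.

    Each group contributes ``n_replicates`` biological samples measured on
    every assay.  Housekeeping assays sit at ``ct_mean_hk`` in both groups;
    non-regulated assays share a group-independent mean; regulated assays
    differ by ``regulated_shift`` cycles between groups (alternating sign),
    so the planted |log2FC| equals the shift in cycles.  A
    ``dropout_fraction`` of the measured (non-housekeeping) assays is pushed
    above the detection ceiling in every sample, emulating failed
    amplification.
    """
    config.validate()
    if len(set(groups)) != 2:
        raise ValueError("groups must be exactly two distinct labels")
    if n_regulated > n_assays:
        raise ValueError("n_regulated cannot exceed n_assays")
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    if not 0.0 <= dropout_fraction <= 1.0:
        raise ValueError("dropout_fraction must be in [0, 1]")

    rng = _rng(config.seed, "ct")
    assay_ids = [f"mir{i:03d}" for i in range(1, n_assays + 1)]
    hk_ids = [f"hk{i}" for i in range(1, n_housekeeping + 1)]

    # Baseline means comfortably inside the detection window.
    base_mean = rng.uniform(config.ct_mean_hk + 1.0, config.detection_ceiling - 2.0, n_assays)
    regulated = rng.choice(n_assays, size=n_regulated, replace=False)
    # Alternate direction of regulation across the planted assays.
    shift = np.zeros(n_assays)
    signs = np.where(np.arange(n_regulated) % 2 == 0, -1.0, 1.0)
    shift[regulated] = signs * regulated_shift

    n_drop = int(round(dropout_fraction * n_assays))
    dropped = set(rng.choice(n_assays, size=n_drop, replace=False).tolist())

    rows = []
    for g_idx, group in enumerate(groups):
        for rep in range(1, n_replicates + 1):
            sample = f"{group}_{rep}"
            for j, hk in enumerate(hk_ids):
                ct = rng.normal(config.ct_mean_hk, config.ct_tech_sd)
                rows.append((hk, sample, group, rep, ct, True))
            for i, assay in enumerate(assay_ids):
                mean = base_mean[i]
                # Convention: the planted shift lowers Ct in the second group
                # (lower Ct = higher expression there).
                if g_idx == 1:
                    mean = mean + shift[i]
                ct = rng.normal(mean, config.ct_tech_sd)
                if i in dropped:
                    ct = config.detection_ceiling + 2.0 + abs(rng.normal(0, 1))
                rows.append((assay, sample, group, rep, ct, False))

    table = pd.DataFrame(
        rows,
        columns=["assay_id", "sample_id", "group", "replicate", "ct", "is_housekeeping"],
    )
    # Planted log2FC(group_a vs group_b) = mean dCt(b) - mean dCt(a); the
    # second group's Ct mean is base + shift, so the planted value is shift.
    planted = {assay_ids[i]: float(shift[i]) for i in regulated}
    truth = PlantedTruth(regulated_assays=planted, true_shift=regulated_shift)
    return table, truth


def simulate_cohort(
    n_samples: int,
    n_features: int,
    n_clusters: int,
    separation: float,
    annotation_association: float,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, PlantedTruth]:
    """Generate a samples x features cohort matrix with cluster structure.

    Features are assigned round-robin to a "driver" cluster; a sample from
    cluster c has mean ``separation`` on features driven by c and 0
    elsewhere, unit noise throughout.  One categorical annotation matches
    the true cluster with probability ``annotation_association`` and is a
    random other category otherwise.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if n_samples < n_clusters:
        raise ValueError("need at least one sample per cluster")
    if not 0.0 <= annotation_association <= 1.0:
        raise ValueError("annotation_association must be a probability")

    rng = _rng(seed, "cohort")
    labels = np.arange(n_samples) % n_clusters  # balanced assignment
    rng.shuffle(labels)
    driver = np.arange(n_features) % n_clusters

    means = np.where(driver[None, :] == labels[:, None], float(separation), 0.0)
    values = means + rng.normal(0.0, 1.0, size=(n_samples, n_features))

    sample_ids = [f"s{i:04d}" for i in range(1, n_samples + 1)]
    feature_ids = [f"f{j:03d}" for j in range(1, n_features + 1)]
    matrix = pd.DataFrame(values, index=sample_ids, columns=feature_ids)

    categories = [f"cat{c}" for c in range(n_clusters)]
    annot = []
    for lab in labels:
        if rng.uniform() < annotation_association:
            annot.append(categories[lab])
        else:
            others = [c for c in range(n_clusters) if c != lab]
            annot.append(categories[rng.choice(others)])
    annotation = pd.Series(annot, index=sample_ids, name="annotation")

    truth = PlantedTruth(true_cluster_labels=labels.tolist())
    return matrix, annotation, truth


def simulate_ld_assay(
    frequency: float,
    doses: Sequence[int],
    n_per_dose: int,
    seed: int = 0,
    group: str = "group",
) -> pd.DataFrame:
    """Draw a limiting-dilution take table from the single-hit model.

    Each injection of ``d`` cells responds independently with probability
    1 - exp(-frequency * d).
    """
    if frequency < 0:
        raise ValueError("frequency must be >= 0")
    doses = [int(d) for d in doses]
    if any(d <= 0 for d in doses):
        raise ValueError("doses must be positive integers")
    if n_per_dose < 1:
        raise ValueError("n_per_dose must be >= 1")

    rng = _rng(seed, "ld")
    rows = []
    for d in doses:
        p = 1.0 - np.exp(-frequency * d)
        k = int(rng.binomial(n_per_dose, p))
        rows.append((group, d, n_per_dose, k))
    return pd.DataFrame(rows, columns=["group", "dose", "n_tested", "n_responded"])


def four_pl(x, top: float, bottom: float, ic50: float, hill: float):
    """Four-parameter logistic inhibition curve, decreasing in x for hill > 0."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (x / ic50) ** hill)


def simulate_dose_response(
    params: tuple[float, float, float, float],
    concentrations: Sequence[float],
    noise_sd: float,
    n_replicates: int,
    seed: int = 0,
    group: str = "group",
) -> pd.DataFrame:
    """Generate replicate viability measurements on a 4PL curve plus noise.

    ``params`` is (top, bottom, ic50, hill) with ic50 in the same units as
    ``concentrations`` (nM throughout the package).
    """
    top, bottom, ic50, hill = params
    concentrations = np.asarray(list(concentrations), dtype=float)
    if np.any(concentrations <= 0):
        raise ValueError("concentrations must be positive")
    if hill == 0:
        raise ValueError("hill slope must be nonzero")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    rng = _rng(seed, "dose")
    rows = []
    for c in concentrations:
        mu = four_pl(c, top, bottom, ic50, hill)
        for rep in range(1, n_replicates + 1):
            y = float(mu + rng.normal(0.0, noise_sd))
            rows.append((group, float(c), y, rep))
    return pd.DataFrame(rows, columns=["group", "concentration_nM", "viability", "replicate"])
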
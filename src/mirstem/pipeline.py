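"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes the requested stages in dependency order
(simulate feeds derepress when no external profiles are given), writes
every stage table under the output directory, and collects a JSON summary
with all materialized parameters, key statistics and per-file SHA-256
checksums, so identical (config, inputs, seed) runs are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import derepression as dr
from . import dose_response as dose_mod
from . import limiting_dilution as ld
from . import profiling, stratify, synthetic
from .config import RunConfig
from .tables import read_table, write_table

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "StageError"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_simulate(cfg: RunConfig, out: Path, summary: dict) -> dict:
    sec = cfg["simulate"]
    config = synthetic.SyntheticConfig(
        n_genes=sec["n_genes"], n_targets=sec["n_targets"],
        target_shift=sec["target_shift"], background_sd=sec["background_sd"],
        n_experiments=sec["n_experiments"], ct_mean_hk=sec["ct_mean_hk"],
        ct_tech_sd=sec["ct_tech_sd"], detection_ceiling=sec["detection_ceiling"],
        seed=cfg.seed,
    )
    profiles, annot, truth = synthetic.simulate_derepression_profiles(config)
    artifacts = {}
    for exp, series in profiles.items():
        path = out / f"profile_{exp}.tsv"
        write_table(series.rename("log2fc").rename_axis("gene_id").reset_index(), path)
        artifacts[exp] = path
    targets_path = out / "targets.tsv"
    write_table(annot.reset_index()[["gene_id", "context_score"]], targets_path)
    truth.to_json(out / "planted_truth.json")
    summary["simulate"] = {"params": sec, "n_profiles": len(profiles)}
    return {"profiles": profiles, "annotation": annot,
            "profile_paths": artifacts, "targets_path": targets_path}


def _stage_derepress(cfg: RunConfig, out: Path, summary: dict, sim: dict | None):
    sec = cfg["derepress"]
    if sec["profile_paths"] is not None:
        profiles = {}
        for p in sec["profile_paths"]:
            df = read_table(p, "profile")
            profiles[Path(p).stem] = df.set_index("gene_id")["log2fc"]
        targets = read_table(sec["targets_path"], "targets")
        annot = dr.make_annotation(
            targets.set_index("gene_id")["context_score"], sec["context_threshold"]
        )
    elif sim is not None:
        profiles, annot = sim["profiles"], sim["annotation"]
    else:
        raise ValueError("derepress needs profile_paths or a simulate stage upstream")

    shifts = {}
    assignments = {}
    selections = {}
    for exp, profile in profiles.items():
        shift = dr.global_shift(profile, annot, n_bootstrap=sec["n_bootstrap"],
                                seed=cfg.seed or 0)
        shifts[exp] = shift
        bins = dr.rank_and_bin(profile, n_bins=sec["n_bins"])
        table = dr.bin_enrichment(bins, annot)
        write_table(table.reset_index(), out / f"bins_{exp}.tsv")
        assignments[exp] = bins
        selections[exp] = dr.select_bins(table, mode=sec["select"])
    consensus = dr.consensus_sets(assignments, selections)
    direct = dr.direct_targets(consensus, annot)

    for name, genes in (("consensus_up.grp", consensus.up_genes),
                        ("consensus_down.grp", consensus.down_genes),
                        ("direct_targets.grp", direct.genes)):
        (out / name).write_text("\n".join(sorted(genes)) + "\n")

    summary["derepress"] = {
        "params": {k: v for k, v in sec.items() if k != "profile_paths"},
        "median_shift": {e: s.median_shift for e, s in shifts.items()},
        "shift_sem": {e: s.sem for e, s in shifts.items()},
        "wilcoxon_p": {e: s.wilcoxon_p for e, s in shifts.items()},
        "n_consensus_up": len(consensus.up_genes),
        "n_consensus_down": len(consensus.down_genes),
        "n_direct_targets": len(direct.genes),
        "direct_chi2": direct.chi2,
        "direct_p": direct.p_value,
    }
    return direct


def _stage_profile(cfg: RunConfig, out: Path, summary: dict):
    sec = cfg["profile"]
    ct = read_table(sec["ct_path"], "ct")
    detected = profiling.filter_detected(ct, sec["detection_ceiling"])
    norm = profiling.normalize_expression(detected)
    result = profiling.differential_mirnas(
        norm, sec["group_a"], sec["group_b"],
        fc_threshold=sec["fc_threshold"], p_threshold=sec["p_threshold"],
        fdr=sec["fdr"],
    )
    write_table(result.table, out / "differential_mirnas.tsv")
    summary["profile"] = {
        "params": {k: v for k, v in sec.items() if k != "ct_path"},
        "test": result.test,
        "n_assays_tested": len(result.table),
        "n_regulated": int(result.table["regulated"].sum()),
        "skipped": result.skipped_assays,
    }
    return result


def _stage_stratify(cfg: RunConfig, out: Path, summary: dict):
    sec = cfg["stratify"]
    matrix = pd.read_csv(sec["matrix_path"], sep="\t", index_col=0)
    annot = pd.read_csv(sec["annot_path"], sep="\t", index_col=0).iloc[:, 0]
    std = stratify.standardize_matrix(matrix, log_transform=sec["log_transform"])
    assign = stratify.ward_cluster(std, sec["k"])
    report = stratify.cluster_annotation_enrichment(assign, annot)
    write_table(assign.labels.rename_axis("sample_id").reset_index(),
                out / "clusters.tsv")
    report.counts.to_csv(out / "contingency.tsv", sep="\t")
    (out / "dendrogram.nwk").write_text(assign.to_newick() + "\n")
    summary["stratify"] = {
        "params": {k: v for k, v in sec.items()
                   if k not in ("matrix_path", "annot_path")},
        "chi2": report.chi2, "dof": report.dof, "p_value": report.p_value,
    }
    return report


def _stage_ldassay(cfg: RunConfig, out: Path, summary: dict):
    sec = cfg["ldassay"]
    table = read_table(sec["table_path"], "ld")
    estimates = {}
    rows = []
    for group, sub in table.groupby("group"):
        est = ld.estimate_frequency(sub, ci_method=sec["ci_method"])
        estimates[group] = est
        rows.append((group, est.frequency, est.one_in, est.ci_lower,
                     est.ci_upper, est.boundary_flag))
    write_table(pd.DataFrame(rows, columns=["group", "frequency", "one_in",
                                            "ci_lower", "ci_upper", "boundary"]),
                out / "ld_estimates.tsv")
    comparison = None
    if sec["compare"]:
        ga, gb = sec["compare"]
        comparison = ld.compare_frequencies(table[table["group"] == ga],
                                            table[table["group"] == gb])
    summary["ldassay"] = {
        "params": {k: v for k, v in sec.items() if k != "table_path"},
        "frequencies": {g: e.frequency for g, e in estimates.items()},
        "comparison": None if comparison is None else {
            "fold_change": comparison.fold_change,
            "lr_statistic": comparison.lr_statistic,
            "p_value": comparison.p_value,
        },
    }
    return estimates


def _stage_dose(cfg: RunConfig, out: Path, summary: dict):
    sec = cfg["dose"]
    table = read_table(sec["table_path"], "dose_response")
    fits = {}
    rows = []
    for group, sub in table.groupby("group"):
        fit = dose_mod.fit_4pl(sub)
        fits[group] = fit
        rows.append((group, fit.top, fit.bottom, fit.ic50, fit.hill,
                     fit.rss, fit.converged))
    write_table(pd.DataFrame(rows, columns=["group", "top", "bottom", "ic50",
                                            "hill", "rss", "converged"]),
                out / "fits_4pl.tsv")
    potency = {}
    if sec["reference"] and sec["reference"] in fits:
        ref_tab = table[table["group"] == sec["reference"]]
        for group in fits:
            if group == sec["reference"]:
                continue
            pr = dose_mod.relative_potency(ref_tab, table[table["group"] == group])
            potency[group] = {"ratio": pr.ratio, "ci": [pr.ci_lower, pr.ci_upper],
                              "shape_warning": pr.shape_warning}
    summary["dose"] = {
        "params": {k: v for k, v in sec.items() if k != "table_path"},
        "ic50": {g: f.ic50 for g, f in fits.items()},
        "relative_potency": potency,
    }
    return fits


_STAGE_FUNCS = {
    "profile": _stage_profile,
    "stratify": _stage_stratify,
    "ldassay": _stage_ldassay,
    "dose": _stage_dose,
}

# derepress depends on simulate when no external profiles are configured
_ORDER = ["simulate", "profile", "stratify", "derepress", "ldassay", "dose"]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; return the JSON-serializable summary.

    A failing stage aborts its dependents but independent stages still run;
    the summary records per-stage status and the overall ``ok`` flag is
    False if anything failed.
    """
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "ok": True, "failures": {}}
    sim_products = None

    for stage in _ORDER:
        if stage not in cfg.stages:
            continue
        try:
            if stage == "simulate":
                sim_products = _stage_simulate(cfg, out, summary)
            elif stage == "derepress":
                needs_sim = cfg["derepress"]["profile_paths"] is None
                if needs_sim and "simulate" in cfg.stages and sim_products is None:
                    raise RuntimeError("upstream simulate stage failed")
                _stage_derepress(cfg, out, summary, sim_products)
            else:
                _STAGE_FUNCS[stage](cfg, out, summary)
            logger.info("stage %s done", stage)
        except Exception as exc:  # noqa: BLE001 - stage isolation is the point
            logger.error("stage %s failed: %s", stage, exc)
            summary["ok"] = False
            summary["failures"][stage] = str(exc)

    checksums = {}
    for path in sorted(out.glob("*")):
        if path.is_file() and path.name != "summary.json":
            checksums[path.name] = _checksum(path)
    summary["checksums"] = checksums
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True,
                                                 default=str) + "\n")
    return summary
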
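"""End-to-end pipeline: filter -> rarefy -> diversity -> BVSTEP -> per-
participant core -> gLV inference -> stability / permanence / invasibility.

The run is a pure function of (inputs, config, seed): all randomness is
derived from the master seed, outputs are written with fixed float
formatting, and the manifest carries a hash of the configuration so mixed-
config output directories are impossible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import f_oneway

from . import __version__
from .bvstep import bvstep_select
from .community import core_microbiota, filter_low_depth, rarefy
from .data_model import (DissimilarityMatrix, OtuTable, PhyloTree,
                         StudyMetadata, ValidationError, validate_joint)
from .diversity import alpha_diversity, dissimilarity, lcbd, ses_phylo
from .glv import GlvModel, InferenceConfig, InferenceError, limits_infer
from .stability import StabilityReport, assess_stability

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"  # all numeric outputs at 6 significant digits


@dataclass
class PipelineConfig:
    """All thresholds of the analysis in one place."""

    min_reads: int = 5000
    rarefaction_depth: int | str = "auto"
    detection: float = 0.001
    prevalence: float = 0.85
    min_series: int = 9
    top_k: int = 1000
    n_null: int = 999
    rho_target: float = 0.95
    lcbd_metric: str = "hellinger"
    bvstep_metric: str = "bray_curtis"
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    r_inv: float = 0.0
    a_inv_inv: float = 0.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_matrix(dm: DissimilarityMatrix, path: Path) -> None:
    df = pd.DataFrame(dm.values, index=dm.ids, columns=dm.ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def run_pipeline(table: OtuTable, metadata: StudyMetadata, tree: PhyloTree,
                 config: PipelineConfig, out_dir) -> dict:
    """Execute the full analysis; returns the manifest (also written).

    Halts with a stage-labelled error on any failure. Participants with
    fewer than ``min_series`` samples are skipped from inference, with the
    reason recorded in the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "microstab",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stages": {},
    }

    def stage(name):
        logger.info("stage: %s", name)
        return manifest["stages"].setdefault(name, {})

    try:
        s = stage("validate")
        validate_joint(table, metadata, tree)
        s["n_samples"], s["n_otus"] = table.n_samples, table.n_otus

        s = stage("filter")
        filtered = filter_low_depth(table, config.min_reads)
        s["n_samples"] = filtered.n_samples
        s["n_removed"] = table.n_samples - filtered.n_samples

        s = stage("rarefy")
        depth = (int(filtered.sample_sums().min())
                 if config.rarefaction_depth == "auto"
                 else int(config.rarefaction_depth))
        rarefied = rarefy(filtered, depth, seed=_stage_seed(config.seed, "rarefy"))
        s["depth"] = depth

        s = stage("alpha")
        alpha = alpha_diversity(rarefied)
        pd.DataFrame(alpha).set_index("sample_id").to_csv(
            out / "alpha.tsv", sep="\t", float_format=FLOAT_FMT)
        s["n_samples"] = rarefied.n_samples

        s = stage("beta")
        matrices = {}
        for metric in ("bray_curtis", "hellinger", "unifrac_unweighted",
                       "unifrac_weighted"):
            dm = dissimilarity(rarefied, metric, tree)
            matrices[metric] = dm
            _write_matrix(dm, out / f"dissimilarity_{metric}.tsv")
        s["metrics"] = sorted(matrices)

        s = stage("lcbd")
        lcbd_vals = lcbd(matrices[config.lcbd_metric])
        pd.DataFrame({"sample_id": rarefied.sample_ids,
                      "lcbd": lcbd_vals}).to_csv(
            out / "lcbd.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
        s["metric"] = config.lcbd_metric

        s = stage("ses")
        ses_rows = []
        for metric in ("MPD", "MNTD"):
            for res in ses_phylo(rarefied, tree, metric,
                                 n_null=config.n_null, top_k=config.top_k,
                                 seed=_stage_seed(config.seed, "ses")):
                ses_rows.append({
                    "sample_id": res.sample_id, "metric": res.metric,
                    "observed": res.observed, "null_mean": res.null_mean,
                    "null_sd": res.null_sd, "ses": res.ses,
                    "index_value": res.index_value,
                    "index_name": "NRI" if metric == "MPD" else "NTI",
                    "defined": res.defined, "clustered": res.clustered,
                })
        pd.DataFrame(ses_rows).to_csv(out / "ses.tsv", sep="\t", index=False,
                                      float_format=FLOAT_FMT)
        s["n_rows"] = len(ses_rows)

        s = stage("bvstep")
        bv = bvstep_select(rarefied, config.bvstep_metric,
                           rho_target=config.rho_target, top_k=config.top_k,
                           tree=tree, seed=_stage_seed(config.seed, "bvstep"))
        with open(out / "bvstep.json", "w") as fh:
            json.dump({"selected_otu_ids": bv.selected_otu_ids,
                       "rho": round(bv.rho, 10), "converged": bv.converged,
                       "n_evaluations": bv.n_evaluations,
                       "config_hash": config.config_hash()}, fh, indent=1,
                      sort_keys=True)
        s["n_selected"], s["rho"] = len(bv.selected_otu_ids), round(bv.rho, 10)

        s = stage("inference")
        reports: list[StabilityReport] = []
        models: dict[str, GlvModel] = {}
        skipped: dict[str, str] = {}
        smoking_of: dict[str, str] = {}
        core_dir = out / "core"
        core_dir.mkdir(exist_ok=True)
        for pid in metadata.participants:
            rows = metadata.for_participant(pid)
            smoking_of[pid] = rows["smoking"].iloc[0]
            in_table = [sid for sid in rows["sample_id"]
                        if sid in set(filtered.sample_ids)]
            if len(in_table) < config.min_series:
                skipped[pid] = (f"{len(in_table)} samples < "
                                f"min_series={config.min_series}")
                continue
            series = core_microbiota(filtered, metadata, pid,
                                     config.detection, config.prevalence)
            core_df = pd.DataFrame(series.abundances,
                                   index=series.weeks,
                                   columns=series.core_otu_ids)
            core_df.index.name = "week"
            core_df.to_csv(core_dir / f"{pid}.tsv", sep="\t",
                           float_format=FLOAT_FMT)
            inf_cfg = dataclasses.replace(
                config.inference, seed=_stage_seed(config.seed, f"infer:{pid}"))
            try:
                model = limits_infer(series, inf_cfg)
            except InferenceError as exc:
                skipped[pid] = str(exc)
                continue
            models[pid] = model
            reports.append(assess_stability(model, pid, config.r_inv,
                                            config.a_inv_inv))
        s["n_inferred"], s["skipped"] = len(models), skipped

        s = stage("stability")
        report_dir = out / "reports"
        report_dir.mkdir(exist_ok=True)
        for rep in reports:
            doc = rep.to_dict()
            doc["config_hash"] = config.config_hash()
            doc["smoking"] = smoking_of[rep.participant_id]
            with open(report_dir / f"{rep.participant_id}.json", "w") as fh:
                json.dump(doc, fh, indent=1, sort_keys=True,
                          default=lambda v: round(float(v), 10))
        s["n_reports"] = len(reports)

        s = stage("summary")
        summary = _group_summary(reports, smoking_of)
        manifest["summary"] = summary
    except Exception as exc:
        failed = list(manifest["stages"])[-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc

    manifest["seed"] = config.seed
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True,
                  default=lambda v: round(float(v), 10))
    return manifest


def _group_summary(reports: list[StabilityReport],
                   smoking_of: dict[str, str]) -> dict:
    """Smoker vs nonsmoker summaries of the per-participant verdicts."""
    groups: dict[str, list[StabilityReport]] = {"smoker": [], "nonsmoker": []}
    for rep in reports:
        groups[smoking_of[rep.participant_id]].append(rep)
    summary: dict = {}
    eig_groups = []
    for name, reps in groups.items():
        eigs = [r.dominant_eigenvalue for r in reps]
        eig_groups.append(eigs)
        summary[name] = {
            "n": len(reps),
            "dominant_eigenvalue_mean": (round(float(np.mean(eigs)), 10)
                                         if eigs else None),
            "dominant_eigenvalue_sd": (round(float(np.std(eigs, ddof=1)), 10)
                                       if len(eigs) > 1 else None),
            "n_locally_stable": sum(r.locally_stable for r in reps),
            "n_permanent": sum(r.permanent for r in reps),
            "n_invasible": sum(r.invasible for r in reps),
        }
    if all(len(g) > 1 for g in eig_groups):
        stat = f_oneway(*eig_groups)
        summary["eigenvalue_anova_F"] = round(float(stat.statistic), 10)
        summary["eigenvalue_anova_p"] = round(float(stat.pvalue), 10)
    return summary
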
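"""End-to-end orchestration: simulate -> assay -> filter -> fit -> select -> stats.

A run is driven by one config (YAML-compatible mapping) plus a master seed,
writes every stage artifact as plain text, and records a manifest with
SHA-256 checksums of all outputs so that reproducibility is checkable by
re-running and comparing manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assay import ic50_per_sample, summarize_activity
from .features import FilterConfig, assemble_blocks
from .opls import back_project_loadings, cross_validated_q2, fit_consensus_opls, permutation_test
from .selection import enrichment_by_group, select_active_ions
from .stats import compare_groups, dunn_many_to_one
from .synthetic import GeneratorConfig, config_from_dict, config_to_dict, generate_dataset, write_dataset

log = logging.getLogger("mbopls")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    n_ortho: int = 1
    scaling: str = "uv"
    cv_folds: int = 7
    n_permutations: int = 99
    reference_concentration: float = 10.0
    selection_threshold: float = 5.0
    alpha: float = 0.05

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        gen = config_from_dict(d.pop("generator", {}) or {})
        filt = FilterConfig(**(d.pop("filters", {}) or {}))
        return cls(generator=gen, filters=filt, **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return {
            "generator": config_to_dict(self.generator),
            "filters": vars(self.filters).copy(),
            "n_ortho": self.n_ortho, "scaling": self.scaling,
            "cv_folds": self.cv_folds, "n_permutations": self.n_permutations,
            "reference_concentration": self.reference_concentration,
            "selection_threshold": self.selection_threshold, "alpha": self.alpha,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir, seed: int | None = None) -> dict:
    """Execute every stage, write artifacts + manifest, return the manifest.

    Any stage failure raises :class:`PipelineError` naming the stage; a
    FAILED marker file is left next to the partial outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config.generator.seed = int(seed)
    master_seed = config.generator.seed
    manifest: dict = {
        "tool_version": __version__,
        "seed": master_seed,
        "config": config.to_dict(),
        "stages": {},
        "checksums": {},
        "metrics": {},
    }
    stage = "simulate"
    try:
        t0 = time.time()
        design, gt, neg, pos, plate = generate_dataset(config.generator)
        paths = write_dataset(out, design, gt, neg, pos, plate)
        log.info("simulate: %d samples, %d neg + %d pos ions (%.2fs)",
                 len(design), neg.n_ions, pos.n_ions, time.time() - t0)
        manifest["stages"]["simulate"] = {
            "n_samples": len(design), "n_ions_neg": neg.n_ions, "n_ions_pos": pos.n_ions}

        stage = "assay"
        activity = summarize_activity(plate, config.reference_concentration)
        activity = activity.set_index("sample_id").loc[design["sample_id"]].reset_index()
        activity.to_csv(out / "activity.tsv", sep="\t", index=False)
        ic50 = ic50_per_sample(plate)
        ic50.to_csv(out / "ic50.tsv", sep="\t", index=False)
        paths["activity"] = str(out / "activity.tsv")
        paths["ic50"] = str(out / "ic50.tsv")
        manifest["stages"]["assay"] = {"n_samples": len(activity)}

        stage = "filter"
        neg_f, pos_f, prov = assemble_blocks(neg, pos, design, config.filters)
        if neg_f.n_ions == 0 or pos_f.n_ions == 0:
            raise PipelineError("a block has zero ions after filtering")
        neg_f.to_csv(out / "block_neg_filtered.csv")
        pos_f.to_csv(out / "block_pos_filtered.csv")
        for mode in ("neg", "pos"):
            prov[mode]["removal_log"].to_csv(out / f"removal_log_{mode}.tsv",
                                             sep="\t", index=False)
        paths.update({
            "block_neg_filtered": str(out / "block_neg_filtered.csv"),
            "block_pos_filtered": str(out / "block_pos_filtered.csv"),
            "removal_log_neg": str(out / "removal_log_neg.tsv"),
            "removal_log_pos": str(out / "removal_log_pos.tsv"),
        })
        manifest["stages"]["filter"] = {m: prov[m]["counts"] for m in ("neg", "pos")}
        log.info("filter: neg %s, pos %s", prov["neg"]["counts"], prov["pos"]["counts"])

        stage = "fit"
        y = activity["inhibition_percent"].to_numpy()
        strata = (design["organ"] + "/" + design["site"]).to_numpy()
        model = fit_consensus_opls(
            [neg_f, pos_f], y, n_ortho=config.n_ortho, scaling=config.scaling,
            block_names=["neg", "pos"], sample_ids=list(design["sample_id"]),
            ion_ids=[neg_f.ion_ids, pos_f.ion_ids])
        model.q2 = cross_validated_q2([neg_f, pos_f], y, config.n_ortho,
                                      config.cv_folds, seed=master_seed,
                                      strata=strata, scaling=config.scaling)
        perm = permutation_test([neg_f, pos_f], y, config.n_ortho,
                                config.n_permutations, seed=master_seed,
                                k_folds=config.cv_folds, strata=strata,
                                scaling=config.scaling)
        model.to_json(out / "model.json")
        scores = pd.DataFrame({"sample_id": design["sample_id"],
                               "t_pred": model.t_pred})
        for k in range(model.T_ortho.shape[1]):
            scores[f"t_ortho_{k + 1}"] = model.T_ortho[:, k]
        scores.to_csv(out / "scores.tsv", sep="\t", index=False)
        loadings = back_project_loadings(model, [neg_f, pos_f])
        loadings.to_csv(out / "loadings.tsv", sep="\t", index=False)
        paths.update({"model": str(out / "model.json"),
                      "scores": str(out / "scores.tsv"),
                      "loadings": str(out / "loadings.tsv")})
        manifest["metrics"].update({
            "r2y": model.r2y, "q2": model.q2,
            "block_weights": dict(zip(model.block_names, model.block_weights.tolist())),
            "explained_variance_predictive": model.explained_variance["predictive"],
            "explained_variance_orthogonal": model.explained_variance["orthogonal"],
            "permutation_p": perm.p_value,
        })
        log.info("fit: R2Y=%.3f Q2=%.3f perm p=%.3g", model.r2y, model.q2, perm.p_value)

        stage = "select"
        sel = select_active_ions(loadings, threshold=config.selection_threshold)
        sel.table.to_csv(out / "selection.tsv", sep="\t", index=False)
        paths["selection"] = str(out / "selection.tsv")
        manifest["stages"]["select"] = {"n_selected": len(sel.selected_ids),
                                        "threshold": sel.threshold}
        enrich_frames = []
        for mode, blk in (("neg", neg_f), ("pos", pos_f)):
            ids = sel.table.query("selected and block == @mode")["ion_id"].tolist()
            if ids:
                e = enrichment_by_group(ids, blk, design)
                e.insert(1, "block", mode)
                enrich_frames.append(e)
        enrichment = (pd.concat(enrich_frames, ignore_index=True)
                      if enrich_frames else pd.DataFrame())
        enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        paths["enrichment"] = str(out / "enrichment.tsv")

        stage = "stats"
        cells = design["organ"] + "/" + design["site"]
        comp = compare_groups(y, cells.to_numpy(), alpha=config.alpha)
        comp.pairwise_adjusted_p.to_csv(out / "pairwise_p.tsv", sep="\t")
        comp.letters.rename_axis("group").to_frame().assign(
            kw_statistic=comp.kw_statistic, kw_p=comp.kw_p).to_csv(
            out / "letters.tsv", sep="\t")
        # many-to-one vs acarbose: acarbose replicate inhibitions at top dose
        from .assay import inhibition_percent  # local, tiny
        ctrl = plate[plate["role"] == "positive_control"]
        top_dose = ctrl["concentration"].max()
        a_neg = plate.loc[plate["role"] == "negative_control", "absorbance_405"].mean()
        acb = np.array([inhibition_percent(a_neg, a) for a in
                        ctrl.loc[ctrl["concentration"] == top_dose, "absorbance_405"]])
        vals = np.concatenate([y, acb])
        grp = np.concatenate([design["organ"].to_numpy(), ["acarbose"] * len(acb)])
        dunn = dunn_many_to_one(vals, grp, "acarbose")
        dunn.rename_axis("group").to_frame().to_csv(out / "dunn_vs_acarbose.tsv", sep="\t")
        paths.update({"pairwise_p": str(out / "pairwise_p.tsv"),
                      "letters": str(out / "letters.tsv"),
                      "dunn_vs_acarbose": str(out / "dunn_vs_acarbose.tsv")})
        manifest["stages"]["stats"] = {
            "kw_p": comp.kw_p, "letters": comp.letters.to_dict(),
            "dunn_vs_acarbose": dunn.to_dict()}
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage} failed: {exc}\n")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    for name, p in paths.items():
        manifest["checksums"][name] = _sha256(Path(p))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
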
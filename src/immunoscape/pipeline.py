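"""End-to-end orchestration: cells → density → classes → scores → survival/genes.

A single YAML config drives the full analysis.  Every stochastic stage
(lymphocyte subsampling, EM restarts, bootstrap) takes its seed from the one
seed in the config, and every artifact is stamped with the seed and a hash of
the config so a run can be replayed exactly.  Optional inputs (clinical
table, expression matrix, gene sets) merely skip their stages with a log
line; a missing cells directory is an error before any computation starts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from glob import glob

import numpy as np
import pandas as pd
import yaml

from . import survival as surv
from .cell_tables import read_cell_map, summarize_cell_map
from .density import KernelSpec, proximity_to_cancer
from .mixture import (
    assign_classes,
    class_thresholds,
    fit_gmm,
    select_k,
    stability_analysis,
)
from .molecular import correlate_genes, find_modules_by_sign, hypergeom_enrichment, read_gmt
from .scores import compute_scores, scores_table

log = logging.getLogger("immunoscape")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (see docs for the YAML layout)."""

    cells_dir: str
    out_dir: str
    clinical: str | None = None
    expression: str | None = None
    gene_sets: str | None = None
    bandwidth: float = 50.0
    sample_size: int = 100_000
    reps: int = 200
    k_max: int = 5
    run_stability: bool = False
    discovery_cohort: str | None = None
    validation_cohort: str | None = None
    scan_lo: float = 20.0
    scan_hi: float = 80.0
    scan_step: float = 1.5
    n_boot: int = 1000
    q_threshold: float = 0.05
    seed: int = 0
    units: str = "um"
    px_size: float | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: RunConfig
    model: object
    thresholds: tuple
    scores: pd.DataFrame
    survival_report: dict | None = None
    gene_correlations: pd.DataFrame | None = None
    modules: list = field(default_factory=list)
    enrichment: pd.DataFrame | None = None
    artifacts: list = field(default_factory=list)


def _stamp(config: RunConfig) -> dict:
    return {"config_hash": config.digest(), "seed": config.seed}


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage in dependency order; see the module docstring."""
    if not os.path.isdir(config.cells_dir):
        raise FileNotFoundError(f"cells directory not found: {config.cells_dir}")
    cell_files = sorted(glob(os.path.join(config.cells_dir, "*.csv")))
    if not cell_files:
        raise FileNotFoundError(f"no cell tables (*.csv) in {config.cells_dir}")
    os.makedirs(config.out_dir, exist_ok=True)
    written: list[str] = []

    def _out(name: str) -> str:
        path = os.path.join(config.out_dir, name)
        written.append(path)
        return path

    try:
        return _run(config, cell_files, _out, written)
    except Exception:
        for path in written:  # no partial outputs on failure
            if os.path.exists(path):
                os.remove(path)
        raise


def _run(config: RunConfig, cell_files, _out, written) -> PipelineResult:
    spec = KernelSpec(bandwidth=config.bandwidth)
    rng = np.random.default_rng(config.seed)

    maps, prox = [], []
    for path in cell_files:
        m = read_cell_map(path, units=config.units, px_size=config.px_size)
        maps.append(m)
        prox.append(proximity_to_cancer(m, spec))
    log.info("loaded %d cell maps", len(maps))

    pooled = np.concatenate([p.values for p in prox])
    if config.run_stability:
        report = stability_analysis(
            pooled,
            sample_size=config.sample_size,
            reps=config.reps,
            k_max=config.k_max,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        best_k = report.modal_k
        log.info("stability: modal K=%d in %.0f%% of reps", best_k, 100 * report.frac_modal)
    else:
        sample = pooled
        if pooled.size > config.sample_size:
            sample = rng.choice(pooled, size=config.sample_size, replace=False)
        best_k = select_k(sample, k_max=config.k_max, seed=int(rng.integers(0, 2**31 - 1))).best_k
        report = None
        log.info("BIC selects K=%d", best_k)

    # deterministic production fit at the selected K on one fixed sample
    sample = pooled
    if pooled.size > config.sample_size:
        sample = np.random.default_rng(config.seed).choice(
            pooled, size=config.sample_size, replace=False
        )
    model = fit_gmm(sample, best_k, seed=config.seed)
    if best_k == 3:
        class_model = model
    else:
        # the ITL/ATL/DTL system is a three-class scheme; classify with a
        # K=3 fit and leave the discrepant K selection visible in model.json
        log.warning("BIC selected K=%d, not 3; classifying with a K=3 fit", best_k)
        class_model = fit_gmm(sample, 3, seed=config.seed)
    thresholds = class_thresholds(class_model)

    model_payload = {**model.to_dict(), "thresholds": list(thresholds), **_stamp(config)}
    if report is not None:
        model_payload["stability"] = report.to_dict()
    with open(_out("model.json"), "w", encoding="utf-8") as fh:
        json.dump(model_payload, fh, indent=2)

    all_scores = []
    labels_dir = os.path.join(config.out_dir, "labels")
    os.makedirs(labels_dir, exist_ok=True)
    for m, p in zip(maps, prox):
        classified = assign_classes(thresholds, p.values, model=class_model)
        summary = summarize_cell_map(m)
        all_scores.append(compute_scores(classified, summary["n_cancer"], m.tumour_id))
        lab = m.cells.copy()
        lab["til_class"] = ""
        lab.loc[p.lymph_index, "til_class"] = classified.labels
        lab_path = os.path.join(labels_dir, f"{m.tumour_id}.csv")
        lab.to_csv(lab_path, index=False)
        written.append(lab_path)
    scores = scores_table(all_scores)
    scores.to_csv(_out("scores.csv"), index=False)

    survival_report = None
    if config.clinical:
        clinical = pd.read_csv(config.clinical, sep=None, engine="python")
        merged = clinical.merge(
            scores[["tumour_id", "itlr"]], left_on="sample_id", right_on="tumour_id"
        )
        if config.discovery_cohort is not None and "cohort" in merged.columns:
            disc = merged[merged["cohort"].astype(str) == str(config.discovery_cohort)]
            val = merged[merged["cohort"].astype(str) == str(config.validation_cohort)]
            dv = surv.discovery_validation(
                disc["itlr"].to_numpy(), disc, val["itlr"].to_numpy(), val,
                lo=config.scan_lo, hi=config.scan_hi, step=config.scan_step,
            )
            res = dv["discovery"]
            survival_report = {
                "chosen_percentile": res.chosen_percentile,
                "chosen_cutoff": res.chosen_cutoff,
                "discovery_logrank_p": res.logrank_p,
                "discovery_hr": res.hr,
                "validation_logrank_p": dv["validation_logrank_p"],
                "cutoff_consistency": dv["consistency"],
            }
            boot_source, boot_scores = disc, disc["itlr"].to_numpy()
            boot_cut = res.chosen_cutoff
        else:
            res = surv.scan_cutoff(
                merged["itlr"].to_numpy(), merged,
                lo=config.scan_lo, hi=config.scan_hi, step=config.scan_step,
            )
            survival_report = {
                "chosen_percentile": res.chosen_percentile,
                "chosen_cutoff": res.chosen_cutoff,
                "logrank_p": res.logrank_p,
                "hr": res.hr,
                "hr_ci": list(res.hr_ci),
            }
            boot_source, boot_scores = merged, merged["itlr"].to_numpy()
            boot_cut = res.chosen_cutoff
        if config.n_boot:
            covs = [c for c in ("node", "size") if c in boot_source.columns]
            boot = surv.bootstrap_stability(
                boot_source,
                (boot_scores >= boot_cut).astype(int),
                covariates=tuple(covs),
                n_boot=config.n_boot,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            survival_report["bootstrap"] = {
                "frac_significant_uni": boot.frac_significant_uni,
                "frac_significant_multi": boot.frac_significant_multi,
            }
        survival_report.update(_stamp(config))
        with open(_out("survival_report.json"), "w", encoding="utf-8") as fh:
            json.dump(survival_report, fh, indent=2)
    else:
        log.info("no clinical table supplied; survival stage skipped")

    gene_corr = None
    modules: list = []
    enrichment = None
    if config.expression:
        expr = pd.read_csv(config.expression, sep="\t", index_col=0)
        itlr = scores.set_index("tumour_id")["itlr"]
        gene_corr = correlate_genes(itlr, expr, q_threshold=config.q_threshold)
        gene_corr.to_csv(_out("gene_correlations.csv"), index=False)
        modules = find_modules_by_sign(gene_corr, expr)
        with open(_out("modules.json"), "w", encoding="utf-8") as fh:
            json.dump(
                [
                    {"module_id": mo.module_id, "sign": mo.sign,
                     "mean_abs_r": mo.mean_abs_r, "genes": mo.genes}
                    for mo in modules
                ],
                fh, indent=2,
            )
        if config.gene_sets:
            sets = read_gmt(config.gene_sets)
            hits = gene_corr.loc[gene_corr["significant"], "gene"].tolist()
            if hits:
                enrichment = hypergeom_enrichment(hits, sets, list(expr.index))
                enrichment.to_csv(_out("enrichment.csv"), index=False)
        else:
            log.info("no gene sets supplied; enrichment stage skipped")
    else:
        log.info("no expression matrix supplied; molecular stage skipped")

    with open(_out("run_meta.json"), "w", encoding="utf-8") as fh:
        json.dump(_stamp(config), fh, indent=2)
    return PipelineResult(
        config=config,
        model=model,
        thresholds=thresholds,
        scores=scores,
        survival_report=survival_report,
        gene_correlations=gene_corr,
        modules=modules,
        enrichment=enrichment,
        artifacts=list(written),
    )
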
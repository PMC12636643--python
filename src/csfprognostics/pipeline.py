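"""End-to-end orchestration of the prognostics workflow.

A single config (YAML or dict) drives: simulate -> preprocess ->
trajectories -> differential -> enrichment -> panels -> staging. Each
stage reads only the declared files of earlier stages, writes TSV/JSON
artifacts into the output directory, and the run ends with a manifest
recording the package version, the per-stage seeds expanded
deterministically from one global seed, and a SHA-256 digest of every
output — so two runs with the same config produce bit-identical
manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .differential import dap_linear
from .enrichment import fdr_over_modules, module_enrichment_z
from .matrix import read_abundance_tsv, write_abundance_tsv
from .panels import evaluate_panel, stability_select
from .preprocess import (TamporConfig, bootstrap_regress_covariates,
                         filter_completeness, filter_quantified, knn_impute,
                         scale_sample_loading, tampor, zeros_to_missing)
from .staging import EventModelConfig, fit_event_sequence
from .synthetic import SimConfig, write_cohort
from .trajectories import (classify_AT, fit_subject_slopes, median_split,
                           select_longitudinal, trim_outlier_slopes)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "preprocess", "trajectories", "differential",
           "enrichment", "panels", "staging")
_STAGE_TAGS = {name: 101 + i for i, name in enumerate(_STAGES)}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Pipeline settings: output directory, global seed, stage toggles and
    per-stage parameter sections (each mirroring the module's own config).
    """

    out_dir: str = "pipeline_out"
    seed: int = 0
    stages: dict = field(default_factory=dict)      # name -> bool
    inputs: dict = field(default_factory=dict)      # paths when simulate is off
    simulate: dict = field(default_factory=dict)    # SimConfig overrides
    preprocess: dict = field(default_factory=dict)
    trajectories: dict = field(default_factory=dict)
    differential: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)
    panels: dict = field(default_factory=dict)
    staging: dict = field(default_factory=dict)

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence([int(self.seed), _STAGE_TAGS[stage]])
        return int(ss.generate_state(1)[0] % (2**31))


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(paths: dict, key: str, stage: str) -> Path:
    if key not in paths or not Path(paths[key]).exists():
        raise PipelineError(f"stage {stage!r}: missing upstream output {key!r}")
    return Path(paths[key])


def run_pipeline(config: PipelineConfig | dict) -> dict:
    """Run the enabled stages and return (and write) the manifest."""
    if isinstance(config, dict):
        config = PipelineConfig(**config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = dict(config.inputs)
    outputs: dict[str, Path] = {}

    def record(name: str, path: Path) -> None:
        paths[name] = str(path)
        outputs[name] = path

    # ---- simulate -------------------------------------------------------
    if config.enabled("simulate"):
        try:
            sim = SimConfig(**{**config.simulate,
                               "seed": config.stage_seed("simulate")})
            written = write_cohort(sim, out)
        except Exception as exc:
            raise PipelineError(f"stage 'simulate' failed: {exc}") from exc
        for key, p in written.items():
            record(key, Path(p))

    # ---- preprocess -----------------------------------------------------
    if config.enabled("preprocess"):
        try:
            ab_path = _require(paths, "abundance", "preprocess")
            meta = pd.read_csv(_require(paths, "metadata", "preprocess"), sep="\t")
            m = read_abundance_tsv(ab_path, scale="raw")
            m = zeros_to_missing(m)
            m = scale_sample_loading(m)
            m = filter_quantified(m, config.preprocess.get("min_quantified_frac", 0.5))
            m = tampor(m, meta, TamporConfig(
                tol=config.preprocess.get("tampor_tol", 1e-8),
                max_iter=config.preprocess.get("tampor_max_iter", 250)))
            design = meta.set_index("sample_id").loc[m.sample_ids, ["batch_id"]]
            m = bootstrap_regress_covariates(
                m, design,
                n_boot=config.preprocess.get("n_boot", 100),
                seed=config.stage_seed("preprocess"))
            norm_path = out / "normalized_log2.tsv"
            write_abundance_tsv(m, norm_path, missing_as_zero=False)
            record("normalized", norm_path)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage 'preprocess' failed: {exc}") from exc

    # ---- trajectories ---------------------------------------------------
    if config.enabled("trajectories"):
        try:
            series = pd.read_csv(_require(paths, "outcomes", "trajectories"), sep="\t")
            meta = pd.read_csv(_require(paths, "metadata", "trajectories"), sep="\t")
            kept = select_longitudinal(series)
            slope_parts = []
            for outcome in kept["outcome_name"].unique():
                st = fit_subject_slopes(kept, outcome_name=outcome)
                st = trim_outlier_slopes(st, config.trajectories.get("trim_sd", 4.0))
                st = median_split(st)
                slope_parts.append(st)
            slopes = pd.concat(slope_parts, ignore_index=True)
            slope_path = out / "slopes.tsv"
            slopes.to_csv(slope_path, sep="\t", index=False)
            record("slopes", slope_path)
            at = classify_AT(meta["abeta42"], meta["ptau181"])
            at_path = out / "at_status.tsv"
            pd.DataFrame({"sample_id": meta["sample_id"], "at_status": at}) \
                .to_csv(at_path, sep="\t", index=False)
            record("at_status", at_path)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage 'trajectories' failed: {exc}") from exc

    # ---- differential ---------------------------------------------------
    if config.enabled("differential"):
        try:
            m = read_abundance_tsv(_require(paths, "normalized", "differential"),
                                   scale="log2")
            meta = pd.read_csv(_require(paths, "metadata", "differential"), sep="\t")
            group = meta.set_index("sample_id").loc[m.sample_ids, "group"].to_numpy()
            dap = dap_linear(m, group)
            dap_path = out / "dap.tsv"
            dap.to_csv(dap_path, sep="\t", index=False)
            record("dap", dap_path)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage 'differential' failed: {exc}") from exc

    # ---- enrichment -----------------------------------------------------
    if config.enabled("enrichment"):
        try:
            dap = pd.read_csv(_require(paths, "dap", "enrichment"), sep="\t")
            if "modules" in paths:
                mem_df = pd.read_csv(Path(paths["modules"]), sep="\t")
                membership = dict(zip(mem_df.iloc[:, 0], mem_df.iloc[:, 1]))
            else:
                truth_path = _require(paths, "truth", "enrichment")
                membership = json.loads(truth_path.read_text())["module_membership"]
            enr = module_enrichment_z(
                dap.set_index("protein_id")["p_value"], membership,
                B=config.enrichment.get("B", 2000),
                seed=config.stage_seed("enrichment"))
            enr = fdr_over_modules(enr)
            enr_path = out / "enrichment.tsv"
            enr.to_csv(enr_path, sep="\t", index=False)
            record("enrichment", enr_path)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage 'enrichment' failed: {exc}") from exc

    # ---- panels ---------------------------------------------------------
    if config.enabled("panels"):
        try:
            m = read_abundance_tsv(_require(paths, "normalized", "panels"),
                                   scale="log2")
            meta = pd.read_csv(_require(paths, "metadata", "panels"), sep="\t")
            dap = pd.read_csv(_require(paths, "dap", "panels"), sep="\t")
            m = filter_completeness(m, config.panels.get("min_complete_frac", 0.95))
            m = knn_impute(m, k=config.panels.get("knn_k", 5))
            # restrict candidate features to the strongest DAPs (configurable)
            n_cand = config.panels.get("n_candidates", 60)
            keep = dap.nsmallest(n_cand, "p_value")["protein_id"]
            keep = [p for p in keep if p in m.protein_ids]
            X = m.to_frame().T[keep]
            y = meta.set_index("sample_id").loc[m.sample_ids, "group"].to_numpy()
            sel_seed = config.stage_seed("panels")
            sel = stability_select(
                X, y,
                n_boot=config.panels.get("n_boot", 25),
                threshold=config.panels.get("threshold", 0.9),
                cv_folds=config.panels.get("select_cv_folds", 3),
                seed=sel_seed)
            panel = sel.selected or [sel.frequencies.idxmax()]
            grid = config.panels.get("grid",
                                     {"n_estimators": [100], "max_depth": [None]})
            ev = evaluate_panel(
                X[panel], y,
                n_runs=config.panels.get("n_runs", 20),
                test_frac=config.panels.get("test_frac", 0.2),
                cv_folds=config.panels.get("cv_folds", 5),
                grid=grid, seed=sel_seed)
            sel_path = out / "panel_selection.tsv"
            sel.frequencies.rename_axis("protein_id").reset_index() \
                .assign(selected=lambda d: d["protein_id"].isin(panel)) \
                .to_csv(sel_path, sep="\t", index=False)
            auc_path = out / "panel_aucs.tsv"
            pd.DataFrame({"run": np.arange(ev.n_runs), "auc": ev.aucs,
                          "youden_threshold": [t for t, _ in ev.youden]}) \
                .to_csv(auc_path, sep="\t", index=False)
            record("panel_selection", sel_path)
            record("panel_aucs", auc_path)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage 'panels' failed: {exc}") from exc

    # ---- staging --------------------------------------------------------
    if config.enabled("staging"):
        try:
            Z = pd.read_csv(_require(paths, "staging", "staging"),
                            sep="\t", index_col=0)
            cfg = EventModelConfig(
                z_event=config.staging.get("z_event", 2.0),
                sigma=config.staging.get("sigma", 0.5),
                n_restarts=config.staging.get("n_restarts", 5),
                mcmc_iters=config.staging.get("mcmc_iters", 2000),
                seed=config.stage_seed("staging"))
            seq = fit_event_sequence(Z, cfg)
            order_path = out / "event_order.tsv"
            pd.DataFrame({"position": np.arange(1, len(seq.order) + 1),
                          "biomarker": seq.order}) \
                .to_csv(order_path, sep="\t", index=False)
            pos_path = out / "positional_probability.tsv"
            seq.positional_probability.to_csv(pos_path, sep="\t")
            stage_path = out / "stage_posteriors.tsv"
            seq.stage_posterior.assign(map_stage=seq.map_stages) \
                .to_csv(stage_path, sep="\t")
            record("event_order", order_path)
            record("positional_probability", pos_path)
            record("stage_posteriors", stage_path)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage 'staging' failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "seed": int(config.seed),
        "stage_seeds": {s: config.stage_seed(s) for s in _STAGES
                        if config.enabled(s)},
        "stages_run": [s for s in _STAGES if config.enabled(s)],
        "outputs": {name: {"path": p.name, "sha256": _sha256(p)}
                    for name, p in sorted(outputs.items())},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
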
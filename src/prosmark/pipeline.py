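"""End-to-end orchestration: simulate -> quantify -> assemble -> screen ->
select -> evaluate -> report.

Stages communicate only through on-disk CSV/TSV artifacts inside the output
directory, so any stage can be re-run or audited independently. A manifest
records the resolved configuration, its hash, the seed and library versions.
All randomness derives from the single run seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import assemble_dataset, summarize_cohort, write_cohort_csv
from .cox import adjusted_screen, univariate_screen
from .ihc import deconvolve, region_metrics, rgb_to_od
from .selection import (
    ImputationConfig,
    final_signature,
    impute,
    lasso_cox_path,
    tally_selections,
)
from .survroc import bootstrap_inference, signature_auc
from .synthetic import (
    CohortSimConfig,
    ExpressionSimConfig,
    SpotSimConfig,
    simulate_cohort,
    simulate_expression_studies,
    simulate_spot_image,
    write_expression_tsv,
    write_spot_csv,
)
from .voting import evaluate_models, train_voting_model

__all__ = ["RunConfig", "ConfigError", "PipelineError", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    """Aggregated, human-readable configuration problems."""


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "prosmark_out"
    cohort: dict = field(default_factory=dict)        # CohortSimConfig overrides
    imputation: dict = field(default_factory=dict)    # ImputationConfig overrides
    lasso: dict = field(default_factory=lambda: {"n_lambda": 100, "lambda_min_ratio": 0.001})
    signature_size: int = 3
    horizons: tuple[float, ...] = (3.0, 5.0)
    cv_folds: int = 10
    bootstrap_B: int = 1000
    expression_enabled: bool = True
    expression: dict = field(default_factory=dict)    # ExpressionSimConfig overrides
    voting_n_each: int = 500
    voting_n_genes: int = 11
    ihc_demo_enabled: bool = True


_KNOWN_KEYS = {f.name for f in dataclasses.fields(RunConfig)}


def validate_config(path) -> RunConfig:
    """Load a YAML run configuration, reject unknown keys, resolve defaults.

    An empty file yields the full default configuration. Errors are
    aggregated into a single :class:`ConfigError`.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    errors = []
    if not isinstance(raw, dict):
        raise ConfigError(f"top-level YAML must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _KNOWN_KEYS
    for key in sorted(unknown):
        errors.append(f"unknown configuration key: {key!r}")
    if "seed" in raw and raw["seed"] is None:
        errors.append("seed is required when stochastic stages are enabled")
    kwargs = {k: v for k, v in raw.items() if k in _KNOWN_KEYS and v is not None}
    if "horizons" in kwargs:
        kwargs["horizons"] = tuple(float(h) for h in kwargs["horizons"])
    try:
        cfg = RunConfig(**kwargs)
    except TypeError as exc:
        errors.append(str(exc))
        cfg = None
    if cfg is not None:
        for sub, cls in (("cohort", CohortSimConfig), ("imputation", ImputationConfig),
                         ("expression", ExpressionSimConfig)):
            known = {f.name for f in dataclasses.fields(cls)}
            for key in sorted(set(getattr(cfg, sub)) - known):
                errors.append(f"unknown {sub} key: {key!r}")
    if errors:
        raise ConfigError("; ".join(errors))
    return cfg


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis on synthetic data and write the report bundle.

    Artifacts (all CSV/TSV/JSON under ``config.outdir``): cohort and spot
    tables, assembled dataset, cohort summary, univariate + adjusted
    biomarker screens, imputed datasets, selection tally, signature, AUC
    table, voting-signature outputs (when enabled), and a manifest.
    Returns a dict of the key in-memory results.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "stages": [],
    }
    results: dict = {}
    stage = "simulate"
    try:
        cohort_cfg = CohortSimConfig(**{"seed": config.seed, **config.cohort})
        records, spot_table, truth = simulate_cohort(cohort_cfg)
        write_cohort_csv(records, out / "cohort.csv")
        write_spot_csv(spot_table, out / "spots.csv")
        manifest["stages"].append(stage)

        if config.ihc_demo_enabled:
            stage = "quantify"
            spot_cfg = SpotSimConfig(seed=config.seed)
            rgb, masks, truth_img = simulate_spot_image(spot_cfg)
            conc, _ = deconvolve(rgb_to_od(rgb))
            met = region_metrics(conc[..., 1], masks, "tumor_epithelium",
                                 threshold=truth_img["threshold"])
            pd.DataFrame(
                [
                    {
                        "region": "tumor_epithelium",
                        "avg_od": met.avg_od,
                        "pct_pos": met.pct_pos,
                        "score": met.score,
                        "truth_avg_od": truth_img["tumor_epithelium"]["avg_od"],
                        "truth_pct_pos": truth_img["tumor_epithelium"]["pct_pos"],
                        "truth_score": truth_img["tumor_epithelium"]["score"],
                    }
                ]
            ).to_csv(out / "ihc_quantification_demo.csv", index=False)
            results["ihc_demo_rel_err"] = abs(
                met.score - truth_img["tumor_epithelium"]["score"]
            ) / max(truth_img["tumor_epithelium"]["score"], 1e-12)
            manifest["stages"].append(stage)

        stage = "assemble"
        dataset = assemble_dataset(records, spot_table)
        dataset.frame.to_csv(out / "dataset.csv", index=False)
        summary = summarize_cohort(dataset)
        summary.to_csv(out / "cohort_summary.csv", index=False)
        results["dataset"] = dataset
        results["summary"] = summary
        manifest["stages"].append(stage)

        stage = "screen"
        biomarkers = dataset.biomarkers
        uni = univariate_screen(dataset.frame, biomarkers)
        adj = adjusted_screen(dataset.frame, biomarkers)
        screen = pd.concat([uni, adj], ignore_index=True)
        screen.to_csv(out / "biomarker_screen.csv", index=False)
        results["screen"] = screen
        manifest["stages"].append(stage)

        stage = "select"
        imp_cfg = ImputationConfig(**{"seed": config.seed + 1, **config.imputation})
        completed = impute(dataset.frame, biomarkers, imp_cfg)
        for i, dfc in enumerate(completed, start=1):
            dfc.to_csv(out / f"imputed_{i:02d}.csv", index=False)
        paths = [
            lasso_cox_path(dfc, biomarkers, max_active=5, **config.lasso)
            for dfc in completed
        ]
        tally = tally_selections(paths)
        tally.to_csv(out / "selection_tally.csv")
        signature = final_signature(tally, size=config.signature_size)
        (out / "signature.txt").write_text("\n".join(signature) + "\n")
        results["tally"] = tally
        results["signature"] = signature
        manifest["stages"].append(stage)

        stage = "evaluate"
        unadj, cvadj = signature_auc(
            completed, signature, horizons=config.horizons,
            cv_folds=config.cv_folds, seed=config.seed + 2,
        )
        rows = []
        for adjusted, res in (("unadjusted", unadj), ("cv_adjusted", cvadj)):
            for h in config.horizons:
                boot = bootstrap_inference(
                    completed, signature, h, B=config.bootstrap_B,
                    seed=config.seed + 3, adjusted=(adjusted == "cv_adjusted"),
                    cv_folds=config.cv_folds,
                )
                rows.append(
                    {
                        "analysis": adjusted,
                        "horizon_years": h,
                        "auc": res[h].auc,
                        "ci_low": boot["ci_low"],
                        "ci_high": boot["ci_high"],
                        "p": boot["p"],
                    }
                )
        auc_table = pd.DataFrame(rows)
        auc_table.to_csv(out / "signature_auc.csv", index=False)
        results["auc_table"] = auc_table
        manifest["stages"].append(stage)

        if config.expression_enabled:
            stage = "voting"
            expr_cfg = ExpressionSimConfig(**{"seed": config.seed + 4, **config.expression})
            studies, expr_truth = simulate_expression_studies(expr_cfg)
            for st in studies:
                write_expression_tsv(
                    st, out / f"expression_{st.name}.tsv", out / f"labels_{st.name}.tsv"
                )
            training = [s for s in studies if s.role == "training"]
            model, ranked = train_voting_model(
                training, n_each=min(config.voting_n_each, expr_cfg.n_genes // 2),
                n_genes=config.voting_n_genes,
            )
            ranked.to_csv(out / "voting_ranked_genes.csv")
            pd.DataFrame(
                {"gene": model.genes,
                 "weighted_sx": model.weighted_sx.values,
                 "boundary": model.boundaries.values}
            ).to_csv(out / "voting_model.tsv", sep="\t", index=False)
            from .voting import normalize_study

            evaluated = evaluate_models(
                [normalize_study(s) for s in studies], ranked,
                n_range=[model.n_genes],
            )
            evaluated.to_csv(out / "voting_metrics.csv", index=False)
            results["voting_metrics"] = evaluated
            results["voting_truth"] = expr_truth
            manifest["stages"].append(stage)
    except Exception as exc:  # persist manifest naming the failed stage
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise PipelineError(stage, exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    return results
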
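"""End-to-end orchestration: simulate → splice/expression outliers →
screen → label → models → prediction → prioritization → burden.

A single :class:`PipelineConfig` (YAML-serializable) carries every stage
parameter; defaults equal the analysis thresholds (Δ >= 0.2, FDR < 0.2,
|Z| >= 1, |Δψ| >= 0.2, expected ψ <= 0.1 or >= 0.9, ±100 bp matching
window, junction min count 15, gene count filter 10 in > 50% of samples,
gnomAD 1e-4, pLI 0.9, 5-fold CV).  A global seed deterministically
derives per-stage seeds, so a rerun with the same config reproduces the
same outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from . import burden as burden_mod
from . import expression_outliers as expr_mod
from . import labeling as label_mod
from . import prioritize as prio_mod
from . import rf_model
from . import splice_outliers as splice_mod
from . import synthetic_cohort as sim_mod
from . import variant_screen as screen_mod

logger = logging.getLogger(__name__)

STAGES = [
    "simulate", "splice_outliers", "expression_outliers", "screen",
    "label", "cv", "train", "predict", "prioritize", "burden", "nmd",
]

_REQUIRES = {
    "splice_outliers": ["simulate"],
    "expression_outliers": ["simulate"],
    "screen": ["simulate"],
    "label": ["screen", "splice_outliers"],
    "cv": ["label"],
    "train": ["label"],
    "predict": ["train", "screen"],
    "prioritize": ["predict"],
    "burden": ["prioritize"],
    "nmd": ["predict", "expression_outliers"],
}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "cardiosplice_run"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    sim: sim_mod.SimConfig = field(default_factory=sim_mod.SimConfig)
    # splice outliers
    min_junction_count: int = 15
    outlier_fdr: float = 0.2
    outlier_min_z: float = 1.0
    outlier_min_dpsi: float = 0.2
    outlier_expected_low: float = 0.1
    outlier_expected_high: float = 0.9
    # expression
    expr_min_count: int = 10
    expr_min_frac: float = 0.5
    # screening
    delta_min: float = 0.2
    max_internal_carriers: int = 1
    gnomad_v2_max: float = 1e-4
    gnomad_v3_popmax_max: float = 1e-4
    # labeling
    window: int = 100
    # models
    feature_sets: list[int] = field(default_factory=lambda: [1, 2, 3, 4])
    imbalance_methods: list[str] = field(default_factory=lambda: ["weighted", "smote"])
    final_feature_set: int = 4
    final_imbalance: str = "weighted"
    n_trees: int = 500
    cv_folds: int = 5
    vote_threshold: float = 0.5
    # prioritization
    pli_min: float = 0.9

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = sim_mod.SimConfig(**self.sim)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise PipelineError(f"unknown stages: {sorted(unknown)}")
        # the global seed drives every stage
        self.sim = dataclasses.replace(self.sim, seed=self.seed)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "sim" in data and isinstance(data["sim"], dict):
            for key in ("exons_per_gene", "expr_lognormal_params", "causal_logit_coefs"):
                if key in data["sim"] and isinstance(data["sim"][key], list):
                    data["sim"][key] = tuple(data["sim"][key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def thresholds(self) -> splice_mod.OutlierThresholds:
        return splice_mod.OutlierThresholds(
            fdr=self.outlier_fdr,
            min_abs_z=self.outlier_min_z,
            min_abs_dpsi=self.outlier_min_dpsi,
            expected_low=self.outlier_expected_low,
            expected_high=self.outlier_expected_high,
        )

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order.

    Returns the artifact dictionary (in-memory results); all tabular
    outputs are also written under ``config.outdir`` along with a run
    log recording the config hash and every threshold applied.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    art: dict = {}
    enabled = [s for s in STAGES if s in config.stages]

    def _require(stage: str) -> None:
        for dep in _REQUIRES.get(stage, []):
            if dep not in art:
                raise PipelineError(f"stage '{stage}' requires missing upstream stage '{dep}'")

    for stage in enabled:
        _require(stage)
        logger.info("pipeline stage: %s", stage)
        if stage == "simulate":
            cohort = sim_mod.simulate_cohort(config.sim)
            sim_mod.write_cohort(cohort, outdir / "inputs")
            art["simulate"] = cohort

        elif stage == "splice_outliers":
            cohort = art["simulate"]
            outliers = splice_mod.find_splice_outliers(
                cohort.junction_counts,
                min_count=config.min_junction_count,
                thresholds=config.thresholds(),
            )
            outliers.to_csv(outdir / "outliers.tsv", sep="\t", index=False)
            art["splice_outliers"] = outliers

        elif stage == "expression_outliers":
            cohort = art["simulate"]
            retained = expr_mod.filter_genes(
                cohort.gene_counts, min_count=config.expr_min_count, min_frac=config.expr_min_frac
            )
            expr = expr_mod.expression_zscores(cohort.gene_counts, retained)
            expr.zscores.to_csv(outdir / "expression_z.tsv", sep="\t", index_label="sample")
            art["expression_outliers"] = expr

        elif stage == "screen":
            cohort = art["simulate"]
            screened = screen_mod.screen_variants(
                cohort.variants,
                delta_min=config.delta_min,
                max_internal_carriers=config.max_internal_carriers,
            )
            screened = screen_mod.annotate_features(screened, cohort.genes, cohort.tpm)
            screened.to_csv(outdir / "screened_variants.tsv", sep="\t", index=False)
            art["screen"] = screened

        elif stage == "label":
            cohort = art["simulate"]
            screened = art["screen"]
            cases = set(cohort.case_samples)
            in_cases = screened["sample"].map(
                lambda v: all(s in cases for s in screen_mod._carrier_list(v))
            )
            labeled = label_mod.label_variants(
                screened.loc[in_cases], art["splice_outliers"], window=config.window
            )
            labeled.to_csv(outdir / "labeled_variants.tsv", sep="\t", index=False)
            gene_set = {g.gene_id for g in cohort.genes if g.tier in (1, 2)}
            orphans = label_mod.orphan_events(
                art["splice_outliers"], screened.loc[in_cases], gene_set, window=config.window
            )
            orphans.to_csv(outdir / "orphan_events.tsv", sep="\t", index=False)
            try:
                enrich = label_mod.univariate_enrichment(labeled)
                enrich.to_csv(outdir / "enrichment.tsv", sep="\t")
                art["enrichment"] = enrich
            except ValueError as exc:
                logger.warning("enrichment skipped: %s", exc)
            art["label"] = labeled
            art["orphans"] = orphans

        elif stage == "cv":
            labeled = art["label"]
            rows = []
            cv_results = {}
            for fs in config.feature_sets:
                for imb in config.imbalance_methods:
                    mc = rf_model.ModelConfig(
                        feature_set=fs, imbalance=imb, n_trees=config.n_trees,
                        cv_folds=config.cv_folds, vote_threshold=config.vote_threshold,
                        seed=config.stage_seed(f"cv:{fs}:{imb}"),
                    )
                    res = rf_model.cross_validate(labeled, mc)
                    cv_results[(fs, imb)] = res
                    row = dict(feature_set=fs, imbalance=imb, **res.pooled.as_dict())
                    rows.append(row)
            cv_df = pd.DataFrame(rows)
            cv_df.to_csv(outdir / "cv_metrics.tsv", sep="\t", index=False)
            art["cv"] = cv_results
            art["cv_metrics"] = cv_df

        elif stage == "train":
            labeled = art["label"]
            mc = rf_model.ModelConfig(
                feature_set=config.final_feature_set, imbalance=config.final_imbalance,
                n_trees=config.n_trees, cv_folds=config.cv_folds,
                vote_threshold=config.vote_threshold, seed=config.stage_seed("train"),
            )
            X, y = rf_model.make_training_set(labeled, mc.feature_set)
            fitted = rf_model.train_model(X, y, mc)
            joblib.dump(fitted, outdir / "model.joblib")
            imp = rf_model.feature_importance(fitted)
            imp.rename("importance").to_csv(outdir / "importances.tsv", sep="\t", index_label="feature")
            art["train"] = fitted

        elif stage == "predict":
            fitted = art["train"]
            screened = art["screen"]
            Xall = screened[fitted.features].astype(float)
            complete = Xall.notna().all(axis=1)
            scores = pd.Series(np.nan, index=screened.index, name="model_score")
            if complete.any():
                scores.loc[complete] = fitted.score(Xall.loc[complete])
            pred = screened.copy()
            pred["model_score"] = scores
            pred["selected"] = scores >= config.vote_threshold
            pred.to_csv(outdir / "predicted.tsv", sep="\t", index=False)
            art["predict"] = pred

        elif stage == "prioritize":
            cohort = art["simulate"]
            pred = art["predict"]
            selected = pred.loc[pred["selected"]]
            hc = screen_mod.rare_in_controls(
                selected, v2_max=config.gnomad_v2_max, v3_popmax_max=config.gnomad_v3_popmax_max
            )
            prioritized = prio_mod.prioritize_variants(hc, cohort.genes)
            prioritized.to_csv(outdir / "prioritized.tsv", sep="\t", index=False)
            art["prioritize"] = prioritized

        elif stage == "burden":
            cohort = art["simulate"]
            prioritized = art["prioritize"]
            case_s, ctrl_s = cohort.case_samples, cohort.control_samples
            syn_counts = burden_mod.count_synonymous(
                cohort.variants, cohort.samples,
                max_internal_carriers=config.max_internal_carriers,
                v2_max=config.gnomad_v2_max, v3_popmax_max=config.gnomad_v3_popmax_max,
            )
            med_ca, med_co, syn_p = burden_mod.synonymous_burden(
                syn_counts[case_s], syn_counts[ctrl_s]
            )
            tier1 = {g.gene_id for g in cohort.genes if g.tier == 1}
            tier12 = {g.gene_id for g in cohort.genes if g.tier in (1, 2)}
            tier2_pli = {g.gene_id for g in cohort.genes if g.tier == 2 and g.pli >= config.pli_min}
            strata: list[tuple[str, set | None, str | None]] = [
                ("all_genes", None, None),
                ("tier1_2", tier12, None),
                ("tier1", tier1, None),
                ("tier2_pli09", tier2_pli, None),
            ]
            for rc in prio_mod.REGION_CLASSES:
                strata.append((f"tier1_2:{rc}", tier12, rc))
            rows = [
                burden_mod.carrier_burden(case_s, ctrl_s, prioritized,
                                          gene_set=gs, region_class=rc, stratum_name=name).as_dict()
                for name, gs, rc in strata
            ]
            bdf = pd.DataFrame(rows)
            bdf.to_csv(outdir / "burden.tsv", sep="\t", index=False)
            art["burden"] = bdf
            art["synonymous_burden"] = dict(median_cases=med_ca, median_controls=med_co, pvalue=syn_p)

        elif stage == "nmd":
            cohort = art["simulate"]
            pred = art["predict"]
            expr = art["expression_outliers"]
            cases = set(cohort.case_samples)
            in_cases = pred["sample"].map(
                lambda v: all(s in cases for s in screen_mod._carrier_list(v))
            )
            case_pred = pred.loc[in_cases & pred["model_score"].notna()]
            sel = case_pred.loc[case_pred["selected"]]
            rej = case_pred.loc[~case_pred["selected"]]
            if len(sel) and len(rej):
                res = expr_mod.nmd_check(expr, sel, rej)
                art["nmd"] = res
                pd.DataFrame([res.__dict__]).to_csv(outdir / "nmd.tsv", sep="\t", index=False)
            else:
                logger.warning("nmd stage skipped: empty selected or rejected group")

    log = {
        "config_hash": config.config_hash,
        "stages_run": [s for s in enabled if s in art or s in ("nmd",)],
        "thresholds": {
            "delta_min": config.delta_min,
            "max_internal_carriers": config.max_internal_carriers,
            "min_junction_count": config.min_junction_count,
            "outlier_fdr": config.outlier_fdr,
            "outlier_min_z": config.outlier_min_z,
            "outlier_min_dpsi": config.outlier_min_dpsi,
            "outlier_expected_low": config.outlier_expected_low,
            "outlier_expected_high": config.outlier_expected_high,
            "expr_min_count": config.expr_min_count,
            "expr_min_frac": config.expr_min_frac,
            "window": config.window,
            "gnomad_v2_max": config.gnomad_v2_max,
            "gnomad_v3_popmax_max": config.gnomad_v3_popmax_max,
            "vote_threshold": config.vote_threshold,
            "pli_min": config.pli_min,
            "cv_folds": config.cv_folds,
        },
        "seed": config.seed,
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    art["run_log"] = log
    return art
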
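"""End-to-end orchestration: simulate -> segment -> extract -> screen -> survive -> classify.

Every stage is seeded from the single pipeline seed; rerunning with the same
configuration produces byte-identical JSON and Markdown reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classifier import BRFConfig, evaluate, fit_brf
from .features import ExtractionConfig, extract_all, feature_schema
from .robustness import intersect_robust, screen, screen_summary
from .segmentation import MASK_LABELS, make_mask_set
from .survival import (
    ENCoxConfig,
    evaluate_selection,
    kaplan_meier,
    logrank,
    mean_split_groups,
    nested_select,
    preprocess,
    risk_score,
    split_train_test,
)
from .synthetic import CohortSpec, PhantomSpec, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "toy_config"]

log = logging.getLogger(__name__)

SCHEMA_VERSION = "petrad-pipeline-1"

MODEL_VARIANTS = ("clinical", "radiomics", "composite")


@dataclass
class PipelineConfig:
    seed: int = 0
    n_subjects: int = 99
    phantom: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    fractions: tuple[float, float, float] = (0.35, 0.40, 0.45)
    bin_widths: tuple[float, ...] = (5.0, 25.0, 75.0)
    resample_options: tuple[bool, ...] = (False, True)
    target_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    feature_classes: tuple[str, ...] = ("firstorder", "shape", "glcm", "glrlm", "glszm", "ngtdm", "gldm")
    log_sigmas_mm: tuple[float, ...] = (2.0, 4.0)
    use_wavelet: bool = True
    reference_mask: str = "suv40"
    icc_threshold: float = 0.75
    test_fraction: float = 0.2
    encox: dict = field(default_factory=dict)
    brf: dict = field(default_factory=dict)
    schema_version: str = SCHEMA_VERSION

    def extraction_configs(self) -> list[ExtractionConfig]:
        configs = []
        for bw in self.bin_widths:
            for rs in self.resample_options:
                configs.append(
                    ExtractionConfig(
                        bin_width=bw,
                        resample=rs,
                        target_spacing_mm=self.target_spacing_mm,
                        log_sigmas_mm=self.log_sigmas_mm,
                        feature_classes=self.feature_classes,
                        use_wavelet=self.use_wavelet,
                        config_id=f"bw{bw:g}_{'rs' if rs else 'orig'}",
                    )
                )
        return configs

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.pop("schema_version", None)
        cfg = cls(**raw)
        for name in ("fractions", "bin_widths", "resample_options", "target_spacing_mm",
                     "feature_classes", "log_sigmas_mm"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        for nested in (cfg.encox, cfg.brf, cfg.cohort, cfg.phantom):
            for key, val in nested.items():
                if isinstance(val, list):
                    nested[key] = tuple(val)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def toy_config(seed: int = 0) -> PipelineConfig:
    """A small configuration for smoke tests and determinism checks."""
    return PipelineConfig(
        seed=seed,
        n_subjects=24,
        phantom=dict(grid_shape=(20, 20, 14), spacing_mm=(3.0, 3.0, 3.0),
                     lesion_radius_mm=12.0, noise_sd=0.0),
        cohort=dict(beta_true={"heterogeneity_sd": 1.2, "suv_max": -0.8},
                    param_ranges={"heterogeneity_sd": (0.05, 0.45),
                                  "texture_scale_mm": (3.0, 9.0),
                                  "suv_max": (4.0, 16.0)}),
        bin_widths=(5.0, 25.0),
        resample_options=(False,),
        feature_classes=("firstorder", "glcm"),
        log_sigmas_mm=(),
        use_wavelet=False,
        encox=dict(l1_ratio_grid=(0.5, 0.9), n_alphas=10, outer_folds=3,
                   inner_folds=3, inner_repeats=2, n_select=7),
        brf=dict(max_depth=(3,), n_estimators=(25,), min_samples_split=(2,),
                 min_samples_leaf=(1,), max_features=("sqrt",), bootstrap=(True,),
                 criterion=("gini",), cv_folds=3),
    )


def _spawn_seed(base: int, *salts: int) -> int:
    out = base
    for s in salts:
        out = (out * 1000003 + s + 1) % (2**31 - 1)
    return out


def _clinical_columns(subjects) -> tuple[list[str], list[str]]:
    continuous, categorical = [], []
    for key, val in subjects[0].clinical.items():
        (continuous if isinstance(val, float) else categorical).append(key)
    return continuous, categorical


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full workflow; writes report.json / report.md plus KM curves.

    Returns the report dictionary.  Any stage failure aborts with the stage
    name; partial outputs written so far are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"schema_version": config.schema_version, "seed": config.seed}
    stage = "simulate"
    try:
        pspec = PhantomSpec(**config.phantom)
        cspec = CohortSpec(n_subjects=config.n_subjects, seed=config.seed, **config.cohort)
        subjects = generate_cohort(cspec, pspec)
        report["simulate"] = {"n_subjects": len(subjects),
                              "n_events": int(sum(s.event for s in subjects))}

        stage = "segment"
        mask_sets = []
        for i, s in enumerate(subjects):
            mask_sets.append(
                make_mask_set(
                    s.volume, s.true_mask, true_mask=s.true_mask,
                    fractions=config.fractions,
                    surrogate_seed=_spawn_seed(config.seed, 1, i),
                )
            )
        report["segment"] = {
            "labels": list(MASK_LABELS),
            "mean_voxels": {
                lab: float(np.mean([ms[lab].sum() for ms in mask_sets])) for lab in MASK_LABELS
            },
        }

        stage = "extract"
        configs = config.extraction_configs()
        ref_config = configs[0]
        schema = feature_schema(ref_config)
        # family 1: extraction parameters (reference contour, all configs)
        rows_param = []
        for i, (s, ms) in enumerate(zip(subjects, mask_sets)):
            for cfg in configs:
                fv = extract_all(s.volume, ms[config.reference_mask], cfg)
                rows_param.append({"subject": s.subject_id, "rater": cfg.config_id, **fv.as_dict()})
        # family 2: contour variants (reference config, all five contours)
        rows_contour = []
        for i, (s, ms) in enumerate(zip(subjects, mask_sets)):
            for lab in MASK_LABELS:
                fv = extract_all(s.volume, ms[lab], ref_config)
                rows_contour.append({"subject": s.subject_id, "rater": lab, **fv.as_dict()})
        df_param = pd.DataFrame(rows_param)
        df_contour = pd.DataFrame(rows_contour)
        report["extract"] = {"n_features": len(schema), "n_param_sets": len(configs)}

        stage = "screen"
        from .robustness import feature_tensor

        tensors_param = feature_tensor(df_param, "subject", "rater")
        tensors_contour = feature_tensor(df_contour, "subject", "rater")
        robust_param, icc_param = screen(tensors_param, config.icc_threshold)
        robust_contour, icc_contour = screen(tensors_contour, config.icc_threshold)
        final_features = intersect_robust(robust_param, robust_contour)
        icc_param.to_csv(out / "icc_params.csv", index=False)
        icc_contour.to_csv(out / "icc_contours.csv", index=False)
        report["screen"] = {
            "params": screen_summary(len(robust_param), len(schema)),
            "contours": screen_summary(len(robust_contour), len(schema)),
            "final_count": len(final_features),
        }

        stage = "survive"
        # assemble the modeling table: radiomics at the reference (config, contour)
        ref_rows = df_param[df_param["rater"] == ref_config.config_id].set_index("subject")
        data = ref_rows[final_features].copy()
        for s in subjects:
            for k, v in s.clinical.items():
                data.loc[s.subject_id, k] = v
        surv = pd.DataFrame(
            {
                "time_days": [s.survival_time_days for s in subjects],
                "event": [s.event for s in subjects],
                "one_year_dead": [s.one_year_dead for s in subjects],
            },
            index=[s.subject_id for s in subjects],
        )
        data = data.join(surv)
        continuous_clin, categorical_clin = _clinical_columns(subjects)

        train, test = split_train_test(
            data, config.test_fraction, seed=config.seed, event_col="one_year_dead",
            strat_cols=tuple(c for c in ("gender",) if c in data.columns),
        )
        Xc_train, Xc_test = preprocess(train, test, continuous_clin, categorical_clin)
        Xr_train, Xr_test = preprocess(train, test, final_features, [])
        variant_features = {
            "clinical": (Xc_train, Xc_test),
            "radiomics": (Xr_train, Xr_test),
            "composite": (Xc_train.join(Xr_train), Xc_test.join(Xr_test)),
        }

        encox = ENCoxConfig(seed=config.seed, **config.encox)
        report["survive"] = {}
        selections = {}
        for variant in MODEL_VARIANTS:
            Xtr, Xte = variant_features[variant]
            sel = nested_select(Xtr, train["time_days"], train["event"], encox)
            ci = evaluate_selection(sel, Xte, test["time_days"], test["event"])
            scores = risk_score(sel.final_coefficients, Xte)
            entry = {
                "selected": sel.selected,
                "coefficients": {k: round(v, 6) for k, v in sel.final_coefficients.items()},
                "outer_concordance": [round(s, 4) for s in sel.outer_scores],
                "winner_fold": sel.winner_fold,
                "test_concordance": round(ci, 4),
            }
            try:
                high = mean_split_groups(scores)
                t = test["time_days"].to_numpy()
                e = test["event"].to_numpy()
                chi2, p = logrank(t[high], e[high], t[~high], e[~high])
                entry["logrank_chi2"] = round(chi2, 4)
                entry["logrank_p"] = float(f"{p:.6g}")
                for name, sel_mask in (("high", high), ("low", ~high)):
                    km_t, km_s = kaplan_meier(t[sel_mask], e[sel_mask])
                    pd.DataFrame({"time_days": km_t, "survival": km_s}).to_csv(
                        out / f"km_{variant}_{name}.csv", index=False
                    )
            except ValueError as exc:
                entry["logrank_error"] = str(exc)
            report["survive"][variant] = entry
            selections[variant] = sel

        stage = "classify"
        brf_cfg = BRFConfig(seed=config.seed, **config.brf)
        report["classify"] = {}
        for variant in MODEL_VARIANTS:
            Xtr, Xte = variant_features[variant]
            feats = selections[variant].selected
            model, search = fit_brf(Xtr[feats].to_numpy(), train["one_year_dead"].to_numpy(), brf_cfg)
            metrics, roc_points = evaluate(model, Xte[feats].to_numpy(), test["one_year_dead"].to_numpy())
            pd.DataFrame(roc_points, columns=["fpr", "tpr", "threshold"]).to_csv(
                out / f"roc_{variant}.csv", index=False
            )
            report["classify"][variant] = {
                "best_params": {k: (v if v is None or isinstance(v, (int, bool, str)) else float(v))
                                for k, v in search["best_params"].items()},
                "cv_auc": round(search["best_cv_auc"], 4),
                **metrics.as_dict(),
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    _write_markdown(report, out / "report.md")
    return report


def _write_markdown(report: dict, path: Path) -> None:
    lines = ["# Pipeline report", ""]
    lines.append(f"Seed: {report['seed']}  ")
    lines.append(f"Subjects: {report['simulate']['n_subjects']} "
                 f"({report['simulate']['n_events']} events)")
    lines.append("")
    scr = report["screen"]
    lines.append("## Robustness screening")
    lines.append(f"- extraction parameters: {scr['params']['robust_count']}/{scr['params']['total']} "
                 f"robust ({scr['params']['percentage']}%)")
    lines.append(f"- contour variants: {scr['contours']['robust_count']}/{scr['contours']['total']} "
                 f"robust ({scr['contours']['percentage']}%)")
    lines.append(f"- final intersected features: {scr['final_count']}")
    lines.append("")
    lines.append("## Models")
    lines.append("| Model | Concordance (survival) | Accuracy (1-year) | AUC | Sens | Spec |")
    lines.append("|---|---|---|---|---|---|")
    for variant in MODEL_VARIANTS:
        s = report["survive"][variant]
        c = report["classify"][variant]
        lines.append(
            f"| {variant} | {s['test_concordance']} | {c['accuracy']} | "
            f"{c['auc']} | {c['sensitivity']} | {c['specificity']} |"
        )
    lines.append("")
    for variant in MODEL_VARIANTS:
        s = report["survive"][variant]
        if "logrank_chi2" in s:
            lines.append(f"- {variant} logrank chi2 = {s['logrank_chi2']}, p = {s['logrank_p']}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
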
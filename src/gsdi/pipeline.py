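"""End-to-end orchestration: simulate -> reference -> metrics -> two-stage
index -> high-specificity evaluation, with a machine- and human-readable
report bundle.

The run writes, under the output directory: the cohort eye table, the
stage-1 weight table (variable group x NFL/GCC weight with the AUC after
combining), the fitted model coefficients, the cross-validated ROC points,
a high-specificity cutoff table, a severity-stratified performance table,
and a manifest recording the seed, sizes and package versions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluate import (compare_auc, loo_cv_scores, roc_curve, stage_table,
                       stage_stratified_performance)
from .index import (apply_stage1, build_feature_table, fit_gsdi, fit_stage1,
                    hosmer_lemeshow, published_gsdi)
from .io import write_cohort
from .reference import build_reference
from .simulate import SimulationConfig, generate_cohort
from .staging import StageBoundaries, classify_gss2, default_boundaries

#: variables where a *lower* value indicates disease
_LOWER_IS_WORSE = ("_um", "rim_volume")

#: severity bins used for the stage-stratified table
STAGE_BINS = ("<1", "1", "2", "3", "4-5")
_STAGE_TO_BIN = {"0": "<1", "borderline": "<1", "1": "1", "2": "2",
                 "3": "3", "4": "4-5", "5": "4-5"}


@dataclass
class RunConfig:
    """Full run configuration: simulation conditions, loss-metric cutoffs,
    model and CV options, and evaluation targets."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    flv_p_cutoff: float = 0.05
    model: str = "fitted"            # fitted | published
    cv_unit: str = "subject"         # subject | eye
    specificities: tuple[float, ...] = (0.99, 0.95)
    pauc_band: tuple[float, float] = (0.90, 1.00)
    n_boot: int = 500
    seed: int = 0
    write_maps: bool = False         # cohort map matrices are bulky

    def __post_init__(self) -> None:
        if self.model not in ("fitted", "published"):
            raise ValueError("model must be 'fitted' or 'published'")
        if self.cv_unit not in ("subject", "eye"):
            raise ValueError("cv_unit must be 'subject' or 'eye'")
        if not all(0.0 < s < 1.0 for s in self.specificities):
            raise ValueError("specificity targets must lie in (0, 1)")
        lo, hi = self.pauc_band
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError("pauc_band must satisfy 0 <= lo < hi <= 1")
        if not 0.0 < self.flv_p_cutoff < 1.0:
            raise ValueError("flv_p_cutoff must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("sim", {}))
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name == "sim":
                continue
            if f.name in raw:
                v = raw.pop(f.name)
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        cfg = cls(sim=sim, **kwargs)
        cfg.sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
        return cfg


def _oriented(scores: pd.Series, var: str) -> np.ndarray:
    """Orient a raw variable so that higher = more diseased."""
    flip = any(tok in var for tok in _LOWER_IS_WORSE)
    return -scores.to_numpy() if flip else scores.to_numpy()


def single_variable_aucs(table: pd.DataFrame,
                         variables: list[str]) -> pd.Series:
    labels = table["label"].to_numpy()
    return pd.Series(
        {v: roc_curve(_oriented(table[v], v), labels).auc for v in variables}
    ).sort_values(ascending=False)


def run_pipeline(config: RunConfig, out_dir=None,
                 boundaries: StageBoundaries | None = None) -> dict:
    """Execute the full study pipeline; optionally write the report bundle.

    Returns a JSON-serializable results dictionary; when ``out_dir`` is
    given, :func:`write_report` persists the bundle there.
    """
    boundaries = boundaries or default_boundaries()
    sim = dataclasses.replace(config.sim, seed=config.seed)
    stage = "simulate"
    try:
        cohort = generate_cohort(sim, boundaries)

        stage = "reference"
        r_eyes = [e for e in cohort if e.group == "R"]
        test_eyes = [e for e in cohort if e.group != "R"]
        ref = build_reference(r_eyes)

        stage = "metrics"
        table = build_feature_table(test_eyes, ref)
        panel = list(ref.scalar_stats.index.drop(["hcdr", "rim_volume"],
                                                 errors="ignore"))
        aucs = single_variable_aucs(table, panel + ["hcdr", "rim_volume"])

        stage = "stage-1"
        weights = fit_stage1(table)
        composites = apply_stage1(table, weights)
        labels = table["label"].to_numpy()
        weight_rows = []
        for g, w in weights.items():
            comp = composites[f"composite_{g.lower()}"]
            flip = g not in ("GLV", "FLV")
            auc_g = roc_curve(-comp if flip else comp, labels).auc
            weight_rows.append({"group": g,
                                "nfl_weight_pct": w.nfl_weight,
                                "gcc_weight_pct": w.gcc_weight,
                                "auc_after_combining": auc_g})
        weight_df = pd.DataFrame(weight_rows)

        stage = "stage-2"
        if config.model == "published":
            model = published_gsdi()
            hl = None
        else:
            model = fit_gsdi(composites)
            in_sample = model.predict(composites)
            hl = hosmer_lemeshow(np.clip(in_sample, 1e-12, 1 - 1e-12), labels)

        stage = "evaluate"
        cv = loo_cv_scores(table, unit=config.cv_unit, model=config.model)
        roc_cv = roc_curve(cv.scores.to_numpy(), labels)
        lo, hi = config.pauc_band
        pauc_gsdi = roc_cv.partial_auc(lo, hi)

        cutoff_rows = []
        for target in config.specificities:
            thr, sens = roc_cv.sensitivity_at(target)
            cutoff_rows.append({"variable": "GSDI", "target_specificity": target,
                                "cutoff": thr, "sensitivity": sens})
        best_var = aucs.index[0]
        best_scores = _oriented(table[best_var], best_var)
        roc_best = roc_curve(best_scores, labels)
        pauc_best = roc_best.partial_auc(lo, hi)
        for target in config.specificities:
            thr, sens = roc_best.sensitivity_at(target)
            cutoff_rows.append({"variable": best_var,
                                "target_specificity": target,
                                "cutoff": thr, "sensitivity": sens})
        cutoff_df = pd.DataFrame(cutoff_rows)

        d_auc, p_auc = compare_auc(
            cv.scores.to_numpy(), best_scores, labels,
            subjects=table["subject_id"].to_numpy(),
            n_resamples=config.n_boot, seed=config.seed + 1)

        case_stage = classify_gss2(table["md_db"].to_numpy(),
                                   table["psd_db"].to_numpy(), boundaries)
        stage_bins = np.array([_STAGE_TO_BIN[str(s)] for s in case_stage],
                              dtype=object)
        perf = stage_stratified_performance(
            cv.scores.to_numpy(), labels, stage_bins,
            targets=tuple(config.specificities), stage_order=list(STAGE_BINS))
        stage_df = stage_table(perf)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    results = {
        "manifest": {
            "seed": config.seed,
            "gsdi_version": __version__,
            "model": config.model,
            "cv_unit": config.cv_unit,
            "n_reference_eyes": len(r_eyes),
            "n_normal_eyes": int((labels == 0).sum()),
            "n_glaucoma_eyes": int((labels == 1).sum()),
            "n_subjects": int(table["subject_id"].nunique()),
            "cv_folds_skipped": list(cv.skipped),
        },
        "model": {
            "source": model.source,
            "params": {k: float(v) for k, v in model.params.items()},
            "standardized_weights": {k: float(v) for k, v
                                     in model.standardized_weights.items()},
            "pvalues": {k: (None if np.isnan(v) else float(v))
                        for k, v in model.pvalues.items()},
            "hosmer_lemeshow": None if hl is None else {
                "statistic": hl.statistic, "pvalue": hl.pvalue, "df": hl.df},
        },
        "stage1_weights": weight_df.to_dict(orient="records"),
        "single_variable_aucs": {k: float(v) for k, v in aucs.items()},
        "evaluation": {
            "cv_auc": roc_cv.auc,
            "best_single_variable": best_var,
            "best_single_auc": float(aucs.iloc[0]),
            "delta_auc_vs_best_single": d_auc,
            "p_vs_best_single": p_auc,
            "pauc_band": [lo, hi],
            "pauc_gsdi": pauc_gsdi,
            "pauc_best_single": pauc_best,
            "pauc_improvement_pct":
                100.0 * (pauc_gsdi - pauc_best) / pauc_best,
            "cutoffs": cutoff_df.to_dict(orient="records"),
        },
        "stage_stratified": stage_df.to_dict(orient="records"),
    }

    if out_dir is not None:
        write_report(results, out_dir)
        out = Path(out_dir)
        pd.DataFrame({
            "subject_id": table["subject_id"], "eye": table["eye"],
            "group": table["group"], "label": table["label"],
            "md_db": table["md_db"], "psd_db": table["psd_db"],
            "gsdi_cv": cv.scores,
        }).to_csv(out / "cv_scores.csv", index=False, float_format="%.6f")
        weight_df.to_csv(out / "stage1_weights.csv", index=False,
                         float_format="%.6f")
        cutoff_df.to_csv(out / "cutoffs.csv", index=False, float_format="%.6f")
        stage_df.to_csv(out / "stage_performance.csv", index=False,
                        float_format="%.6f")
        pd.DataFrame({"specificity": roc_cv.specificity,
                      "sensitivity": roc_cv.sensitivity}
                     ).to_csv(out / "roc_points.csv", index=False,
                              float_format="%.6f")
        if config.write_maps:
            write_cohort(cohort, out / "cohort")
        else:
            pd.DataFrame([{
                "subject_id": e.subject_id, "eye": e.eye, "group": e.group,
                "md_db": e.md_db, "psd_db": e.psd_db, "vcdr": e.disc.vcdr,
                "true_stage": e.true_stage or "",
            } for e in cohort]).to_csv(out / "cohort_eyes.csv", index=False,
                                       float_format="%.6f")
    return results


def write_report(results: dict, path) -> Path:
    """Persist a results dict as report.json + a readable report.md."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(results, fh, indent=2)

    ev = results["evaluation"]
    man = results["manifest"]
    lines = [
        "# GSDI run report",
        "",
        f"- seed: {man['seed']}",
        f"- eyes: {man['n_normal_eyes']} normal / "
        f"{man['n_glaucoma_eyes']} glaucoma "
        f"(+{man['n_reference_eyes']} reference)",
        f"- model: {results['model']['source']}, CV unit: {man['cv_unit']}",
        "",
        f"Cross-validated AUC: {ev['cv_auc']:.3f} "
        f"(best single variable {ev['best_single_variable']}: "
        f"{ev['best_single_auc']:.3f}, p={ev['p_vs_best_single']:.3f})",
        f"Partial AUC {ev['pauc_band'][0]:.0%}-{ev['pauc_band'][1]:.0%} "
        f"specificity: {ev['pauc_gsdi']:.4f} vs {ev['pauc_best_single']:.4f} "
        f"({ev['pauc_improvement_pct']:+.0f}%)",
        "",
        "| variable | target specificity | cutoff | sensitivity |",
        "|---|---|---|---|",
    ]
    for row in ev["cutoffs"]:
        lines.append(f"| {row['variable']} | {row['target_specificity']:.2f} "
                     f"| {row['cutoff']:.4f} | {row['sensitivity']:.3f} |")
    lines += ["", "| stage | n cases | AUC | sens@99% | sens@95% |",
              "|---|---|---|---|---|"]
    for row in results["stage_stratified"]:
        lines.append(
            f"| {row['stage']} | {row['n_cases']} | {row['auc']:.3f} "
            f"| {row['sens_at_99_spec']:.3f} | {row['sens_at_95_spec']:.3f} |")
    (out / "report.md").write_text("\n".join(lines) + "\n")
    return out
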
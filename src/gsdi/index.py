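"""Two-stage construction of the glaucoma structural diagnostic index.

Stage 1 combines the NFL and GCC member of each variable group (overall,
superior, inferior thickness; GLV; FLV) into a composite via a bivariate
logistic fit on R-group-standardized values: the composite is the convex
combination of the two z-scores weighted by the absolute coefficient
shares.  Stage 2 fits a multivariate logistic model on composite overall
thickness (z scale), composite FLV (% scale) and the raw vertical
cup-to-disc ratio; the index is the logistic transform of that linear
predictor, in (0, 1), higher = more likely glaucomatous.

The published model ships as a fixed scorer:

    GSDI = logistic(-0.74 * composite_overall + 0.70 * composite_FLV
                    + 3.37 * VCDR - 3.69)

with standardized weight shares 38 / 28 / 34 (%).  The VCDR coefficient
applies to the non-standardized ratio; the FLV coefficient applies per 1%
of composite focal loss volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as _stats
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .metrics import compute_all_metrics
from .reference import NormativeReference, standardize

#: stage-1 variable groups -> (nfl column, gcc column) of the feature table
PAIR_GROUPS: dict[str, tuple[str, str]] = {
    "overall": ("z_nfl_overall_um", "z_gcc_overall_um"),
    "superior": ("z_nfl_superior_um", "z_gcc_superior_um"),
    "inferior": ("z_nfl_inferior_um", "z_gcc_inferior_um"),
    "GLV": ("z_nfl_glv_pct", "z_gcc_glv_pct"),
    "FLV": ("z_nfl_flv_pct", "z_gcc_flv_pct"),
}

GSDI_EXOG = ("composite_overall", "composite_flv", "vcdr")


def logistic(x):
    """1 / (1 + exp(-x)): strictly increasing log-odds -> probability."""
    return expit(x)


# --------------------------------------------------------------------------
# shared logistic fitting with a penalized fallback on separation
# --------------------------------------------------------------------------

class SeparationWarning(UserWarning):
    """Raised (as a warning) when an unpenalized fit failed and a weakly
    L2-penalized fallback was used instead."""


def _fit_logit(X: np.ndarray, y: np.ndarray):
    """Unpenalized ML logistic fit; weakly penalized fallback on failure.

    Returns (params, bse, pvalues, penalized) where params[0] is the
    intercept.  bse/pvalues are NaN under the fallback (Wald theory does
    not apply to the penalized fit).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xc = sm.add_constant(X, has_constant="add")
    params = bse = pvalues = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        ok = bool(res.mle_retvals.get("converged", False))
        if ok and np.abs(res.params).max() < 30 and np.isfinite(res.bse).all():
            params, bse, pvalues = (np.asarray(res.params),
                                    np.asarray(res.bse),
                                    np.asarray(res.pvalues))
    except Exception:
        pass
    if params is not None:
        return params, bse, pvalues, False

    warnings.warn(
        "unpenalized logistic fit failed (separation or non-convergence); "
        "falling back to a weakly L2-penalized fit",
        SeparationWarning, stacklevel=3)
    clf = LogisticRegression(penalty="l2", C=10.0, solver="lbfgs", max_iter=2000)
    clf.fit(X, y)
    params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
    nan = np.full(params.shape, np.nan)
    return params, nan, nan, True


# --------------------------------------------------------------------------
# stage 1: pairwise NFL/GCC composites
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CompositeWeights:
    """NFL/GCC weight shares (%) for one variable group; they sum to 100."""

    group: str
    nfl_weight: float
    gcc_weight: float

    def __post_init__(self) -> None:
        if self.nfl_weight < 0 or self.gcc_weight < 0:
            raise ValueError("weights must be non-negative")
        if abs(self.nfl_weight + self.gcc_weight - 100.0) > 1e-6:
            raise ValueError("weights must sum to 100")


def fit_pair_weights(nfl_std, gcc_std, labels, group: str = "") -> CompositeWeights:
    """Optimal NFL/GCC weight shares from a bivariate logistic fit.

    Inputs must be standardized against the reference group.  The share of
    each member is its absolute coefficient over the absolute-coefficient
    sum, x100.
    """
    nfl_std = np.asarray(nfl_std, dtype=float)
    gcc_std = np.asarray(gcc_std, dtype=float)
    y = np.asarray(labels, dtype=float)
    if not (0 < y.sum() < y.size):
        raise ValueError("need at least one case and one control")
    params, _, _, _ = _fit_logit(np.column_stack([nfl_std, gcc_std]), y)
    a, b = abs(params[1]), abs(params[2])
    if a + b == 0:
        raise ValueError("both coefficients are zero; weights undefined")
    return CompositeWeights(group=group, nfl_weight=100.0 * a / (a + b),
                            gcc_weight=100.0 * b / (a + b))


def composite_value(nfl_std, gcc_std, w: CompositeWeights):
    """Convex combination (nfl_weight * nfl + gcc_weight * gcc) / 100."""
    return (w.nfl_weight * np.asarray(nfl_std, dtype=float)
            + w.gcc_weight * np.asarray(gcc_std, dtype=float)) / 100.0


def fit_stage1(table: pd.DataFrame,
               label_col: str = "label") -> dict[str, CompositeWeights]:
    """Fit composite weights for every variable group on a feature table."""
    return {
        g: fit_pair_weights(table[nfl], table[gcc], table[label_col], group=g)
        for g, (nfl, gcc) in PAIR_GROUPS.items()
    }


def apply_stage1(table: pd.DataFrame,
                 weights: dict[str, CompositeWeights]) -> pd.DataFrame:
    """Append composite columns to a feature table.

    Adds ``composite_<group>`` (z scale) for each group plus
    ``composite_flv`` on the raw % scale (the stage-2 FLV input), built
    with the FLV group's weights.
    """
    out = table.copy()
    for g, (nfl, gcc) in PAIR_GROUPS.items():
        out[f"composite_{g.lower()}"] = composite_value(
            table[nfl], table[gcc], weights[g])
    w = weights["FLV"]
    out["composite_flv"] = (w.nfl_weight * table["nfl_flv_pct"]
                            + w.gcc_weight * table["gcc_flv_pct"]) / 100.0
    return out


# --------------------------------------------------------------------------
# feature table: cohort + reference -> per-eye standardized variable panel
# --------------------------------------------------------------------------

def build_feature_table(cohort, ref: NormativeReference) -> pd.DataFrame:
    """Per-eye table of raw and R-standardized diagnostic variables.

    Columns: identity (subject_id, eye, group, label, stage via MD/PSD is
    left to the caller), the raw variable panel, and ``z_<var>`` columns
    standardized against the reference.  ``label`` is 1 for PG eyes.
    """
    rows = []
    for e in cohort:
        s = compute_all_metrics(e, ref).to_series()
        row = {"subject_id": e.subject_id, "eye": e.eye, "group": e.group,
               "label": int(e.group == "PG"),
               "true_stage": e.true_stage,
               "md_db": e.md_db, "psd_db": e.psd_db}
        row.update(s.to_dict())
        for var in ref.scalar_stats.index:
            row[f"z_{var}"] = float(standardize(s[var], var, ref))
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# stage 2: the GSDI logistic model
# --------------------------------------------------------------------------

class GSDIModel:
    """Multivariate logistic model for the structural diagnostic index.

    Built from per-eye stage-1 composites: ``exog`` columns are
    composite overall thickness (z), composite FLV (%), and VCDR (raw
    ratio); ``endog`` is the 0/1 glaucoma label.  ``fit`` returns a
    :class:`GSDIResults`.
    """

    def __init__(self, endog, exog: pd.DataFrame):
        exog = pd.DataFrame(exog)
        missing = [c for c in GSDI_EXOG if c not in exog.columns]
        if missing:
            raise ValueError(f"exog is missing columns {missing}")
        self.exog = exog.loc[:, list(GSDI_EXOG)].astype(float)
        self.endog = np.asarray(endog, dtype=float)
        if self.endog.shape[0] != len(self.exog):
            raise ValueError("endog and exog lengths differ")
        if not np.isfinite(self.exog.to_numpy()).all():
            raise ValueError("exog contains non-finite values")
        n_events = int(min(self.endog.sum(), (1 - self.endog).sum()))
        if n_events < 10 * len(GSDI_EXOG):
            warnings.warn(
                f"only {n_events} events for {len(GSDI_EXOG)} predictors; "
                "coefficients may be unstable", stacklevel=2)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label") -> "GSDIModel":
        return cls(df[label_col].to_numpy(), df)

    def fit(self) -> "GSDIResults":
        params, bse, pvalues, penalized = _fit_logit(
            self.exog.to_numpy(), self.endog)
        names = ["const", *GSDI_EXOG]
        params = pd.Series(params, index=names)
        # weight shares from absolute standardized coefficients
        sds = self.exog.std(ddof=1)
        std_coef = params[list(GSDI_EXOG)].abs() * sds
        weights = 100.0 * std_coef / std_coef.sum()
        return GSDIResults(
            params=params,
            bse=pd.Series(bse, index=names),
            pvalues=pd.Series(pvalues, index=names),
            standardized_weights=weights,
            source="fitted",
            penalized=penalized,
            nobs=len(self.exog),
            n_cases=int(self.endog.sum()),
        )


@dataclass
class GSDIResults:
    """Fitted (or published) GSDI coefficients with inference and scoring.

    ``params`` holds const + one coefficient per exog column;
    ``standardized_weights`` are the absolute standardized-coefficient
    shares, summing to 100.  Wald standard errors and p-values are NaN for
    the published instance and for penalized-fallback fits.
    """

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    standardized_weights: pd.Series
    source: str = "fitted"
    penalized: bool = False
    nobs: int | None = None
    n_cases: int | None = None

    def __post_init__(self) -> None:
        if abs(self.standardized_weights.sum() - 100.0) > 1e-6:
            raise ValueError("standardized weights must sum to 100")

    # convenience accessors on the published naming
    @property
    def intercept(self) -> float:
        return float(self.params["const"])

    @property
    def coef_overall(self) -> float:
        return float(self.params["composite_overall"])

    @property
    def coef_flv(self) -> float:
        return float(self.params["composite_flv"])

    @property
    def coef_vcdr(self) -> float:
        return float(self.params["vcdr"])

    def linear_predictor(self, composite_overall, composite_flv, vcdr):
        return (self.intercept
                + self.coef_overall * np.asarray(composite_overall, dtype=float)
                + self.coef_flv * np.asarray(composite_flv, dtype=float)
                + self.coef_vcdr * np.asarray(vcdr, dtype=float))

    def predict(self, exog: pd.DataFrame) -> np.ndarray:
        """Index values in (0, 1) for a table carrying the exog columns."""
        return logistic(self.linear_predictor(
            exog["composite_overall"], exog["composite_flv"], exog["vcdr"]))

    def odds_ratios(self) -> pd.Series:
        """ORs per conventional worsening unit: 1 SD-equivalent thinner
        composite overall thickness, 1% higher composite FLV, 0.1 higher
        VCDR."""
        return pd.Series({
            "composite_overall_per_1sd_thinner": float(np.exp(-self.coef_overall)),
            "composite_flv_per_1pct_higher": float(np.exp(self.coef_flv)),
            "vcdr_per_0.1_higher": float(np.exp(0.1 * self.coef_vcdr)),
        })

    def summary(self) -> str:
        lines = [
            "Glaucoma structural diagnostic index (GSDI)",
            f"  source: {self.source}"
            + (", penalized fallback" if self.penalized else ""),
        ]
        if self.nobs is not None:
            lines.append(f"  n eyes: {self.nobs} ({self.n_cases} cases)")
        lines.append(f"{'term':<22}{'coef':>10}{'se':>10}{'p':>12}{'weight%':>10}")
        for name in self.params.index:
            w = (f"{self.standardized_weights[name]:.1f}"
                 if name in self.standardized_weights.index else "")
            se = self.bse.get(name, np.nan)
            p = self.pvalues.get(name, np.nan)
            lines.append(
                f"{name:<22}{self.params[name]:>10.3f}"
                f"{se:>10.3f}{p:>12.3g}{w:>10}")
        return "\n".join(lines)


def fit_gsdi(records: pd.DataFrame, label_col: str = "label") -> GSDIResults:
    """Maximum-likelihood GSDI fit on per-eye composite records."""
    return GSDIModel.from_dataframe(records, label_col=label_col).fit()


def published_gsdi() -> GSDIResults:
    """The fixed published GSDI instance (coefficients and weight shares)."""
    names = ["const", *GSDI_EXOG]
    nan = pd.Series([np.nan] * 4, index=names)
    return GSDIResults(
        params=pd.Series([-3.69, -0.74, 0.70, 3.37], index=names),
        bse=nan.copy(), pvalues=nan.copy(),
        standardized_weights=pd.Series(
            [38.0, 28.0, 34.0], index=list(GSDI_EXOG)),
        source="published",
    )


def score_gsdi(model: GSDIResults, composite_overall, composite_flv, vcdr):
    """Index value(s) in (0, 1) from a coefficient set and raw inputs."""
    inputs = [np.asarray(a, dtype=float)
              for a in (composite_overall, composite_flv, vcdr)]
    if any(not np.isfinite(a).all() for a in inputs):
        raise ValueError("inputs must be finite")
    return logistic(model.linear_predictor(*inputs))


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HosmerLemeshowResult:
    statistic: float
    pvalue: float
    df: int
    table: pd.DataFrame  # per-bin observed/expected events


def hosmer_lemeshow(scores, labels, n_bins: int = 10) -> HosmerLemeshowResult:
    """Decile-of-risk goodness-of-fit test for probability scores.

    Bins by score deciles (duplicate bin edges are merged with a warning),
    compares observed and expected event counts per bin, and refers the
    chi-square statistic to ``bins - 2`` degrees of freedom.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.size < n_bins:
        raise ValueError("need at least n_bins observations")
    if ((scores <= 0) | (scores >= 1)).any():
        raise ValueError("scores must lie strictly in (0, 1)")

    bins = pd.qcut(scores, q=n_bins, duplicates="drop")
    if bins.categories.size < n_bins:
        warnings.warn(
            f"tied score deciles: merged into {bins.categories.size} bins",
            stacklevel=2)
    grouped = pd.DataFrame({"y": labels, "p": scores, "bin": bins}).groupby(
        "bin", observed=True)
    table = grouped.agg(n=("y", "size"), observed=("y", "sum"),
                        expected=("p", "sum")).reset_index()
    n_used = table.shape[0]
    if n_used < 3:
        raise ValueError("too few distinct bins for the test")
    o1, e1, n = (table["observed"].to_numpy(), table["expected"].to_numpy(),
                 table["n"].to_numpy())
    chi2 = float(np.sum((o1 - e1) ** 2 / e1 + ((n - o1) - (n - e1)) ** 2 / (n - e1)))
    df = n_used - 2
    return HosmerLemeshowResult(
        statistic=chi2, pvalue=float(_stats.chi2.sf(chi2, df)), df=df, table=table)
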
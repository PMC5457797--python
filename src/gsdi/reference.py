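"""Normative reference built from the healthy reference (R) group.

The reference carries per-location mean/SD thickness maps per modality,
(mean, SD) standardization constants for every scalar diagnostic variable,
and the significance cutoffs used to flag loss-direction deviations
(borderline p in (0.01, 0.05], outside-normal p <= 0.01, one-sided in the
thinning direction).  Sample (n-1) SDs are used throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import EyeRecord, MODALITIES

DEFAULT_CUTOFFS = {"borderline": 0.05, "outside_normal": 0.01}

CATEGORIES = ("normal", "borderline", "outside_normal")


@dataclass
class NormativeReference:
    mean_maps: dict  # modality -> 2-D array (um)
    sd_maps: dict    # modality -> 2-D array (um)
    regions: dict    # modality -> region-label grid
    scalar_stats: pd.DataFrame  # index: variable id; columns: mean, sd
    cutoffs: dict = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))
    n_eyes: int = 0
    #: per-location mean/SD of *rescaled* (diffuse-removed) reference maps;
    #: the null for pattern-deviation significance.  Locations whose
    #: pattern SD degenerates to zero (reference eyes exact scalings of one
    #: pattern) fall back to the raw SD map.
    pattern_mean_maps: dict | None = None
    pattern_sd_maps: dict | None = None

    def __post_init__(self) -> None:
        if not self.cutoffs["outside_normal"] < self.cutoffs["borderline"]:
            raise ValueError("cutoff levels must be strictly ordered")

    def overall_mean(self, modality: str) -> float:
        valid = self.regions[modality] != 0
        return float(self.mean_maps[modality][valid].mean())

    def variables(self) -> list[str]:
        return list(self.scalar_stats.index)


def build_reference(r_eyes: list[EyeRecord],
                    cutoffs: dict | None = None) -> NormativeReference:
    """Build the normative reference from >= 2 R-group eyes.

    Per-location means and SDs are computed across eyes for each modality;
    the scalar standardization table covers every variable the pipeline
    standardizes (regional thicknesses, GLV, FLV per modality, and the
    disc metrics) computed on the R eyes against the map reference itself.
    Zero variance anywhere is a degenerate-input error.
    """
    from .metrics import compute_all_metrics  # deferred: metrics needs this type

    if len(r_eyes) < 2:
        raise ValueError("need at least 2 reference eyes")
    if any(e.group != "R" for e in r_eyes):
        raise ValueError("all reference eyes must belong to group R")

    maps = {"GCC": [e.gcc_map for e in r_eyes], "NFL": [e.nfl_map for e in r_eyes]}
    mean_maps, sd_maps, regions = {}, {}, {}
    pattern_mean_maps, pattern_sd_maps = {}, {}
    for mod in MODALITIES:
        shapes = {m.values.shape for m in maps[mod]}
        if len(shapes) != 1:
            raise ValueError("reference eyes must share one grid shape")
        stack = np.stack([m.values for m in maps[mod]])
        mean_maps[mod] = stack.mean(axis=0)
        sd_maps[mod] = stack.std(axis=0, ddof=1)
        regions[mod] = maps[mod][0].region
        valid = regions[mod] != 0
        if (sd_maps[mod][valid] <= 0).any():
            raise ValueError(
                f"zero variance at some {mod} locations: degenerate reference")
        # pattern null: rescale every eye to the common overall mean, so the
        # remaining spread reflects shape (focal) variation only
        overall = mean_maps[mod][valid].mean()
        eye_means = stack[:, valid].mean(axis=1)
        if (eye_means <= 0).any():
            raise ValueError("reference eye with non-positive overall mean")
        rescaled = stack * (overall / eye_means)[:, None, None]
        pattern_mean_maps[mod] = rescaled.mean(axis=0)
        p_sd = rescaled.std(axis=0, ddof=1)
        pattern_sd_maps[mod] = np.where(p_sd > 0, p_sd, sd_maps[mod])

    ref = NormativeReference(
        mean_maps=mean_maps, sd_maps=sd_maps, regions=regions,
        scalar_stats=pd.DataFrame(columns=["mean", "sd"], dtype=float),
        cutoffs=dict(cutoffs or DEFAULT_CUTOFFS), n_eyes=len(r_eyes),
        pattern_mean_maps=pattern_mean_maps, pattern_sd_maps=pattern_sd_maps,
    )

    table = pd.DataFrame([compute_all_metrics(e, ref).to_series() for e in r_eyes])
    stats_df = pd.DataFrame({"mean": table.mean(), "sd": table.std(ddof=1)})
    # a variable that is (numerically) constant across reference eyes cannot
    # be standardized; drop it rather than divide by floating noise
    tol = 1e-9 * np.maximum(stats_df["mean"].abs(), 1.0)
    degenerate = stats_df.index[stats_df["sd"] <= tol].tolist()
    if degenerate:
        warnings.warn(
            f"scalar variables {degenerate} are constant across reference "
            "eyes and were dropped from the standardization table",
            stacklevel=2)
        stats_df = stats_df.drop(index=degenerate)
    ref.scalar_stats = stats_df
    return ref


def standardize(value, variable_id: str, ref: NormativeReference):
    """(value - R-group mean) / R-group SD for a named scalar variable."""
    if variable_id not in ref.scalar_stats.index:
        raise KeyError(f"unknown variable {variable_id!r}")
    row = ref.scalar_stats.loc[variable_id]
    return (value - row["mean"]) / row["sd"]


def unstandardize(z, variable_id: str, ref: NormativeReference):
    if variable_id not in ref.scalar_stats.index:
        raise KeyError(f"unknown variable {variable_id!r}")
    row = ref.scalar_stats.loc[variable_id]
    return z * row["sd"] + row["mean"]


def loss_p_value(value, mean, sd, empirical_null=None):
    """One-sided p-value for a loss-direction (low-value) deviation.

    Gaussian by default; with ``empirical_null`` (array of healthy draws)
    the p-value is the smoothed empirical percentile (r+1)/(n+1).
    """
    if empirical_null is not None:
        null = np.sort(np.asarray(empirical_null, dtype=float))
        v = np.atleast_1d(np.asarray(value, dtype=float))
        r = np.searchsorted(null, v, side="right")
        p = (r + 1.0) / (null.size + 1.0)
        return p if np.ndim(value) else float(p[0])
    z = (np.asarray(value, dtype=float) - mean) / sd
    p = stats.norm.cdf(z)
    return p if np.ndim(value) else float(p)


def significance_category(value, mean=None, sd=None, *,
                          cutoffs: dict | None = None,
                          empirical_null=None):
    """Classify loss-direction deviations as normal / borderline / outside_normal.

    ``p > borderline`` is normal, ``outside_normal < p <= borderline`` is
    borderline, ``p <= outside_normal`` is outside normal limits; a p equal
    to a cutoff belongs to the more severe category.  Works elementwise on
    arrays.
    """
    cut = cutoffs or DEFAULT_CUTOFFS
    p = loss_p_value(value, mean, sd, empirical_null=empirical_null)
    p_arr = np.atleast_1d(np.asarray(p, dtype=float))
    eps = 1e-12  # a p exactly at a cutoff belongs to the more severe category
    out = np.where(p_arr <= cut["outside_normal"] + eps, "outside_normal",
                   np.where(p_arr <= cut["borderline"] + eps, "borderline",
                            "normal"))
    if np.ndim(value) == 0:
        return str(out[0])
    return out
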
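"""Per-eye structural loss statistics: regional thickness, GLV and FLV.

Global loss volume (GLV) averages the negative fractional deviation from
the normative mean over the map -- a diffuse-loss statistic, in percent of
normal tissue.  Focal loss volume (FLV) first removes the diffuse
component by rescaling the map so its overall mean matches the reference
overall mean (the pattern deviation), then sums the fractional loss only
over locations whose pattern deviation is statistically significant in the
thinning direction.  A uniformly thinned map therefore has GLV equal to
its scale deficit and FLV near zero: the pair separates diffuse from focal
loss.

All statistics weight locations equally and are defined over the valid
grid generically, so a 1-row circumpapillary profile and a 2-D macular
grid are handled identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .reference import NormativeReference
from .simulate import EyeRecord, ThicknessMap

#: default one-sided significance cutoff on pattern deviation used by FLV
FLV_P_CUTOFF = 0.05

REGIONS = ("overall", "superior", "inferior")


@dataclass(frozen=True)
class ModalityMetrics:
    overall_um: float
    superior_um: float
    inferior_um: float
    glv_pct: float
    flv_pct: float


@dataclass(frozen=True)
class LossMetrics:
    gcc: ModalityMetrics
    nfl: ModalityMetrics
    vcdr: float
    hcdr: float
    rim_volume: float

    def to_series(self) -> pd.Series:
        """Flat per-variable view keyed by the pipeline's variable ids."""
        out = {}
        for mod, m in (("gcc", self.gcc), ("nfl", self.nfl)):
            out[f"{mod}_overall_um"] = m.overall_um
            out[f"{mod}_superior_um"] = m.superior_um
            out[f"{mod}_inferior_um"] = m.inferior_um
            out[f"{mod}_glv_pct"] = m.glv_pct
            out[f"{mod}_flv_pct"] = m.flv_pct
        out["vcdr"] = self.vcdr
        out["hcdr"] = self.hcdr
        out["rim_volume"] = self.rim_volume
        return pd.Series(out)


def regional_mean(tmap: ThicknessMap, region: str = "overall") -> float:
    """Arithmetic mean thickness (um) over a named region."""
    mask = tmap.region_mask(region)
    if not mask.any():
        raise ValueError(f"region {region!r} is empty")
    return float(tmap.values[mask].mean())


def _check_shapes(tmap: ThicknessMap, ref: NormativeReference) -> np.ndarray:
    mean_map = ref.mean_maps[tmap.modality]
    if mean_map.shape != tmap.values.shape:
        raise ValueError("map shape does not match the reference")
    return mean_map


def fractional_deviation_map(tmap: ThicknessMap,
                             ref: NormativeReference) -> np.ndarray:
    """FD(loc) = (measured - normative mean) / normative mean; NaN outside."""
    mean_map = _check_shapes(tmap, ref)
    valid = tmap.valid
    if (mean_map[valid] <= 0).any():
        raise ValueError("non-positive reference mean inside the valid grid")
    fd = np.full_like(tmap.values, np.nan)
    fd[valid] = (tmap.values[valid] - mean_map[valid]) / mean_map[valid]
    return fd


def compute_glv(tmap: ThicknessMap, ref: NormativeReference) -> float:
    """Average fractional tissue loss, % of normal (locations with FD >= 0
    contribute zero)."""
    fd = fractional_deviation_map(tmap, ref)
    valid = tmap.valid
    loss = np.clip(-fd[valid], 0.0, None)
    return float(100.0 * loss.sum() / valid.sum())


def pattern_deviation_map(tmap: ThicknessMap,
                          ref: NormativeReference) -> np.ndarray:
    """Fractional deviation after removing the diffuse component.

    The map is rescaled by the single factor matching its overall mean to
    the reference overall mean, then FD is computed on the rescaled map;
    uniform thinning of any magnitude maps to (near-)zero everywhere.
    """
    mean_map = _check_shapes(tmap, ref)
    valid = tmap.valid
    own_mean = tmap.values[valid].mean()
    if own_mean <= 0:
        raise ValueError("map overall mean must be positive")
    factor = mean_map[valid].mean() / own_mean
    pd_map = np.full_like(tmap.values, np.nan)
    pd_map[valid] = (tmap.values[valid] * factor - mean_map[valid]) / mean_map[valid]
    return pd_map


def compute_flv(tmap: ThicknessMap, ref: NormativeReference,
                p_cutoff: float = FLV_P_CUTOFF,
                sum_pattern: bool = False) -> float:
    """Fractional loss over pattern-significant locations, % of normal.

    A location contributes when its pattern deviation is significant in
    the loss direction at ``p_cutoff`` under the per-location Gaussian
    null for *rescaled* maps (the reference's pattern mean/SD, which
    excludes the global-scale variation the rescaling removes).  By
    default the *full* fractional deviation is summed at those locations,
    so FLV reads as percent of normal tissue lost focally;
    ``sum_pattern=True`` sums the pattern deviation instead (sensitivity
    analysis).
    """
    mean_map = _check_shapes(tmap, ref)
    valid = tmap.valid
    if ref.pattern_mean_maps is not None:
        null_mean = ref.pattern_mean_maps[tmap.modality]
        null_sd = ref.pattern_sd_maps[tmap.modality]
    else:
        null_mean, null_sd = mean_map, ref.sd_maps[tmap.modality]

    own_mean = tmap.values[valid].mean()
    if own_mean <= 0:
        raise ValueError("map overall mean must be positive")
    factor = mean_map[valid].mean() / own_mean
    z = (tmap.values[valid] * factor - null_mean[valid]) / null_sd[valid]
    p = _stats.norm.cdf(z)
    significant = p <= p_cutoff
    pd_map = pattern_deviation_map(tmap, ref)

    if sum_pattern:
        contrib = np.clip(-pd_map[valid], 0.0, None)
    else:
        fd = fractional_deviation_map(tmap, ref)
        contrib = np.clip(-fd[valid], 0.0, None)
    return float(100.0 * contrib[significant].sum() / valid.sum())


def compute_all_metrics(eye: EyeRecord, ref: NormativeReference,
                        p_cutoff: float = FLV_P_CUTOFF) -> LossMetrics:
    """Fill the full per-eye variable panel for both modalities."""
    per_mod = {}
    for mod, tmap in (("GCC", eye.gcc_map), ("NFL", eye.nfl_map)):
        per_mod[mod] = ModalityMetrics(
            overall_um=regional_mean(tmap, "overall"),
            superior_um=regional_mean(tmap, "superior"),
            inferior_um=regional_mean(tmap, "inferior"),
            glv_pct=compute_glv(tmap, ref),
            flv_pct=compute_flv(tmap, ref, p_cutoff=p_cutoff),
        )
    return LossMetrics(
        gcc=per_mod["GCC"], nfl=per_mod["NFL"],
        vcdr=eye.disc.vcdr, hcdr=eye.disc.hcdr, rim_volume=eye.disc.rim_volume,
    )
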
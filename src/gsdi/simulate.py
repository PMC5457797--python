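"""Seeded synthetic OCT cohorts for glaucoma diagnostic-index studies.

Generates three groups of eyes mirroring a case-control FD-OCT study design:

* ``R`` -- healthy reference eyes used only to build the normative reference,
* ``N`` -- healthy test eyes (controls for diagnostic accuracy),
* ``PG`` -- perimetric-glaucoma eyes.

Each eye carries a macular ganglion-cell-complex (GCC) thickness map, a
circumpapillary nerve-fibre-layer (NFL) thickness profile, optic-disc
metrics, and visual-field global indices (MD, PSD).  Glaucomatous eyes are
built by drawing a severity stage, drawing (MD, PSD) inside that stage's
region of the staging plane, then applying diffuse thinning proportional
to the MD loss plus zero or more wedge-shaped focal defects with an
inferior predilection; vertical cupping rises with total structural loss.
Bilateral eyes share a subject-level latent thickness factor so that
subject-level cross-validation differs meaningfully from eye-level.

Defaults emulate the marginals of a referral-centre perimetric-glaucoma
case-control cohort (MD -0.1+-1.0 dB in normals vs about -5+-4.5 dB in
glaucoma, PSD 1.4+-0.2 vs ~5.9 dB, a 2:1 case-control ratio, and a stage
mix concentrated in early disease).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .staging import StageBoundaries, STAGE_SEVERITY, default_boundaries

# region-mask codes
OUTSIDE, SUPERIOR, INFERIOR = 0, 1, 2
REGION_NAMES = {SUPERIOR: "superior", INFERIOR: "inferior"}

GROUPS = ("R", "N", "PG")
MODALITIES = ("GCC", "NFL")


# --------------------------------------------------------------------------
# core containers
# --------------------------------------------------------------------------

@dataclass
class ThicknessMap:
    """A gridded thickness measurement (um) with anatomical region labels.

    ``region`` has the same shape as ``values``; cells are labelled
    SUPERIOR (1) or INFERIOR (2), with 0 marking cells outside the scanned
    field (e.g. corners of a square grid holding a circular macular scan).
    The superior and inferior labels partition the valid grid.  A
    circumpapillary NFL profile is simply a 1-row grid.
    """

    values: np.ndarray
    region: np.ndarray
    modality: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region = np.asarray(self.region, dtype=np.int8)
        if self.values.shape != self.region.shape:
            raise ValueError("values and region must share a shape")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if not (self.region >= OUTSIDE).all() or not (self.region <= INFERIOR).all():
            raise ValueError("region labels must be 0 (outside), 1 or 2")
        valid = self.region != OUTSIDE
        if not valid.any():
            raise ValueError("map has no valid locations")
        if (self.values[valid] < 0).any():
            raise ValueError("thickness values must be non-negative")

    @property
    def valid(self) -> np.ndarray:
        return self.region != OUTSIDE

    @property
    def n_locations(self) -> int:
        return int(self.valid.sum())

    def region_mask(self, region: str) -> np.ndarray:
        if region == "overall":
            return self.valid
        code = {"superior": SUPERIOR, "inferior": INFERIOR}.get(region)
        if code is None:
            raise ValueError(f"unknown region {region!r}")
        return self.region == code

    def with_values(self, values: np.ndarray) -> "ThicknessMap":
        return ThicknessMap(values=values, region=self.region, modality=self.modality)

    def copy(self) -> "ThicknessMap":
        return ThicknessMap(self.values.copy(), self.region.copy(), self.modality)


@dataclass(frozen=True)
class DiscMetrics:
    """Optic-disc morphometrics: cup-to-disc ratios and rim volume."""

    vcdr: float
    hcdr: float
    rim_volume: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.vcdr <= 1.0 and 0.0 <= self.hcdr <= 1.0):
            raise ValueError("cup-to-disc ratios must lie in [0, 1]")
        if self.rim_volume < 0:
            raise ValueError("rim volume must be non-negative")


@dataclass
class EyeRecord:
    """One eye's full measurement set."""

    subject_id: str
    eye: str  # OD | OS
    group: str  # R | N | PG
    md_db: float
    psd_db: float
    gcc_map: ThicknessMap
    nfl_map: ThicknessMap
    disc: DiscMetrics
    true_stage: str | None = None
    age: float | None = None
    sex: str | None = None
    ethnicity: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.group == "PG" and self.true_stage is None:
            raise ValueError("PG eyes must carry a true_stage")


@dataclass(frozen=True)
class FocalDefectParams:
    """Wedge-defect generator settings.

    ``area_frac`` and ``depth_frac`` are (lo, hi) uniform ranges for the
    fraction of the map covered and the fractional thinning inside the
    wedge; ``inferior_superior_odds`` is the odds an individual defect
    lands in the inferior hemifield; ``rate_per_stage`` scales the Poisson
    mean number of defects with the eye's numeric severity.
    """

    area_frac: tuple[float, float] = (0.03, 0.12)
    depth_frac: tuple[float, float] = (0.2, 0.7)
    inferior_superior_odds: float = 2.0
    rate_per_stage: float = 0.4

    def __post_init__(self) -> None:
        for lo, hi in (self.area_frac, self.depth_frac):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("area/depth fractions must satisfy 0 <= lo <= hi <= 1")
        if self.inferior_superior_odds < 0 or self.rate_per_stage < 0:
            raise ValueError("odds and rates must be non-negative")


def _as_group_probs(p) -> dict[str, float]:
    if isinstance(p, Mapping):
        probs = {g: float(p[g]) for g in GROUPS}
    else:
        probs = {g: float(p) for g in GROUPS}
    for g, v in probs.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"bilateral probability for {g} must be in [0,1]")
    return probs


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Group sizes default to the 2:1 case-control design (118 normal / 236
    glaucoma test eyes) with a separate 105-eye reference group; bilateral
    enrolment probabilities default to each group's observed eyes-per-
    subject ratio.  ``stage_mix`` spans the seven staging categories in
    order (stage 0, borderline, 1..5).
    """

    n_reference_eyes: int = 105
    n_normal_eyes: int = 118
    n_glaucoma_eyes: int = 236
    eyes_per_subject_prob: Mapping[str, float] | float = field(
        default_factory=lambda: {"R": 0.72, "N": 0.97, "PG": 0.42}
    )
    md_normal: tuple[float, float] = (-0.1, 1.0)
    md_glaucoma: tuple[float, float] = (-5.0, 4.5)
    psd_normal: tuple[float, float] = (1.4, 0.2)
    psd_glaucoma: tuple[float, float] = (5.9, 4.1)
    # stage 0, borderline, 1, 2, 3, 4, 5 -- printed counts 1/3/90/47/45/39/9
    stage_mix: tuple[float, ...] = tuple(
        c / 234.0 for c in (1, 3, 90, 47, 45, 39, 9)
    )
    diffuse_loss_per_db: float = 0.02
    focal_defect_params: FocalDefectParams = field(default_factory=FocalDefectParams)
    vcdr_normal: tuple[float, float] = (0.43, 0.10)
    vcdr_coupling: float = 1.2
    noise_sd_um: float = 2.0
    grid_shape: tuple[int, int] = (32, 32)
    nfl_profile_len: int = 128
    subject_scale_sd: float = 0.06
    eye_scale_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_reference_eyes", "n_normal_eyes", "n_glaucoma_eyes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(sum(self.stage_mix) - 1.0) > 1e-6:
            raise ValueError("stage_mix must sum to 1")
        if len(self.stage_mix) != 7:
            raise ValueError("stage_mix must cover the 7 staging categories")
        if not 0.0 <= self.diffuse_loss_per_db:
            raise ValueError("diffuse_loss_per_db must be non-negative")
        if self.noise_sd_um < 0 or self.subject_scale_sd < 0 or self.eye_scale_sd < 0:
            raise ValueError("noise/scale SDs must be non-negative")
        if min(self.grid_shape) < 2 or self.nfl_profile_len < 4:
            raise ValueError("map grids are implausibly small")
        _as_group_probs(self.eyes_per_subject_prob)
        if isinstance(self.focal_defect_params, dict):
            self.focal_defect_params = FocalDefectParams(**self.focal_defect_params)

    def null_effect(self) -> "SimulationConfig":
        """A copy with all structure-function coupling switched off."""
        return replace(
            self,
            diffuse_loss_per_db=0.0,
            focal_defect_params=replace(self.focal_defect_params, rate_per_stage=0.0),
            vcdr_coupling=0.0,
        )


# --------------------------------------------------------------------------
# map geometry and normative shape
# --------------------------------------------------------------------------

def gcc_region_grid(shape: tuple[int, int]) -> np.ndarray:
    """Circular macular field on a square grid, split into hemifields.

    Rows above the horizontal midline are superior, at/below inferior;
    corners outside the inscribed circle are OUTSIDE.
    """
    nr, nc = shape
    r = (np.arange(nr) + 0.5 - nr / 2.0)[:, None]
    c = (np.arange(nc) + 0.5 - nc / 2.0)[None, :]
    radius = min(nr, nc) / 2.0
    inside = (r**2 + c**2) <= radius**2
    region = np.where(r < 0, SUPERIOR, INFERIOR).astype(np.int8)
    region = np.broadcast_to(region, shape).copy()
    region[~inside] = OUTSIDE
    return region


def nfl_region_profile(n: int) -> np.ndarray:
    """Circumpapillary profile: first half superior, second half inferior."""
    region = np.full((1, n), INFERIOR, dtype=np.int8)
    region[0, : n // 2] = SUPERIOR
    return region


def gcc_base_pattern(shape: tuple[int, int]) -> np.ndarray:
    """Mean healthy GCC thickness: perifoveal ring peaking near 110 um."""
    nr, nc = shape
    r = (np.arange(nr) + 0.5 - nr / 2.0)[:, None]
    c = (np.arange(nc) + 0.5 - nc / 2.0)[None, :]
    rho = np.sqrt(r**2 + c**2) / (min(nr, nc) / 2.0)
    return 88.0 + 22.0 * np.exp(-(((rho - 0.45) / 0.28) ** 2))


def nfl_base_pattern(n: int) -> np.ndarray:
    """Mean healthy circumpapillary NFL: classic double-hump profile."""
    theta = (np.arange(n) + 0.5) / n * 360.0
    hump = lambda centre: np.exp(-(((theta - centre + 180) % 360 - 180) / 32.0) ** 2)
    return (70.0 + 55.0 * hump(80.0) + 55.0 * hump(280.0))[None, :]


def _wedge_mask(region: np.ndarray, hemisphere: int, centre_angle: float,
                area_frac: float) -> np.ndarray:
    """Angular wedge inside one hemifield of a 2-D grid (angles in radians,
    measured anticlockwise from the +x axis with superior = positive y)."""
    nr, nc = region.shape
    r = (np.arange(nr) + 0.5 - nr / 2.0)[:, None]
    c = (np.arange(nc) + 0.5 - nc / 2.0)[None, :]
    angle = np.arctan2(-np.broadcast_to(r, region.shape),
                       np.broadcast_to(c, region.shape))
    half_width = area_frac * math.pi  # wedge spans area_frac of the full disc
    diff = np.angle(np.exp(1j * (angle - centre_angle)))
    return (np.abs(diff) <= half_width) & (region == hemisphere)


def _arc_mask(region: np.ndarray, hemisphere: int, start_frac: float,
              area_frac: float) -> np.ndarray:
    """Contiguous arc inside one hemifield of a 1-row profile."""
    n = region.shape[1]
    idx = np.flatnonzero(region[0] == hemisphere)
    length = max(1, int(round(area_frac * n)))
    length = min(length, idx.size)
    start = int(round(start_frac * (idx.size - length))) if idx.size > length else 0
    mask = np.zeros_like(region, dtype=bool)
    mask[0, idx[start : start + length]] = True
    return mask


# --------------------------------------------------------------------------
# loss-injection primitives
# --------------------------------------------------------------------------

def inject_diffuse_loss(tmap: ThicknessMap, fraction: float) -> ThicknessMap:
    """Thin every location by ``fraction`` (0 <= fraction < 1)."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must satisfy 0 <= fraction < 1")
    return tmap.with_values(tmap.values * (1.0 - fraction))


def inject_focal_defect(tmap: ThicknessMap, sector: np.ndarray,
                        depth: float) -> ThicknessMap:
    """Thin the locations inside ``sector`` (a boolean mask) by ``depth``."""
    sector = np.asarray(sector, dtype=bool)
    if sector.shape != tmap.values.shape:
        raise ValueError("sector mask shape must match the map")
    if not (sector & tmap.valid).any():
        raise ValueError("sector selects no valid locations")
    if not 0.0 <= depth <= 1.0:
        raise ValueError("depth must lie in [0, 1]")
    values = tmap.values.copy()
    values[sector] *= 1.0 - depth
    return tmap.with_values(values)


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

def _subject_eye_counts(n_eyes: int, p_bilateral: float,
                        rng: np.random.Generator) -> list[int]:
    counts: list[int] = []
    total = 0
    while total < n_eyes:
        k = 2 if rng.random() < p_bilateral else 1
        if total + k > n_eyes:
            k = 1
        counts.append(k)
        total += k
    return counts


def _draw_stage_md_psd(cfg: SimulationConfig, boundaries: StageBoundaries,
                       rng: np.random.Generator) -> tuple[str, float, float]:
    idx = rng.choice(len(boundaries.labels), p=np.asarray(cfg.stage_mix))
    label = boundaries.labels[idx]
    md_lo, md_hi = boundaries.md_box(label)
    psd_lo, psd_hi = boundaries.psd_box(label)
    # uniform strictly inside the box so classification round-trips exactly
    md = rng.uniform(md_lo + 1e-9, md_hi - 1e-9)
    psd = rng.uniform(psd_lo + 1e-9, psd_hi - 1e-9)
    return label, md, psd


def generate_cohort(config: SimulationConfig,
                    boundaries: StageBoundaries | None = None) -> list[EyeRecord]:
    """Generate a full R/N/PG cohort; deterministic given ``config.seed``."""
    config.validate()
    boundaries = boundaries or default_boundaries()
    rng = np.random.default_rng(config.seed)
    probs = _as_group_probs(config.eyes_per_subject_prob)

    gcc_region = gcc_region_grid(config.grid_shape)
    nfl_region = nfl_region_profile(config.nfl_profile_len)
    gcc_base = gcc_base_pattern(config.grid_shape)
    nfl_base = nfl_base_pattern(config.nfl_profile_len)
    fd = config.focal_defect_params
    p_inferior = (fd.inferior_superior_odds / (1.0 + fd.inferior_superior_odds)
                  if fd.inferior_superior_odds > 0 else 0.0)

    cohort: list[EyeRecord] = []
    targets = {"R": config.n_reference_eyes, "N": config.n_normal_eyes,
               "PG": config.n_glaucoma_eyes}
    for group in GROUPS:
        eye_counts = _subject_eye_counts(targets[group], probs[group], rng)
        for s_idx, n_eyes in enumerate(eye_counts):
            subject_id = f"{group}{s_idx + 1:04d}"
            subject_scale = rng.normal(1.0, config.subject_scale_sd)
            age = float(np.clip(rng.normal(59.0, 9.0), 40.0, 79.0))
            sex = "F" if rng.random() < 0.63 else "M"
            ethnicity = "AA" if rng.random() < 0.11 else "other"
            eyes = ("OD", "OS")[:n_eyes]
            for eye in eyes:
                cohort.append(_make_eye(
                    config, boundaries, rng, group, subject_id, eye,
                    subject_scale, age, sex, ethnicity,
                    gcc_region, nfl_region, gcc_base, nfl_base, p_inferior,
                ))
    return cohort


def _make_eye(cfg, boundaries, rng, group, subject_id, eye, subject_scale,
              age, sex, ethnicity, gcc_region, nfl_region, gcc_base, nfl_base,
              p_inferior) -> EyeRecord:
    fd = cfg.focal_defect_params
    eye_scale = rng.normal(1.0, cfg.eye_scale_sd)
    scale = max(subject_scale * eye_scale, 0.05)

    if group == "PG":
        stage, md, psd = _draw_stage_md_psd(cfg, boundaries, rng)
        severity = STAGE_SEVERITY[stage]
    else:
        stage = None
        md = rng.normal(*cfg.md_normal)
        psd = max(rng.normal(*cfg.psd_normal), 0.5)
        severity = 0.0

    gcc = ThicknessMap(gcc_base * scale, gcc_region, "GCC")
    nfl = ThicknessMap(nfl_base * scale, nfl_region, "NFL")

    total_loss = 0.0
    if group == "PG":
        loss_db = max(0.0, -md)
        diffuse = min(cfg.diffuse_loss_per_db * loss_db, 0.6)
        if diffuse > 0:
            gcc = inject_diffuse_loss(gcc, diffuse)
            nfl = inject_diffuse_loss(nfl, diffuse)
        total_loss += diffuse
        n_defects = rng.poisson(fd.rate_per_stage * severity)
        for _ in range(n_defects):
            hemi = INFERIOR if rng.random() < p_inferior else SUPERIOR
            area = rng.uniform(*fd.area_frac)
            depth = rng.uniform(*fd.depth_frac)
            centre = (rng.uniform(-math.pi + 0.1, -0.1) if hemi == INFERIOR
                      else rng.uniform(0.1, math.pi - 0.1))
            start_frac = rng.uniform(0.0, 1.0)
            wedge = _wedge_mask(gcc.region, hemi, centre, area)
            if (wedge & gcc.valid).any():
                gcc = inject_focal_defect(gcc, wedge, depth)
            arc = _arc_mask(nfl.region, hemi, start_frac, area)
            nfl = inject_focal_defect(nfl, arc, depth)
            total_loss += area * depth

    # measurement noise, clipped to physical range
    gcc = gcc.with_values(np.clip(
        gcc.values + rng.normal(0.0, cfg.noise_sd_um, gcc.values.shape), 0.0, None))
    nfl = nfl.with_values(np.clip(
        nfl.values + rng.normal(0.0, cfg.noise_sd_um, nfl.values.shape), 0.0, None))

    vcdr = float(np.clip(
        rng.normal(*cfg.vcdr_normal) + cfg.vcdr_coupling * total_loss, 0.02, 0.98))
    hcdr = float(np.clip(vcdr - 0.06 + rng.normal(0.0, 0.05), 0.0, 1.0))
    rim_volume = float(max(0.40 * (1.0 - vcdr) + rng.normal(0.0, 0.03), 0.005))

    return EyeRecord(
        subject_id=subject_id, eye=eye, group=group,
        md_db=float(md), psd_db=float(psd),
        gcc_map=gcc, nfl_map=nfl,
        disc=DiscMetrics(vcdr=vcdr, hcdr=hcdr, rim_volume=rim_volume),
        true_stage=stage, age=age, sex=sex, ethnicity=ethnicity,
    )
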
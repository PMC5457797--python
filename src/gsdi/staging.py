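"""Glaucoma severity staging from visual-field global indices.

Stages eyes on the (MD, PSD) plane in the spirit of the Enhanced Glaucoma
Staging System: seven ordered categories (stage 0, borderline, stages 1-5)
whose boundaries worsen with more negative mean deviation (MD) or higher
pattern standard deviation (PSD).  The boundary curves are supplied by
configuration so the classifier is auditable and replaceable; the shipped
default uses "L-shaped" piecewise boundaries -- an eye is at or above
severity *k* if its MD is at or below the k-th MD cut **or** its PSD is at
or above the k-th PSD cut -- which keeps the stage monotone in each index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

#: ordered category labels, mildest first
STAGE_LABELS: tuple[str, ...] = ("0", "borderline", "1", "2", "3", "4", "5")

#: numeric severity used where a scalar is needed (borderline sits at 0.5)
STAGE_SEVERITY: dict[str, float] = {
    "0": 0.0, "borderline": 0.5, "1": 1.0, "2": 2.0, "3": 3.0, "4": 4.0, "5": 5.0,
}


@dataclass(frozen=True)
class StageBoundaries:
    """Ordered boundary curves separating the seven severity categories.

    ``md_cuts`` are strictly decreasing (dB): an eye with MD <= md_cuts[k]
    is at least category k+1 on the MD axis.  ``psd_cuts`` are strictly
    increasing (dB): PSD >= psd_cuts[k] is at least category k+1 on the
    PSD axis.  The assigned stage is the worse of the two, so boundary
    points fall to the more severe side (screening-conservative tie-break).
    ``md_floor``/``psd_ceiling`` delimit the supported range; inputs
    outside it are clamped with a warning.
    """

    md_cuts: tuple[float, ...] = (-0.5, -1.5, -2.8, -5.0, -7.8, -12.0)
    psd_cuts: tuple[float, ...] = (1.7, 2.4, 3.2, 5.2, 8.0, 11.5)
    md_floor: float = -18.0
    md_ceiling: float = 1.5
    psd_floor: float = 0.6
    psd_ceiling: float = 16.0
    labels: tuple[str, ...] = field(default=STAGE_LABELS)

    def __post_init__(self) -> None:
        if len(self.md_cuts) != len(self.labels) - 1:
            raise ValueError("need one MD cut per category boundary")
        if len(self.psd_cuts) != len(self.labels) - 1:
            raise ValueError("need one PSD cut per category boundary")
        if not all(a > b for a, b in zip(self.md_cuts, self.md_cuts[1:])):
            raise ValueError("md_cuts must be strictly decreasing")
        if not all(a < b for a, b in zip(self.psd_cuts, self.psd_cuts[1:])):
            raise ValueError("psd_cuts must be strictly increasing")
        if self.md_floor >= self.md_cuts[-1]:
            raise ValueError("md_floor must lie below the last MD cut")
        if self.psd_ceiling <= self.psd_cuts[-1]:
            raise ValueError("psd_ceiling must lie above the last PSD cut")

    # -- stage-conditional (MD, PSD) boxes, used by the cohort generator ----
    def md_box(self, label: str) -> tuple[float, float]:
        """Open/closed MD interval (lo, hi] occupied by ``label`` on the MD axis."""
        i = self.labels.index(label)
        hi = self.md_ceiling if i == 0 else self.md_cuts[i - 1]
        lo = self.md_floor if i == len(self.labels) - 1 else self.md_cuts[i]
        return lo, hi

    def psd_box(self, label: str) -> tuple[float, float]:
        """PSD interval [lo, hi) occupied by ``label`` on the PSD axis."""
        i = self.labels.index(label)
        lo = self.psd_floor if i == 0 else self.psd_cuts[i - 1]
        hi = self.psd_ceiling if i == len(self.labels) - 1 else self.psd_cuts[i]
        return lo, hi

    @classmethod
    def from_yaml(cls, path) -> "StageBoundaries":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            md_cuts=tuple(raw["md_cuts"]),
            psd_cuts=tuple(raw["psd_cuts"]),
            md_floor=float(raw.get("md_floor", cls.md_floor)),
            md_ceiling=float(raw.get("md_ceiling", cls.md_ceiling)),
            psd_floor=float(raw.get("psd_floor", cls.psd_floor)),
            psd_ceiling=float(raw.get("psd_ceiling", cls.psd_ceiling)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "md_cuts": list(self.md_cuts),
                    "psd_cuts": list(self.psd_cuts),
                    "md_floor": self.md_floor,
                    "md_ceiling": self.md_ceiling,
                    "psd_floor": self.psd_floor,
                    "psd_ceiling": self.psd_ceiling,
                },
                fh,
            )


def default_boundaries() -> StageBoundaries:
    """The package's default staging configuration."""
    return StageBoundaries()


@dataclass(frozen=True)
class StageResult:
    stage: str
    defect_type: str | None = None

    @property
    def severity(self) -> float:
        return STAGE_SEVERITY[self.stage]


def classify_gss2(md, psd, boundaries: StageBoundaries | None = None):
    """Assign each (MD, PSD) pair to a severity category.

    Scalar inputs return a :class:`StageResult`; array inputs return an
    array of stage labels.  Stage is monotone: at fixed PSD a more negative
    MD never lowers the stage, and vice versa.  Values outside the
    supported range are clamped with a warning.
    """
    b = boundaries or default_boundaries()
    md_arr = np.atleast_1d(np.asarray(md, dtype=float))
    psd_arr = np.atleast_1d(np.asarray(psd, dtype=float))
    if md_arr.shape != psd_arr.shape:
        raise ValueError("md and psd must have matching shapes")
    if not (np.isfinite(md_arr).all() and np.isfinite(psd_arr).all()):
        raise ValueError("MD and PSD must be finite")

    out_of_range = (
        (md_arr < b.md_floor) | (md_arr > b.md_ceiling)
        | (psd_arr < b.psd_floor) | (psd_arr > b.psd_ceiling)
    )
    if out_of_range.any():
        warnings.warn(
            f"{int(out_of_range.sum())} input(s) outside the supported "
            "(MD, PSD) range; clamped",
            stacklevel=2,
        )
        md_arr = np.clip(md_arr, b.md_floor, b.md_ceiling)
        psd_arr = np.clip(psd_arr, b.psd_floor, b.psd_ceiling)

    md_idx = (md_arr[:, None] <= np.asarray(b.md_cuts)[None, :]).sum(axis=1)
    psd_idx = (psd_arr[:, None] >= np.asarray(b.psd_cuts)[None, :]).sum(axis=1)
    idx = np.maximum(md_idx, psd_idx)
    labels = np.asarray(b.labels, dtype=object)[idx]

    if np.isscalar(md) or (isinstance(md, np.ndarray) and md.ndim == 0):
        return StageResult(stage=str(labels[0]))
    return labels


def stage_distribution(cohort, boundaries: StageBoundaries | None = None) -> pd.DataFrame:
    """Per-group stage counts and proportions for a cohort.

    Accepts either a sequence of eye records (anything with ``md_db``,
    ``psd_db`` and ``group`` attributes) or a DataFrame with columns
    ``md_db``, ``psd_db``, ``group``.  Returns a tidy table with one row
    per (group, stage), counts summing to the cohort size.
    """
    if isinstance(cohort, pd.DataFrame):
        df = cohort[["group", "md_db", "psd_db"]].copy()
    else:
        df = pd.DataFrame(
            {"group": [e.group for e in cohort],
             "md_db": [e.md_db for e in cohort],
             "psd_db": [e.psd_db for e in cohort]}
        )
    b = boundaries or default_boundaries()
    rows = []
    if df.empty:
        groups: Iterable[str] = []
    else:
        groups = df["group"].unique()
    for g in groups:
        sub = df[df["group"] == g]
        stages = classify_gss2(sub["md_db"].to_numpy(), sub["psd_db"].to_numpy(), b)
        n = len(sub)
        for lab in b.labels:
            cnt = int((stages == lab).sum())
            rows.append({"group": g, "stage": lab, "n": cnt,
                         "proportion": cnt / n if n else 0.0})
    out = pd.DataFrame(rows, columns=["group", "stage", "n", "proportion"])
    return out
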
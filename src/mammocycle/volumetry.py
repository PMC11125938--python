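"""Per-scan volumetrics, TBV normalization, and study-style data cleaning."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import EmptyScanError
from .segmentation import Tissue, TissueLabelVolume

__all__ = [
    "BreastVolumetrics",
    "VolumeSeries",
    "CleaningRules",
    "compute_volumetrics",
    "normalize_by_tbv",
    "clean_series",
    "series_to_frame",
    "cohort_to_frame",
]

MM3_PER_CC = 1000.0


@dataclass(frozen=True)
class BreastVolumetrics:
    """Tissue volumes (cc) and quantitative breast density for one scan.

    Invariants: fgv_cc = gland_cc + duct_cc and
    tbv_cc = fat_cc + fgv_cc + skin_cc, both by construction.
    qbd = fgv_cc / tbv_cc is the continuous density measure.
    """

    tbv_cc: float
    gland_cc: float
    duct_cc: float
    fat_cc: float
    skin_cc: float
    scan_id: str = ""
    day: float = 0.0

    @property
    def fgv_cc(self) -> float:
        return self.gland_cc + self.duct_cc

    @property
    def qbd(self) -> float:
        return self.fgv_cc / self.tbv_cc if self.tbv_cc > 0 else float("nan")

    def __post_init__(self) -> None:
        parts = self.fat_cc + self.gland_cc + self.duct_cc + self.skin_cc
        if not np.isclose(parts, self.tbv_cc, rtol=0, atol=1e-6 * max(1.0, self.tbv_cc)):
            raise ValueError(
                f"volume additivity violated: fat+gland+duct+skin = {parts:g} "
                f"but tbv = {self.tbv_cc:g}"
            )


@dataclass
class VolumeSeries:
    """One breast's volumetrics over the study window.

    ``excluded`` holds a per-observation exclusion reason ("" = retained),
    aligned with ``observations``, which are kept sorted by day.
    """

    subject_id: str
    side: str                     # "L" or "R"
    group: str                    # "pre" | "peri" | "post"
    observations: list[BreastVolumetrics] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in ("pre", "peri", "post"):
            raise ValueError(f"unknown menopausal group {self.group!r}")
        self.observations = sorted(self.observations, key=lambda o: o.day)
        if not self.excluded:
            self.excluded = [""] * len(self.observations)
        if len(self.excluded) != len(self.observations):
            raise ValueError("excluded flags must align with observations")

    @property
    def breast_id(self) -> str:
        return f"{self.subject_id}{self.side}"

    @property
    def retained(self) -> list[BreastVolumetrics]:
        return [o for o, r in zip(self.observations, self.excluded) if not r]

    def values(self, tissue: str) -> np.ndarray:
        """Retained volume series for one tissue ('gland', 'duct', 'tbv', 'fgv')."""
        return np.array([getattr(o, f"{tissue}_cc") for o in self.retained])


def compute_volumetrics(
    labels: TissueLabelVolume, scan_id: str = "", day: float = 0.0
) -> BreastVolumetrics:
    """Convert a label volume to tissue volumes: voxel count x voxel volume.

    Raises :class:`EmptyScanError` when no breast voxels are present
    (TBV = 0), which is exactly the failure mode the cleaning step flags.
    """
    voxel_cc = float(np.prod(labels.voxel_size)) / MM3_PER_CC
    counts = np.bincount(labels.labels.ravel(), minlength=5)
    skin = counts[Tissue.SKIN] * voxel_cc
    fat = counts[Tissue.FAT] * voxel_cc
    gland = counts[Tissue.GLAND] * voxel_cc
    duct = counts[Tissue.DUCT] * voxel_cc
    tbv = skin + fat + gland + duct
    if tbv == 0.0:
        raise EmptyScanError(f"scan {scan_id!r}: no breast voxels")
    return BreastVolumetrics(tbv_cc=tbv, gland_cc=gland, duct_cc=duct,
                             fat_cc=fat, skin_cc=skin, scan_id=scan_id, day=day)


def normalize_by_tbv(series: VolumeSeries) -> pd.DataFrame:
    """Express gland and duct volumes as a percentage of TBV per timepoint.

    Returns a frame with both the raw cc values and the normalized
    percentages, one row per retained observation.
    """
    obs = series.retained
    if any(o.tbv_cc <= 0 for o in obs):
        raise EmptyScanError(f"breast {series.breast_id}: zero TBV in series")
    return pd.DataFrame({
        "scan_id": [o.scan_id for o in obs],
        "day": [o.day for o in obs],
        "gland_cc": [o.gland_cc for o in obs],
        "duct_cc": [o.duct_cc for o in obs],
        "tbv_cc": [o.tbv_cc for o in obs],
        "gland_pct_tbv": [100.0 * o.gland_cc / o.tbv_cc for o in obs],
        "duct_pct_tbv": [100.0 * o.duct_cc / o.tbv_cc for o in obs],
    })


@dataclass(frozen=True)
class CleaningRules:
    """Automated stand-in for the study's visual review of reconstructions.

    An observation is excluded when (a) it has zero TBV (an empty/failed
    scan), (b) fibroglandular volume is zero despite a non-zero TBV
    (a segmentation that found no gland or duct at all, the signature of a
    poor reconstruction), or (c) its glandular volume lies more than
    ``outlier_z`` robust SDs (modified z-score via the MAD) from its own
    breast's median.  The MAD is floored at ``scale_floor_frac`` of the
    median: in a short series with a luteal peak the raw MAD collapses to
    the measurement-noise scale and would flag the physiological peak
    itself; the floor keeps the rule aimed at reconstruction failures
    (order-of-magnitude anomalies), not cycle biology.
    """

    outlier_z: float = 5.0
    scale_floor_frac: float = 0.10
    flag_zero_fgv: bool = True


def _modified_z(x: np.ndarray, scale_floor_frac: float = 0.10) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = max(mad, scale_floor_frac * abs(med))
    if scale == 0.0:
        return np.zeros_like(x)
    return 0.6745 * (x - med) / scale


def clean_series(
    cohort: Iterable[VolumeSeries],
    rules: CleaningRules | None = None,
) -> tuple[list[VolumeSeries], pd.DataFrame]:
    """Flag anomalous observations and return (cleaned cohort, exclusion report).

    Cleaning never raises: series left with fewer than two retained
    observations are reported (reason ``series-too-short``) and dropped
    from the returned cohort.  The operation is idempotent.
    """
    rules = rules or CleaningRules()
    report_rows = []
    cleaned: list[VolumeSeries] = []
    for series in cohort:
        flags = list(series.excluded)
        gland = np.array([o.gland_cc for o in series.observations])
        tbv = np.array([o.tbv_cc for o in series.observations])
        fgv = np.array([o.fgv_cc for o in series.observations])

        for i, obs in enumerate(series.observations):
            if flags[i]:
                continue
            if tbv[i] <= 0:
                flags[i] = "empty-scan"
            elif rules.flag_zero_fgv and fgv[i] == 0.0:
                flags[i] = "zero-fgv"

        # robust outlier pass on the still-retained glandular values
        idx = [i for i, f in enumerate(flags) if not f]
        if len(idx) >= 3:
            z = _modified_z(gland[idx], rules.scale_floor_frac)
            for j, i in enumerate(idx):
                if abs(z[j]) > rules.outlier_z:
                    flags[i] = "gland-outlier"

        for i, obs in enumerate(series.observations):
            if flags[i] and not series.excluded[i]:
                report_rows.append({
                    "scan_id": obs.scan_id, "breast_id": series.breast_id,
                    "day": obs.day, "reason": flags[i],
                })

        n_keep = sum(1 for f in flags if not f)
        out = VolumeSeries(subject_id=series.subject_id, side=series.side,
                           group=series.group,
                           observations=list(series.observations),
                           excluded=flags)
        if n_keep >= 2:
            cleaned.append(out)
        else:
            report_rows.append({
                "scan_id": "", "breast_id": series.breast_id,
                "day": float("nan"), "reason": "series-too-short",
            })
    report = pd.DataFrame(report_rows,
                          columns=["scan_id", "breast_id", "day", "reason"])
    return cleaned, report


def series_to_frame(series: VolumeSeries) -> pd.DataFrame:
    """One row per observation (retained or not) with the full CSV schema."""
    rows = []
    for obs, reason in zip(series.observations, series.excluded):
        rows.append({
            "scan_id": obs.scan_id,
            "subject_id": series.subject_id,
            "breast": series.side,
            "breast_id": series.breast_id,
            "group": series.group,
            "day": obs.day,
            "tbv_cc": obs.tbv_cc,
            "fgv_cc": obs.fgv_cc,
            "gland_cc": obs.gland_cc,
            "duct_cc": obs.duct_cc,
            "fat_cc": obs.fat_cc,
            "skin_cc": obs.skin_cc,
            "qbd": obs.qbd,
            "excluded": bool(reason),
            "exclusion_reason": reason,
        })
    return pd.DataFrame(rows)


def cohort_to_frame(cohort: Iterable[VolumeSeries]) -> pd.DataFrame:
    frames = [series_to_frame(s) for s in cohort]
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
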
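"""PDX tumor-growth quantification.

Caliper length/width pairs become volumes via ``W^2 * L * 0.5`` (mm^3).
Tumors enter an efficacy analysis only when their volume at treatment
start lies in a configurable half-open window, default (60, 200] mm^3.
Each tumor's trajectory is normalized to its treatment-start volume
(relative tumor volume, so every curve starts at 1), integrated by the
trapezoid rule up to a chosen end day, and expressed relative to the
untreated-control arm: ``relative AUC = tumor AUC / mean(control
AUCs)``. Values below 1 indicate growth inhibition; the control arm's
mean relative AUC is 1 by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import InvariantError

logger = logging.getLogger("chemoresist")


def tumor_volume(length: float | np.ndarray, width: float | np.ndarray) -> float | np.ndarray:
    """Caliper volume W^2 * L * 0.5 in mm^3 (length >= width > 0)."""
    length = np.asarray(length, dtype=float)
    width = np.asarray(width, dtype=float)
    if np.any(width <= 0) or np.any(length <= 0):
        raise InvariantError("caliper axes must be positive")
    if np.any(width > length):
        raise InvariantError("width exceeds length — caliper axes swapped?")
    vol = width ** 2 * length * 0.5
    return float(vol) if vol.ndim == 0 else vol


@dataclass
class GrowthSeries:
    """Per-animal caliper series with treatment metadata.

    ``days`` count from treatment start (strictly increasing, and a
    measurement must exist at ``treatment_start_day``). ``volumes`` are
    mm^3; when built from calipers the raw axes are retained.
    """

    animal_id: str
    arm: str
    days: np.ndarray
    volumes: np.ndarray
    treatment_start_day: int = 0
    lengths: np.ndarray | None = None
    widths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if len(self.days) != len(self.volumes):
            raise InvariantError(f"{self.animal_id}: days/volumes length mismatch")
        if len(self.days) == 0:
            raise InvariantError(f"{self.animal_id}: empty series")
        if np.any(np.diff(self.days) <= 0):
            raise InvariantError(f"{self.animal_id}: days must be strictly increasing")
        if self.treatment_start_day not in self.days:
            raise InvariantError(
                f"{self.animal_id}: no measurement at treatment start day {self.treatment_start_day}"
            )
        if np.any(self.volumes <= 0):
            raise InvariantError(f"{self.animal_id}: volumes must be positive")

    @classmethod
    def from_caliper(cls, animal_id: str, arm: str, days, lengths_mm, widths_mm,
                     treatment_start_day: int = 0) -> "GrowthSeries":
        lengths = np.asarray(lengths_mm, dtype=float)
        widths = np.asarray(widths_mm, dtype=float)
        vols = tumor_volume(lengths, widths)
        return cls(animal_id, arm, np.asarray(days, dtype=int), np.asarray(vols, dtype=float),
                   treatment_start_day, lengths=lengths, widths=widths)

    @property
    def start_volume(self) -> float:
        return float(self.volumes[self.days == self.treatment_start_day][0])


def include_tumor(series: GrowthSeries, window: tuple[float, float]) -> bool:
    """True iff the treatment-start volume lies in the half-open window (min, max]."""
    lo, hi = window
    return lo < series.start_volume <= hi


def partition_by_inclusion(series_list: list[GrowthSeries],
                           window: tuple[float, float]) -> tuple[list[GrowthSeries], list[GrowthSeries]]:
    """Split series into (included, excluded) by the start-volume window; excluded are logged."""
    included = [s for s in series_list if include_tumor(s, window)]
    excluded = [s for s in series_list if not include_tumor(s, window)]
    if excluded:
        logger.info("inclusion window (%g, %g]: excluded %s",
                    window[0], window[1],
                    [(s.animal_id, round(s.start_volume, 1)) for s in excluded])
    return included, excluded


def relative_volume(series: GrowthSeries) -> pd.Series:
    """Volume divided by the treatment-start volume (value 1 at day 0), indexed by day."""
    v0 = series.start_volume
    if v0 <= 0:
        raise InvariantError(f"{series.animal_id}: zero start volume")
    rel = series.volumes / v0
    return pd.Series(rel, index=series.days - series.treatment_start_day, name=series.animal_id)


@dataclass
class EfficacyResult:
    """Per-tumor AUCs and arm summaries.

    ``per_tumor`` columns: animal, arm, auc (day units on the
    relative-volume scale), relative_auc (fraction of the control-arm
    mean), truncated (series ended before end_day). ``arm_summary``
    columns: arm, n, mean, sem of relative AUC.
    """

    per_tumor: pd.DataFrame
    arm_summary: pd.DataFrame
    end_day: int
    control_mean_auc: float


def _auc_to(series: GrowthSeries, end_day: float) -> tuple[float, bool]:
    rel = relative_volume(series)
    days = rel.index.to_numpy(dtype=float)
    mask = (days >= 0) & (days <= end_day)
    days = days[mask]
    vals = rel.to_numpy(dtype=float)[mask]
    if len(days) < 2:
        raise InvariantError(
            f"{series.animal_id}: needs >= 2 measurements in [0, {end_day}] for AUC, got {len(days)}"
        )
    truncated = days[-1] < end_day
    if truncated:
        logger.info("relative_auc: %s ends at day %g (< end_day %g); integrated to its last day",
                    series.animal_id, days[-1], end_day)
    return float(np.trapezoid(vals, days)), truncated


def relative_auc(treated: list[GrowthSeries], controls: list[GrowthSeries],
                 end_day: int) -> EfficacyResult:
    """Per-tumor trapezoid AUC of relative volume, normalized to the control-arm mean.

    Series are truncated at ``end_day``; a series ending earlier is
    integrated to its last measured day and flagged, never extrapolated.
    """
    if not controls:
        raise InvariantError("control arm is empty")
    rows = []
    control_aucs = []
    for s in controls:
        auc, trunc = _auc_to(s, end_day)
        control_aucs.append(auc)
        rows.append({"animal": s.animal_id, "arm": s.arm, "auc": auc, "truncated": trunc,
                     "is_control": True})
    control_mean = float(np.mean(control_aucs))
    if control_mean <= 0:
        raise InvariantError(f"control mean AUC must be positive, got {control_mean}")
    for s in treated:
        auc, trunc = _auc_to(s, end_day)
        rows.append({"animal": s.animal_id, "arm": s.arm, "auc": auc, "truncated": trunc,
                     "is_control": False})
    per_tumor = pd.DataFrame(rows)
    per_tumor["relative_auc"] = per_tumor["auc"] / control_mean
    summaries = []
    for arm, grp in per_tumor.groupby("arm", sort=True):
        x = grp["relative_auc"].to_numpy(dtype=float)
        sem = float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan
        summaries.append({"arm": arm, "n": len(x), "mean": float(np.mean(x)), "sem": sem})
    return EfficacyResult(
        per_tumor[["animal", "arm", "auc", "relative_auc", "truncated", "is_control"]],
        pd.DataFrame(summaries), int(end_day), control_mean,
    )
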
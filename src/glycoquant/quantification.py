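"""Per-cell, per-compartment intensity measurement and condition summaries.

The primary statistic is the arithmetic mean probe intensity per cell and
compartment (membrane band, cytoplasm, nucleus, whole cell), matching the
average-intensity-per-cell readout used for uptake time courses; the
integrated intensity (mean x area) is also emitted.  A scalar per-channel
background estimated from untreated control fields is subtracted before
summarization; corrected values may be negative (no clipping, so group
means stay unbiased).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .segmentation import CompartmentMasks

log = logging.getLogger(__name__)

COMPARTMENTS = ("pm", "cytoplasm", "nucleus", "whole_cell")


@dataclass
class IntensityRecord:
    field_id: str
    cell_id: int
    compartment: str
    mean_intensity: float
    integrated_intensity: float
    area: int
    probe: str = ""
    time_min: float = float("nan")
    uv_condition: str = ""
    cell_line: str = ""


@dataclass
class ConditionSummary:
    group: dict
    n_cells: int
    mean: float
    sd: float
    se: float
    degenerate: bool = False  # single-observation group


@dataclass
class BackgroundModel:
    """Scalar per-channel background estimated over untreated cell pixels."""

    background: float
    source_fields: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.background < 0:
            raise ValueError("background must be >= 0")


def measure_compartments(
    probe: np.ndarray,
    masks: CompartmentMasks,
    field_id: str = "field0",
    probe_id: str = "",
    time_min: float = float("nan"),
    uv_condition: str = "",
    cell_line: str = "",
) -> list[IntensityRecord]:
    """One record per retained cell per compartment plus the whole cell.

    Means are arithmetic means of the probe over the mask pixels; an empty
    compartment is skipped with a warning rather than silently zeroed.
    """
    probe = np.asarray(probe, dtype=float)
    if probe.shape != masks.cell_labels.shape:
        raise ValueError("probe raster shape does not match masks")
    records: list[IntensityRecord] = []
    meta = dict(field_id=field_id, probe=probe_id, time_min=time_min, uv_condition=uv_condition, cell_line=cell_line)
    for k in masks.labels():
        cell = masks.cell_labels == k
        comps = {
            "pm": masks.pm_mask & cell,
            "cytoplasm": masks.cytoplasm_mask & cell,
            "nucleus": masks.nucleus_labels == k,
            "whole_cell": cell,
        }
        for name, mask in comps.items():
            area = int(mask.sum())
            if area == 0:
                warnings.warn(f"cell {k}: compartment {name!r} is empty, record skipped", stacklevel=2)
                continue
            total = float(probe[mask].sum())
            records.append(
                IntensityRecord(
                    cell_id=k,
                    compartment=name,
                    mean_intensity=total / area,
                    integrated_intensity=total,
                    area=area,
                    **meta,
                )
            )
    return records


def records_to_frame(records: Iterable[IntensityRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def estimate_background(
    untreated: Sequence[tuple[np.ndarray, CompartmentMasks]],
    field_ids: Sequence[str] | None = None,
) -> BackgroundModel:
    """Mean probe intensity over all cell pixels of untreated fields.

    Pixels are pooled across fields.  With no untreated fields the model
    falls back to zero background with a logged warning.
    """
    if len(untreated) == 0:
        log.warning("no untreated fields supplied; background set to 0")
        return BackgroundModel(0.0, [])
    total, npix = 0.0, 0
    for probe, masks in untreated:
        cells = masks.cell_labels > 0
        total += float(np.asarray(probe, dtype=float)[cells].sum())
        npix += int(cells.sum())
    if npix == 0:
        log.warning("untreated fields contain no cells; background set to 0")
        return BackgroundModel(0.0, list(field_ids or []))
    return BackgroundModel(total / npix, list(field_ids or []))


def subtract_background(records: Iterable[IntensityRecord], model: BackgroundModel) -> list[IntensityRecord]:
    """Shift mean intensities down by the scalar background (no clipping)."""
    out = []
    for r in records:
        out.append(
            IntensityRecord(
                **{
                    **asdict(r),
                    "mean_intensity": r.mean_intensity - model.background,
                    "integrated_intensity": r.integrated_intensity - model.background * r.area,
                }
            )
        )
    return out


def summarize_conditions(
    records: Iterable[IntensityRecord],
    grouping: Sequence[str] = ("probe", "cell_line", "time_min", "uv_condition", "compartment"),
) -> list[ConditionSummary]:
    """Per-group n, mean, sample SD (n-1 denominator) and SE of the per-cell
    mean intensities.  Single-record groups report SD 0 and are flagged."""
    frame = records_to_frame(records)
    if frame.empty:
        raise ValueError("no records to summarize")
    summaries = []
    for keys, grp in frame.groupby(list(grouping), dropna=False, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        vals = grp["mean_intensity"].to_numpy()
        n = len(vals)
        sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
        summaries.append(
            ConditionSummary(
                group=dict(zip(grouping, keys)),
                n_cells=n,
                mean=float(vals.mean()),
                sd=sd,
                se=sd / np.sqrt(n),
                degenerate=(n == 1),
            )
        )
    return summaries


def summaries_to_frame(summaries: Iterable[ConditionSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append({**s.group, "n_cells": s.n_cells, "mean": s.mean, "sd": s.sd, "se": s.se, "degenerate": s.degenerate})
    return pd.DataFrame(rows)


@dataclass
class TTestResult:
    t: float
    p_value: float
    alternative: str
    degenerate: bool = False


def compare_groups_ttest(group_a: Sequence[float], group_b: Sequence[float], direction: str = "greater") -> TTestResult:
    """Classic two-sample Student's t-test (pooled variance), one-sided.

    ``direction='greater'`` tests mean(A) > mean(B).  Zero pooled variance
    is degenerate: p is 0 or 1 by the sign of the mean difference (0.5 at
    exact equality), flagged.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    pooled = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2)
    if pooled == 0:
        diff = a.mean() - b.mean()
        if diff == 0:
            return TTestResult(0.0, 0.5, direction, degenerate=True)
        favored = (diff > 0) == (direction == "greater")
        return TTestResult(float(np.sign(diff) * np.inf), 0.0 if favored else 1.0, direction, degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=True, alternative=direction)
    return TTestResult(float(res.statistic), float(res.pvalue), direction)


@dataclass
class TimecourseCurve:
    """Piecewise-linear interpolant through group means; no extrapolation."""

    times: np.ndarray
    means: np.ndarray

    def __call__(self, t: float | np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < self.times[0]) or np.any(t > self.times[-1]):
            raise ValueError(f"query outside observed time range [{self.times[0]}, {self.times[-1]}]")
        return np.interp(t, self.times, self.means)


def interpolate_timecourse(summaries: Sequence[ConditionSummary], time_key: str = "time_min") -> TimecourseCurve:
    """Exact linear interpolation through per-time group means.

    Duplicate time points (e.g. the same time from several groupings) are
    averaged first, with a log note.
    """
    pairs: dict[float, list[float]] = {}
    for s in summaries:
        pairs.setdefault(float(s.group[time_key]), []).append(s.mean)
    if any(len(v) > 1 for v in pairs.values()):
        log.info("duplicate time points averaged before interpolation")
    times = np.array(sorted(pairs))
    if len(times) < 2:
        raise ValueError("need at least 2 distinct time points to interpolate")
    means = np.array([float(np.mean(pairs[t])) for t in times])
    return TimecourseCurve(times=times, means=means)
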
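"""Gel lane densitometry and −UV/+UV incorporation ratios.

Lanes are located from the column-sum profile of the gel raster (lanes
appear as plateaus above the inter-lane baseline); each lane's 1-D
migration profile is integrated above a per-lane baseline estimated as
the median of the top and bottom 5% migration windows.  The −UV/+UV
signal ratio estimates the covalently incorporated probe fraction:
−UV samples retain only fixable (covalently bound) probe, so the ratio,
computed per replicate pair and then averaged, is the incorporation
efficiency.  Ladder / no-click / untreated / vehicle lanes are quantified
but excluded from the ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

log = logging.getLogger(__name__)


@dataclass
class LaneProfile:
    lane_id: int
    role: str
    profile: np.ndarray  # intensity (AU) vs migration position


@dataclass
class LaneBoundaries:
    bounds: list[tuple[int, int]]  # (start, stop) column ranges
    fallback: bool = False         # equal-width partition was used


@dataclass
class IncorporationResult:
    probe: str
    time_h: float
    ratio: float           # mean of per-replicate S(−UV)/S(+UV)
    percent: float         # 100 * ratio, not capped
    n_replicates: int
    se: float
    p_value: float | None = None
    flagged_over_100: bool = False


def detect_lanes(gel: np.ndarray, n_expected: int) -> LaneBoundaries:
    """Locate lane column ranges from the column-sum profile.

    Peaks (lane plateaus) are found with a prominence floor relative to the
    profile range; when fewer than ``n_expected`` peaks are found the gel is
    partitioned into equal-width lanes and the result is flagged.
    """
    gel = np.asarray(gel, dtype=float)
    if gel.ndim != 2:
        raise ValueError("gel must be a 2-D raster")
    if n_expected < 1:
        raise ValueError("n_expected must be >= 1")
    if gel.shape[1] < n_expected:
        raise ValueError(f"gel is only {gel.shape[1]} px wide; cannot hold {n_expected} lanes")
    if n_expected == 1:
        return LaneBoundaries(bounds=[(0, gel.shape[1])])

    col = gel.sum(axis=0)
    rng = col.max() - col.min()
    peaks: np.ndarray = np.array([], dtype=int)
    if rng > 0:
        min_dist = max(1, gel.shape[1] // (2 * n_expected))
        peaks, props = find_peaks(col, distance=min_dist, prominence=0.1 * rng, plateau_size=1)
        # use plateau centers so wide flat lanes localize to their middle
        peaks = ((props["left_edges"] + props["right_edges"]) // 2).astype(int)
    if len(peaks) < n_expected:
        log.warning("found %d lane peaks, expected %d; falling back to equal-width partition", len(peaks), n_expected)
        edges = np.linspace(0, gel.shape[1], n_expected + 1).astype(int)
        return LaneBoundaries(bounds=[(edges[i], edges[i + 1]) for i in range(n_expected)], fallback=True)
    if len(peaks) > n_expected:
        order = np.argsort(col[peaks])[::-1][:n_expected]
        peaks = np.sort(peaks[order])

    # equal-width spans centered on the lane plateaus: unequal spans would
    # dilute lanes unequally and bias lane-to-lane ratios
    width = int(np.median(np.diff(peaks)))
    width = max(2, min(width, gel.shape[1] // n_expected))
    bounds = []
    for center in peaks:
        start = int(center) - width // 2
        start = min(max(start, 0), gel.shape[1] - width)
        bounds.append((start, start + width))
    return LaneBoundaries(bounds=bounds)


def extract_profiles(gel: np.ndarray, boundaries: LaneBoundaries, roles: Sequence[str]) -> list[LaneProfile]:
    """Average each lane's columns into a 1-D migration profile."""
    gel = np.asarray(gel, dtype=float)
    if len(roles) != len(boundaries.bounds):
        raise ValueError("one role per lane required")
    return [
        LaneProfile(lane_id=i, role=role, profile=gel[:, start:stop].mean(axis=1))
        for i, ((start, stop), role) in enumerate(zip(boundaries.bounds, roles))
    ]


def integrate_lane(profile: LaneProfile | np.ndarray) -> float:
    """Background-subtracted integrated lane signal.

    Baseline is the median of the top and bottom 5% migration windows;
    signal is the sum of the positive part of (profile − baseline)."""
    prof = np.asarray(profile.profile if isinstance(profile, LaneProfile) else profile, dtype=float)
    if prof.size == 0:
        raise ValueError("empty profile")
    w = max(1, int(round(0.05 * len(prof))))
    baseline = float(np.median(np.concatenate([prof[:w], prof[-w:]])))
    return float(np.clip(prof - baseline, 0.0, None).sum())


def incorporation_ratio(
    minus_uv_signals: Sequence[float],
    plus_uv_signals: Sequence[float],
    probe: str = "",
    time_h: float = float("nan"),
) -> IncorporationResult:
    """Mean ± SE of per-replicate-pair S(−UV)/S(+UV); percent = 100 x mean.

    Replicates with non-positive +UV signal are dropped (logged).  Percent
    values can exceed 100 through noise; they are flagged, not capped.
    """
    minus = np.asarray(minus_uv_signals, dtype=float)
    plus = np.asarray(plus_uv_signals, dtype=float)
    if minus.shape != plus.shape:
        raise ValueError("−UV and +UV replicate lists must pair up")
    keep = plus > 0
    if not keep.all():
        log.warning("dropped %d replicate(s) with non-positive +UV signal", int((~keep).sum()))
    minus, plus = minus[keep], plus[keep]
    if len(minus) == 0:
        raise ValueError("no usable replicate pairs")
    ratios = minus / plus
    n = len(ratios)
    sd = float(np.std(ratios, ddof=1)) if n > 1 else 0.0
    mean = float(ratios.mean())
    return IncorporationResult(
        probe=probe,
        time_h=time_h,
        ratio=mean,
        percent=100.0 * mean,
        n_replicates=n,
        se=sd / np.sqrt(n),
        flagged_over_100=bool(mean > 1.0),
    )


def quantify_gel(
    gel: np.ndarray,
    roles: Sequence[str],
    probe: str = "",
    time_h: float = float("nan"),
) -> tuple[list[LaneProfile], dict[str, list[float]], IncorporationResult | None]:
    """Detect lanes, integrate every lane, and form the −UV/+UV ratio.

    Returns the lane profiles, a role → integrated-signals map, and the
    incorporation result (None when either UV arm is missing).  Control
    lanes (ladder, no-click, untreated, vehicle) are quantified but never
    enter the ratio.
    """
    boundaries = detect_lanes(gel, n_expected=len(roles))
    profiles = extract_profiles(gel, boundaries, roles)
    signals: dict[str, list[float]] = {}
    for lane in profiles:
        signals.setdefault(lane.role, []).append(integrate_lane(lane))
    result = None
    if signals.get("minusUV") and signals.get("plusUV"):
        n = min(len(signals["minusUV"]), len(signals["plusUV"]))
        result = incorporation_ratio(signals["minusUV"][:n], signals["plusUV"][:n], probe=probe, time_h=time_h)
    return profiles, signals, result
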
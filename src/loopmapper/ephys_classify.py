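"""Threshold-based response detection and population classification.

A unit is *positive* (excited) if its smoothed PSTH first crosses the
excitation threshold ``baseline mean + k_up * SD`` during the stimulation
period, *negative* (inhibited) if it first drops below ``baseline mean -
k_down * SD`` (floored at 0), and unresponsive otherwise.  Response latency
is the left edge of the first crossing bin.  Only units whose latency falls
inside the acceptance window (default 5-35 ms) count as responsive;
crossings before the lower bound are treated as potential antidromic
activation and render the unit unresponsive rather than being skipped over.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from loopmapper.ephys_psth import Psth, BaselineStats

__all__ = [
    "ResponseCriterion",
    "ResponseResult",
    "PopulationSummary",
    "detect_latency",
    "classify_population",
    "window_sensitivity",
    "latency_histogram",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("positive", "negative", "none")


@dataclass(frozen=True)
class ResponseCriterion:
    """Thresholds and latency window defining a significant response.

    ``k_up`` and ``k_down`` are baseline-SD multipliers for excitation and
    inhibition (defaults +3 SD and -1 SD).  ``latency_window`` is the
    half-open interval of acceptable latencies ``[min, max)``;
    ``search_duration`` is the stimulation-train duration scanned for
    crossings.
    """

    k_up: float = 3.0
    k_down: float = 1.0
    latency_window: tuple[float, float] = (0.005, 0.035)
    search_duration: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.latency_window
        if not (0 <= lo < hi <= self.search_duration):
            raise ValueError("latency window must satisfy 0 <= min < max <= search duration")
        if self.k_up <= 0 or self.k_down <= 0:
            raise ValueError("SD multipliers must be positive")


@dataclass
class ResponseResult:
    """Per-unit classification outcome.

    ``crossing_latency``/``crossing_sign`` record the first threshold
    crossing anywhere in the search window (used for latency histograms);
    ``latency`` is set only when that crossing lies inside the acceptance
    window, in which case ``category`` is its sign.
    """

    unit_id: str
    category: str
    latency: float | None
    up_threshold: float
    down_threshold: float
    criterion: ResponseCriterion
    crossing_latency: float | None = None
    crossing_sign: str | None = None
    unclassifiable: bool = False

    @property
    def responsive(self) -> bool:
        return self.category in ("positive", "negative")


@dataclass
class PopulationSummary:
    n_total: int
    n_positive: int
    n_negative: int
    n_none: int

    def __post_init__(self) -> None:
        if self.n_positive + self.n_negative + self.n_none != self.n_total:
            raise ValueError("category counts do not sum to n_total")

    @property
    def n_responsive(self) -> int:
        return self.n_positive + self.n_negative

    @property
    def proportions(self) -> dict[str, float]:
        return {
            "positive": self.n_positive / self.n_total,
            "negative": self.n_negative / self.n_total,
            "none": self.n_none / self.n_total,
        }

    @property
    def responsive_proportion(self) -> float:
        return self.n_responsive / self.n_total


def detect_latency(
    psth: Psth,
    baseline: BaselineStats,
    criterion: ResponseCriterion = ResponseCriterion(),
) -> ResponseResult:
    """Scan smoothed bins from laser onset for the first threshold crossing.

    When a bin crosses both thresholds (possible only in the degenerate case
    ``up < down``, which the floor rule prevents) or crossings tie on the
    same bin, excitation wins: disinhibition of the thalamo-cortical
    pathway predicts excitation.
    """
    up = baseline.mean_rate + criterion.k_up * baseline.sd_rate
    down = max(baseline.mean_rate - criterion.k_down * baseline.sd_rate, 0.0)
    if baseline.sd_rate == 0:
        logger.warning("unit %s: baseline SD = 0, unclassifiable", psth.unit_id)
        return ResponseResult(psth.unit_id, "none", None, up, down, criterion,
                              unclassifiable=True)
    i_start = psth.bin_index(0.0)
    i_stop = min(psth.bin_index(0.0) + int(round(criterion.search_duration / psth.bin_width)),
                 psth.smoothed_rate.size)
    seg = psth.smoothed_rate[i_start:i_stop]
    up_hits = np.flatnonzero(seg > up)
    down_hits = np.flatnonzero(seg < down)
    first_up = up_hits[0] if up_hits.size else np.inf
    first_down = down_hits[0] if down_hits.size else np.inf
    if np.isinf(first_up) and np.isinf(first_down):
        return ResponseResult(psth.unit_id, "none", None, up, down, criterion)
    sign = "positive" if first_up <= first_down else "negative"  # tie -> positive
    crossing = float(min(first_up, first_down) * psth.bin_width)
    lo, hi = criterion.latency_window
    if lo <= crossing < hi:
        return ResponseResult(psth.unit_id, sign, crossing, up, down, criterion,
                              crossing_latency=crossing, crossing_sign=sign)
    # crossing outside the window (incl. < 5 ms potential antidromic): unresponsive
    return ResponseResult(psth.unit_id, "none", None, up, down, criterion,
                          crossing_latency=crossing, crossing_sign=sign)


def classify_population(results: list[ResponseResult]) -> PopulationSummary:
    """Counts and proportions of positive / negative / unresponsive units."""
    if not results:
        raise ValueError("empty result list")
    ids = [r.unit_id for r in results]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate unit_id in population")
    n_pos = sum(r.category == "positive" for r in results)
    n_neg = sum(r.category == "negative" for r in results)
    return PopulationSummary(
        n_total=len(results),
        n_positive=n_pos,
        n_negative=n_neg,
        n_none=len(results) - n_pos - n_neg,
    )


def window_sensitivity(
    psths: list[Psth],
    baselines: list[BaselineStats],
    criterion: ResponseCriterion = ResponseCriterion(),
    windows: list[tuple[float, float]] = ((0.005, 0.015), (0.005, 0.025),
                                          (0.005, 0.035), (0.005, 0.045)),
) -> pd.DataFrame:
    """Re-classify the same cohort under each latency window.

    Returns one row per window with category counts and the responsive
    proportion.  For nested windows the responsive count is non-decreasing
    with window length.
    """
    if not psths:
        raise ValueError("empty cohort")
    if len(psths) != len(baselines):
        raise ValueError("psths and baselines must pair up")
    rows = []
    for win in windows:
        crit = ResponseCriterion(k_up=criterion.k_up, k_down=criterion.k_down,
                                 latency_window=win,
                                 search_duration=criterion.search_duration)
        summary = classify_population(
            [detect_latency(p, b, crit) for p, b in zip(psths, baselines)]
        )
        rows.append({
            "window_min_ms": win[0] * 1000, "window_max_ms": win[1] * 1000,
            "n_total": summary.n_total, "n_positive": summary.n_positive,
            "n_negative": summary.n_negative, "n_none": summary.n_none,
            "n_responsive": summary.n_responsive,
            "responsive_proportion": summary.responsive_proportion,
        })
    return pd.DataFrame(rows)


def latency_histogram(results: list[ResponseResult], bin_width: float = 0.005) -> pd.DataFrame:
    """Histogram of first-crossing latencies, window restriction disabled.

    Uses every unit with a detected crossing anywhere in the search window,
    whether or not it fell inside the acceptance window.
    """
    lats = np.array([r.crossing_latency for r in results if r.crossing_latency is not None])
    max_lat = max((r.criterion.search_duration for r in results), default=1.0)
    edges = np.arange(0.0, max_lat + bin_width, bin_width)
    counts = np.histogram(lats, bins=edges)[0] if lats.size else np.zeros(edges.size - 1, int)
    return pd.DataFrame({"bin_left_s": edges[:-1], "count": counts})


def results_to_frame(results: list[ResponseResult]) -> pd.DataFrame:
    """Per-unit classification table for CSV export."""
    return pd.DataFrame(
        [
            {
                "unit_id": r.unit_id,
                "category": r.category,
                "latency_ms": None if r.latency is None else r.latency * 1000,
                "up_threshold": r.up_threshold,
                "down_threshold": r.down_threshold,
                "unclassifiable": r.unclassifiable,
            }
            for r in results
        ]
    )
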
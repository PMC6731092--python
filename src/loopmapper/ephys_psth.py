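"""Peri-stimulus time histograms and baseline statistics for sorted units.

The PSTH convention follows the common in vivo optogenetics workflow: 1 ms
half-open bins aligned to laser onset at time 0 (a spike exactly at onset
falls in bin 0), trial-averaged firing rate in spikes/s, and a unit-area
Gaussian smoothing kernel truncated at +/-3 sigma with reflection padding at
the window edges so that total spike count is conserved.

Baseline (spontaneous) statistics are taken from a pre-onset window, by
default the final second before laser onset.  The mean spontaneous rate is
measured on the smoothed track; the SD that parameterizes the response
thresholds is measured on the *raw* 1 ms bins.  Raw-bin SD reflects the
counting noise of the spontaneous process itself; the SD of the smoothed
track shrinks with the kernel width, and using it would make the
``mean - SD`` inhibition threshold fire on a large fraction of perfectly
stationary Poisson units (see docs/methods.md).  A ``sd_track`` switch
restores the smoothed-bin variant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from loopmapper._protocol import StimProtocol

__all__ = [
    "UnitSpikes",
    "Psth",
    "BaselineStats",
    "build_psth",
    "baseline_stats",
    "gaussian_smooth",
    "write_unit_csv",
    "read_unit_csv",
    "write_psth_csv",
]


@dataclass
class UnitSpikes:
    """One sorted unit: spike timestamps plus the trial (laser-onset) times."""

    unit_id: str
    spike_times: np.ndarray
    trial_onsets: np.ndarray
    protocol: StimProtocol

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        self.trial_onsets = np.asarray(self.trial_onsets, dtype=float)
        if not np.all(np.isfinite(self.spike_times)) or not np.all(np.isfinite(self.trial_onsets)):
            raise ValueError("non-finite timestamps")
        if self.spike_times.size > 1 and not np.all(np.diff(self.spike_times) > 0):
            raise ValueError("spike_times must be strictly increasing")
        if self.trial_onsets.size == 0:
            raise ValueError("unit has no trials")
        if self.trial_onsets.size > 1:
            spacing = np.diff(self.trial_onsets)
            if not np.all(spacing > 0):
                raise ValueError("trial_onsets must be strictly increasing")
            if np.any(spacing < self.protocol.train_duration - 1e-9):
                raise ValueError("trial onsets closer than the stimulation train duration")

    @property
    def n_trials(self) -> int:
        return int(self.trial_onsets.size)


@dataclass
class Psth:
    """Binned, trial-averaged firing rate with raw and smoothed tracks."""

    bin_width: float
    window: tuple[float, float]  # (pre, post): bins cover [-pre, post)
    raw_rate: np.ndarray
    smoothed_rate: np.ndarray
    n_trials: int
    kernel_sigma: float
    unit_id: str = ""

    def __post_init__(self) -> None:
        self.raw_rate = np.asarray(self.raw_rate, dtype=float)
        self.smoothed_rate = np.asarray(self.smoothed_rate, dtype=float)
        if self.raw_rate.shape != self.smoothed_rate.shape:
            raise ValueError("raw and smoothed tracks must have identical length")
        if np.any(self.raw_rate < 0):
            raise ValueError("negative rate bin")

    @property
    def bin_edges(self) -> np.ndarray:
        """Left edges of the half-open bins, relative to laser onset."""
        pre, post = self.window
        n = self.raw_rate.size
        return -pre + np.arange(n) * self.bin_width

    def bin_index(self, t: float) -> int:
        """Index of the bin whose half-open interval contains time ``t``."""
        pre, _ = self.window
        return int(np.floor((t + pre) / self.bin_width))


@dataclass
class BaselineStats:
    """Spontaneous-rate mean and SD from a strictly pre-onset window."""

    mean_rate: float
    sd_rate: float
    baseline_window: tuple[float, float]
    sd_track: str = "raw"

    def __post_init__(self) -> None:
        if self.sd_rate < 0:
            raise ValueError("sd_rate must be non-negative")
        if self.baseline_window[1] > 0:
            raise ValueError("baseline window must end at or before laser onset")


def gaussian_smooth(rate: np.ndarray, bin_width: float, sigma: float) -> np.ndarray:
    """Convolve with a unit-area Gaussian truncated at +/-3 sigma, reflecting at edges.

    ``sigma`` is in seconds.  ``sigma`` smaller than a fraction of a bin
    degenerates to the identity.
    """
    rate = np.asarray(rate, dtype=float)
    if sigma < 0:
        raise ValueError("kernel sigma must be non-negative")
    radius = int(np.ceil(3.0 * sigma / bin_width))
    if radius == 0:
        return rate.copy()
    k = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (k * bin_width / sigma) ** 2)
    kernel /= kernel.sum()
    # 'reflect' (symmetric, edge-including) padding conserves total area:
    # every kernel tap that leaves the domain folds back onto a valid bin.
    return ndimage.convolve1d(rate, kernel, mode="reflect")


def build_psth(
    unit: UnitSpikes,
    bin_width: float = 0.001,
    window: tuple[float, float] = (1.0, 2.0),
    kernel_sigma: float = 0.002,
) -> Psth:
    """Trial-aligned PSTH with 1 ms half-open bins and Gaussian smoothing.

    ``window = (pre, post)`` covers ``[-pre, post)`` around each laser onset.
    Per-bin rate is the summed spike count across trials divided by
    ``n_trials * bin_width``.  Spikes outside every trial window are ignored.
    """
    pre, post = window
    if pre < 0 or post <= 0:
        raise ValueError("window must extend before and after onset")
    if post < unit.protocol.train_duration:
        raise ValueError("window must cover the stimulation train")
    n_bins = int(round((pre + post) / bin_width))
    edges = -pre + np.arange(n_bins + 1) * bin_width
    counts = np.zeros(n_bins)
    for onset in unit.trial_onsets:
        rel = unit.spike_times - onset
        rel = rel[(rel >= -pre) & (rel < edges[-1])]
        # np.histogram's last bin is closed; drop spikes landing exactly on
        # the right edge above so every bin behaves as half-open [l, r).
        counts += np.histogram(rel, bins=edges)[0]
    raw = counts / (unit.n_trials * bin_width)
    smoothed = gaussian_smooth(raw, bin_width, kernel_sigma)
    return Psth(
        bin_width=bin_width,
        window=window,
        raw_rate=raw,
        smoothed_rate=smoothed,
        n_trials=unit.n_trials,
        kernel_sigma=kernel_sigma,
        unit_id=unit.unit_id,
    )


def baseline_stats(
    psth: Psth,
    baseline_window: tuple[float, float] = (-1.0, 0.0),
    sd_track: str = "raw",
    min_bins: int = 50,
) -> BaselineStats:
    """Spontaneous mean and SD over the pre-onset baseline window.

    Mean is taken on the smoothed track (the track the thresholds are applied
    to); SD on the track selected by ``sd_track`` (population SD, divisor n).
    """
    start, end = baseline_window
    if end > 0:
        raise ValueError("baseline window must end at or before onset")
    pre, _ = psth.window
    if start < -pre - 1e-12:
        raise ValueError("baseline window extends before the PSTH window")
    if sd_track not in ("raw", "smoothed"):
        raise ValueError("sd_track must be 'raw' or 'smoothed'")
    i0 = psth.bin_index(start)
    i1 = psth.bin_index(end) if end > -pre else int(round((end + pre) / psth.bin_width))
    sel = slice(max(i0, 0), i1)
    n_sel = sel.stop - sel.start
    if n_sel < min_bins:
        raise ValueError(f"only {n_sel} baseline bins; need at least {min_bins} for a stable SD")
    mean = float(psth.smoothed_rate[sel].mean())
    track = psth.raw_rate if sd_track == "raw" else psth.smoothed_rate
    sd = float(track[sel].std(ddof=0))
    return BaselineStats(mean_rate=mean, sd_rate=sd, baseline_window=baseline_window, sd_track=sd_track)


# ---------------------------------------------------------------------------
# CSV interchange


def write_unit_csv(units: list[UnitSpikes], out_dir: str | Path) -> None:
    """Write spikes, trial events, and protocol sidecar for a cohort of units."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spikes = pd.DataFrame(
        [(u.unit_id, t) for u in units for t in u.spike_times],
        columns=["unit_id", "spike_time_s"],
    )
    spikes.to_csv(out / "spikes.csv", index=False)
    trials = pd.DataFrame(
        [(u.unit_id, i, t) for u in units for i, t in enumerate(u.trial_onsets)],
        columns=["unit_id", "trial_index", "onset_s"],
    )
    trials.to_csv(out / "trials.csv", index=False)
    proto = units[0].protocol if units else StimProtocol()
    with open(out / "protocol.json", "w") as fh:
        json.dump(
            {
                "pattern": proto.pattern,
                "train_duration": proto.train_duration,
                "pulse_width": proto.pulse_width,
                "frequency": proto.frequency,
                "n_trials": proto.n_trials,
                "inter_trial_interval": proto.inter_trial_interval,
            },
            fh,
            indent=2,
        )


def read_unit_csv(in_dir: str | Path) -> list[UnitSpikes]:
    """Read a cohort written by :func:`write_unit_csv` (or real exports in that schema)."""
    src = Path(in_dir)
    spikes = pd.read_csv(src / "spikes.csv")
    trials = pd.read_csv(src / "trials.csv")
    with open(src / "protocol.json") as fh:
        proto = StimProtocol(**json.load(fh))
    units = []
    for uid, tgrp in trials.groupby("unit_id", sort=False):
        sgrp = spikes[spikes.unit_id == uid]
        units.append(
            UnitSpikes(
                unit_id=str(uid),
                spike_times=np.sort(sgrp.spike_time_s.to_numpy()),
                trial_onsets=tgrp.sort_values("trial_index").onset_s.to_numpy(),
                protocol=proto,
            )
        )
    return units


def write_psth_csv(psth: Psth, path: str | Path) -> None:
    """One PSTH as CSV (bin_left_ms, raw_rate, smoothed_rate) plus JSON metadata."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "bin_left_ms": psth.bin_edges * 1000.0,
            "raw_rate": psth.raw_rate,
            "smoothed_rate": psth.smoothed_rate,
        }
    )
    df.to_csv(path, index=False)
    meta = {
        "unit_id": psth.unit_id,
        "bin_width_s": psth.bin_width,
        "window_s": list(psth.window),
        "n_trials": psth.n_trials,
        "kernel_sigma_s": psth.kernel_sigma,
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=2)
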
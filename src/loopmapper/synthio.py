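"""Seeded synthetic-data generators with known ground truth.

Three generators emulate the statistical structure the analysis stages
assume: inhomogeneous-Poisson spike trains under the optogenetic stimulation
protocol, double-exponential inhibitory synaptic currents under paired-pulse
stimulation, and labeled-cell point clouds with region-specific counts.

Reproducibility contract: every generator takes an explicit seed, and cohort
helpers derive per-item child seeds through ``numpy.random.SeedSequence``
spawn keys, so generating unit ``i`` is unaffected by how many other units
the cohort contains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from loopmapper._protocol import StimProtocol
from loopmapper.ephys_psth import UnitSpikes
from loopmapper.slice_ipsc import SweepTrace
from loopmapper.anatomy import CellPoint, RegionPartition

__all__ = [
    "StimProtocol",
    "EvokedSpec",
    "SweepSpec",
    "PointCloudSpec",
    "generate_unit",
    "generate_cohort",
    "generate_sweep",
    "generate_point_cloud",
    "child_rng",
    "write_sweep_csv",
    "write_point_cloud_csv",
]


def child_rng(seed: int, index: int) -> np.random.Generator:
    """Per-item generator derived from one master seed by a fixed splitting rule."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


@dataclass(frozen=True)
class EvokedSpec:
    """Ground truth for one simulated unit.

    ``response_sign`` 'positive' adds ``rate_delta`` spikes/s to the baseline
    rate inside the evoked window ``[latency_true, latency_true +
    response_duration]`` after each laser onset (clipped to the stimulation
    period); 'negative' subtracts it, floored at zero, since firing rates
    cannot be negative.
    """

    baseline_rate: float = 5.0
    response_sign: str = "none"
    latency_true: float = 0.010
    response_duration: float = 0.050
    rate_delta: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.baseline_rate, self.latency_true,
                            self.response_duration, self.rate_delta]).all():
            raise ValueError("non-finite EvokedSpec parameter")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be non-negative")
        if self.response_sign not in ("positive", "negative", "none"):
            raise ValueError(f"unknown response_sign {self.response_sign!r}")
        if self.latency_true < 0:
            raise ValueError("latency_true must be non-negative")
        if self.response_sign != "none" and self.response_duration <= 0:
            raise ValueError("response_duration must be positive for evoked units")
        if self.response_sign == "negative" and self.rate_delta > self.baseline_rate:
            raise ValueError("negative response cannot subtract more than the baseline rate")


def _rate_segments(spec: EvokedSpec, protocol: StimProtocol, pre_window: float):
    """Piecewise-constant rate as (onsets, evoked windows, rates) in session time."""
    onsets = protocol.trial_onsets(first_onset=pre_window)
    if spec.response_sign == "none" or spec.rate_delta == 0:
        return onsets, np.empty((0, 2)), spec.baseline_rate
    sign = 1.0 if spec.response_sign == "positive" else -1.0
    evoked_rate = max(spec.baseline_rate + sign * spec.rate_delta, 0.0)
    lo = np.minimum(spec.latency_true, protocol.train_duration)
    hi = np.minimum(spec.latency_true + spec.response_duration, protocol.train_duration)
    windows = np.column_stack([onsets + lo, onsets + hi])
    return onsets, windows, evoked_rate


def generate_unit(
    spec: EvokedSpec,
    protocol: StimProtocol = StimProtocol(),
    pre_window: float = 1.5,
    seed: int = 0,
    unit_id: str = "unit0",
) -> UnitSpikes:
    """Simulate one unit as an inhomogeneous Poisson process by thinning.

    A homogeneous candidate process at the ceiling rate is thinned by the
    ratio rate(t)/ceiling — exact for a piecewise-constant rate function.
    The session runs from 0 to ``last onset + train_duration +
    inter_trial_interval``, with the first laser onset at ``pre_window`` so
    every trial has at least that much pre-onset baseline.
    """
    if pre_window <= 0:
        raise ValueError("pre_window must be positive")
    onsets, windows, evoked_rate = _rate_segments(spec, protocol, pre_window)
    t_end = onsets[-1] + protocol.train_duration + protocol.inter_trial_interval
    rate_max = max(spec.baseline_rate, evoked_rate if windows.size else spec.baseline_rate)
    rng = np.random.default_rng(seed)
    if rate_max == 0:
        spikes = np.empty(0)
    else:
        n_cand = rng.poisson(rate_max * t_end)
        cand = np.sort(rng.uniform(0.0, t_end, size=n_cand))
        if windows.size:
            in_evoked = np.zeros(n_cand, dtype=bool)
            for lo, hi in windows:
                in_evoked |= (cand >= lo) & (cand < hi)
            rate_at = np.where(in_evoked, evoked_rate, spec.baseline_rate)
        else:
            rate_at = np.full(n_cand, spec.baseline_rate)
        keep = rng.uniform(size=n_cand) < rate_at / rate_max
        spikes = cand[keep]
        spikes = spikes[np.insert(np.diff(spikes) > 0, 0, True)]  # drop exact ties
    return UnitSpikes(unit_id=unit_id, spike_times=spikes, trial_onsets=onsets, protocol=protocol)


def generate_cohort(
    specs: list[EvokedSpec],
    protocol: StimProtocol = StimProtocol(),
    pre_window: float = 1.5,
    seed: int = 0,
    id_prefix: str = "unit",
) -> list[UnitSpikes]:
    """One unit per spec, each with its own child seed from the master seed."""
    return [
        generate_unit(
            spec, protocol, pre_window,
            seed=child_rng(seed, i).integers(2**31),
            unit_id=f"{id_prefix}{i:04d}",
        )
        for i, spec in enumerate(specs)
    ]


# ---------------------------------------------------------------------------
# Synaptic-current sweeps


@dataclass(frozen=True)
class SweepSpec:
    """Ground truth for one paired-pulse voltage-clamp sweep.

    Each optically evoked IPSC is a peak-normalized double exponential
    (difference of exponentials), so ``a1_true`` is the literal first-pulse
    peak amplitude in pA and the second response (amplitude ``a1_true *
    ppr_true``) is superposed linearly on the decay of the first.  The
    recorded current is inward (negative) as for GABA-A currents with a
    high-chloride internal at -70 mV.  Defaults mirror the slice protocol:
    50 ms inter-pulse interval, 10 kHz sampling.
    """

    a1_true: float = 100.0
    ppr_true: float = 0.7
    tau_rise: float = 0.0015
    tau_decay: float = 0.012
    inter_pulse_interval: float = 0.050
    noise_sd: float = 2.0
    sampling_rate: float = 10_000.0
    duration: float = 0.25
    first_pulse_time: float = 0.05

    def __post_init__(self) -> None:
        if not self.a1_true > 0 or not self.ppr_true > 0:
            raise ValueError("amplitudes must be positive")
        if not (self.tau_decay > self.tau_rise > 0):
            raise ValueError("need tau_decay > tau_rise > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.tau_rise * self.sampling_rate < 3:
            raise ValueError("sampling_rate too low: tau_rise must span >= 3 samples")


def _psc_kernel(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Difference-of-exponentials synaptic waveform, peak-normalized to 1, zero for t<0."""
    t_peak = tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    out = np.zeros_like(t)
    pos = t >= 0
    out[pos] = (np.exp(-t[pos] / tau_decay) - np.exp(-t[pos] / tau_rise)) / peak
    return out


def generate_sweep(spec: SweepSpec, seed: int = 0) -> SweepTrace:
    """Synthesize a paired-pulse IPSC sweep with additive white noise."""
    rng = np.random.default_rng(seed)
    dt = 1.0 / spec.sampling_rate
    t = np.arange(0.0, spec.duration, dt)
    p1 = spec.first_pulse_time
    p2 = p1 + spec.inter_pulse_interval
    current = -spec.a1_true * _psc_kernel(t - p1, spec.tau_rise, spec.tau_decay)
    current += -spec.a1_true * spec.ppr_true * _psc_kernel(t - p2, spec.tau_rise, spec.tau_decay)
    if spec.noise_sd > 0:
        current = current + rng.normal(0.0, spec.noise_sd, size=t.size)
    return SweepTrace(time=t, current=current, pulse_onsets=(p1, p2), baseline_window=p1)


# ---------------------------------------------------------------------------
# Anatomical point clouds


@dataclass
class PointCloudSpec:
    """Requested labeled-cell counts per named subregion of a partition."""

    per_region_counts: dict[str, int]
    region_partition: RegionPartition
    jitter: float = 0.0
    label: str = "synthetic-tracer"
    section_interval: float = 0.16  # mm; 160 um section series

    def __post_init__(self) -> None:
        if not self.region_partition.regions:
            raise ValueError("empty region partition")
        for name, n in self.per_region_counts.items():
            if name not in self.region_partition.regions:
                raise ValueError(f"unknown region {name!r}")
            if n < 0:
                raise ValueError("counts must be non-negative")


def generate_point_cloud(spec: PointCloudSpec, seed: int = 0) -> list[CellPoint]:
    """Draw the requested number of cells uniformly inside each region.

    A region made of several boxes is sampled proportionally to box volume.
    Optional Gaussian jitter is applied and clipped so points stay inside
    their box.  ``section_id`` is the AP coordinate rounded to the nearest
    section plane (plane 0 at AP = 0, spacing ``section_interval``).
    """
    rng = np.random.default_rng(seed)
    points: list[CellPoint] = []
    cell = 0
    for name in spec.region_partition.region_order:
        n = spec.per_region_counts.get(name, 0)
        if n == 0:
            continue
        boxes = spec.region_partition.regions[name]
        vols = np.array([np.prod([hi - lo for lo, hi in box]) for box in boxes])
        choice = rng.choice(len(boxes), size=n, p=vols / vols.sum())
        for b in choice:
            (ap0, ap1), (ml0, ml1), (dv0, dv1) = boxes[b]
            ap = rng.uniform(ap0, ap1)
            ml = rng.uniform(ml0, ml1)
            dv = rng.uniform(dv0, dv1)
            if spec.jitter > 0:
                ap = np.clip(ap + rng.normal(0, spec.jitter), ap0, ap1)
                ml = np.clip(ml + rng.normal(0, spec.jitter), ml0, ml1)
                dv = np.clip(dv + rng.normal(0, spec.jitter), dv0, dv1)
            points.append(
                CellPoint(
                    cell_id=f"cell{cell:05d}",
                    AP=float(ap),
                    ML=float(ml),
                    DV=float(dv),
                    section_id=int(round(ap / spec.section_interval)),
                    label=spec.label,
                )
            )
            cell += 1
    return points


# ---------------------------------------------------------------------------
# CSV interchange (spike CSVs live in ephys_psth, shared with real exports)


def write_sweep_csv(trace: SweepTrace, path: str | Path) -> None:
    """Sweep as CSV (time_s, current_pA) with pulse onsets in a JSON sidecar."""
    path = Path(path)
    pd.DataFrame({"time_s": trace.time, "current_pA": trace.current}).to_csv(path, index=False)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump({"pulse_onsets_s": list(trace.pulse_onsets),
                   "baseline_window_s": trace.baseline_window}, fh, indent=2)


def write_point_cloud_csv(points: list[CellPoint], path: str | Path) -> None:
    pd.DataFrame(
        [(p.cell_id, p.AP, p.ML, p.DV, p.section_id, p.label) for p in points],
        columns=["cell_id", "AP_mm", "ML_mm", "DV_mm", "section_id", "label"],
    ).to_csv(path, index=False)


def read_point_cloud_csv(path: str | Path) -> list[CellPoint]:
    df = pd.read_csv(path)
    return [
        CellPoint(cell_id=str(r.cell_id), AP=r.AP_mm, ML=r.ML_mm, DV=r.DV_mm,
                  section_id=int(r.section_id), label=str(r.label))
        for r in df.itertuples()
    ]
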
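"""End-to-end orchestration: simulate -> PSTH -> classify -> summarize -> stats.

A run is described by a plain-dict (YAML-friendly) configuration and executed
stage by stage; every stage writes CSV/JSON outputs plus a manifest entry
(parameters and an order-independent hash of the numeric outputs), so a rerun
with identical config and seed reproduces identical numbers.

Config schema (all blocks optional except ``stages``)::

    seed: 1
    stages: [simulate_spikes, psth_classify, ztests]
    protocol: {pattern: constant, train_duration: 1.0, n_trials: 30,
               inter_trial_interval: 4.0}
    criterion: {k_up: 3.0, k_down: 1.0, latency_window_ms: [5, 35]}
    psth: {kernel_sigma_ms: 2.0, baseline_s: 1.0}
    cohorts:                      # simulate_spikes + psth_classify
      - name: DLS_to_M1
        n_units: 60
        responsive_fraction: 0.24
        baseline_rate: 5.0
        rate_delta: 80.0
        latency_ms_range: [8, 30]
        response_duration_ms: 50
    ztest_pairs: [[DLS_to_M1, VS_to_M1]]
    sweeps:                       # simulate_sweeps + ipsc
      - {group: medial, n: 8, a1_true: 120, ppr_true: 0.7}
    cells:                        # simulate_cells + anatomy_distribution
      per_region_counts: {VMS: 30, VLS: 10, DMS: 25, DLS: 30, TS: 5}
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from loopmapper._protocol import StimProtocol
from loopmapper import synthio, ephys_psth, ephys_classify, slice_ipsc, anatomy, stats

__all__ = ["run_pipeline", "load_config"]

KNOWN_STAGES = (
    "simulate_spikes",
    "psth_classify",
    "ztests",
    "simulate_sweeps",
    "ipsc",
    "simulate_cells",
    "anatomy_distribution",
)


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _protocol(cfg: dict) -> StimProtocol:
    return StimProtocol(**cfg.get("protocol", {}))


def _criterion(cfg: dict) -> ephys_classify.ResponseCriterion:
    c = dict(cfg.get("criterion", {}))
    if "latency_window_ms" in c:
        lo, hi = c.pop("latency_window_ms")
        c["latency_window"] = (lo / 1000.0, hi / 1000.0)
    c.setdefault("search_duration", _protocol(cfg).train_duration)
    return ephys_classify.ResponseCriterion(**c)


def _cohort_specs(block: dict, rng: np.random.Generator) -> list[synthio.EvokedSpec]:
    n = int(block["n_units"])
    frac = float(block.get("responsive_fraction", 0.0))
    lat_lo, lat_hi = block.get("latency_ms_range", (8.0, 30.0))
    n_resp = int(round(frac * n))
    specs = []
    for i in range(n):
        if i < n_resp:
            specs.append(
                synthio.EvokedSpec(
                    baseline_rate=float(block.get("baseline_rate", 5.0)),
                    response_sign="positive",
                    latency_true=float(rng.uniform(lat_lo, lat_hi)) / 1000.0,
                    response_duration=float(block.get("response_duration_ms", 50.0)) / 1000.0,
                    rate_delta=float(block.get("rate_delta", 80.0)),
                )
            )
        else:
            specs.append(
                synthio.EvokedSpec(
                    baseline_rate=float(block.get("baseline_rate", 5.0)),
                    response_sign="none",
                )
            )
    return specs


def run_pipeline(config: dict, out_dir: str | Path, seed: int | None = None) -> dict:
    """Execute the configured stages in order; returns the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", []))
    unknown = set(stages) - set(KNOWN_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    seed = int(config.get("seed", 0) if seed is None else seed)
    manifest: dict[str, Any] = {"seed": seed, "stages": []}
    state: dict[str, Any] = {}

    for stage in stages:
        entry: dict[str, Any] = {"stage": stage, "outputs": {}}
        if stage == "simulate_spikes":
            proto = _protocol(config)
            cohorts = {}
            for ci, block in enumerate(config.get("cohorts", [])):
                rng = synthio.child_rng(seed, 1000 + ci)
                specs = _cohort_specs(block, rng)
                units = synthio.generate_cohort(
                    specs, proto, seed=int(rng.integers(2**31)),
                    id_prefix=f"{block['name']}_u",
                )
                cdir = out / "spikes" / block["name"]
                ephys_psth.write_unit_csv(units, cdir)
                cohorts[block["name"]] = units
                entry["outputs"][block["name"]] = _hash_file(cdir / "spikes.csv")
            state["cohorts"] = cohorts
        elif stage == "psth_classify":
            crit = _criterion(config)
            pcfg = config.get("psth", {})
            sigma = float(pcfg.get("kernel_sigma_ms", 2.0)) / 1000.0
            baseline_s = float(pcfg.get("baseline_s", 1.0))
            summaries = {}
            for name, units in state.get("cohorts", {}).items():
                results = []
                for u in units:
                    p = ephys_psth.build_psth(
                        u, window=(baseline_s, u.protocol.train_duration),
                        kernel_sigma=sigma,
                    )
                    b = ephys_psth.baseline_stats(p, (-baseline_s, 0.0))
                    results.append(ephys_classify.detect_latency(p, b, crit))
                ephys_classify.results_to_frame(results).to_csv(
                    out / f"classification_{name}.csv", index=False
                )
                s = ephys_classify.classify_population(results)
                summaries[name] = {
                    "n_total": s.n_total, "n_positive": s.n_positive,
                    "n_negative": s.n_negative, "n_none": s.n_none,
                    "responsive_proportion": s.responsive_proportion,
                }
            path = out / "population_summary.json"
            path.write_text(json.dumps(summaries, indent=2, sort_keys=True))
            entry["outputs"]["population_summary"] = _hash_file(path)
            state["summaries"] = summaries
        elif stage == "ztests":
            results = []
            for g1, g2 in config.get("ztest_pairs", []):
                s1, s2 = state["summaries"][g1], state["summaries"][g2]
                r = stats.two_proportion_z(stats.ProportionPair(
                    x1=s1["n_positive"] + s1["n_negative"], n1=s1["n_total"],
                    x2=s2["n_positive"] + s2["n_negative"], n2=s2["n_total"],
                ))
                results.append({"groups": [g1, g2], "z": r.statistic, "p": r.p_value})
            path = out / "ztests.json"
            path.write_text(json.dumps(results, indent=2))
            entry["outputs"]["ztests"] = _hash_file(path)
        elif stage == "simulate_sweeps":
            traces = {}
            for gi, block in enumerate(config.get("sweeps", [])):
                group = block["group"]
                for k in range(int(block["n"])):
                    spec = synthio.SweepSpec(
                        a1_true=float(block.get("a1_true", 100.0)),
                        ppr_true=float(block.get("ppr_true", 0.7)),
                        noise_sd=float(block.get("noise_sd", 2.0)),
                    )
                    child = synthio.child_rng(seed, 2000 + 100 * gi + k)
                    traces.setdefault(group, []).append(
                        synthio.generate_sweep(spec, seed=int(child.integers(2**31)))
                    )
            state["sweeps"] = traces
            entry["outputs"]["groups"] = sorted(traces)
        elif stage == "ipsc":
            measures = {
                g: [slice_ipsc.measure_ipsc(tr) for tr in trs]
                for g, trs in state.get("sweeps", {}).items()
            }
            frame = slice_ipsc.measures_to_frame(measures)
            path = out / "ipsc_measures.csv"
            frame.to_csv(path, index=False)
            entry["outputs"]["ipsc_measures"] = _hash_file(path)
            state["ipsc"] = measures
        elif stage == "simulate_cells":
            block = config.get("cells", {})
            partition = anatomy.RegionPartition.default_mouse()
            spec = synthio.PointCloudSpec(
                per_region_counts=dict(block.get("per_region_counts", {})),
                region_partition=partition,
                jitter=float(block.get("jitter", 0.0)),
            )
            pts = synthio.generate_point_cloud(
                spec, seed=int(synthio.child_rng(seed, 3000).integers(2**31))
            )
            path = out / "cells.csv"
            synthio.write_point_cloud_csv(pts, path)
            entry["outputs"]["cells"] = _hash_file(path)
            state["cells"] = (pts, partition)
        elif stage == "anatomy_distribution":
            pts, partition = state["cells"]
            dist = anatomy.normalized_distribution(pts, partition=partition)
            path = out / "distribution.csv"
            dist.to_csv(path, index=False)
            entry["outputs"]["distribution"] = _hash_file(path)
        manifest["stages"].append(entry)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
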
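import numpy as np
import pytest

from loopmapper import (
    StimProtocol,
    EvokedSpec,
    RegionPartition,
    build_psth,
    baseline_stats,
    generate_unit,
)
from loopmapper.synthio import child_rng


@pytest.fixture(scope="session")
def protocol():
    return StimProtocol()


@pytest.fixture(scope="session")
def mouse_partition():
    return RegionPartition.default_mouse()


def make_unit(spec: EvokedSpec, protocol: StimProtocol, master_seed: int, index: int):
    return generate_unit(
        spec, protocol,
        seed=int(child_rng(master_seed, index).integers(2**31)),
        unit_id=f"u{index:04d}",
    )


def psth_and_baseline(unit, kernel_sigma=0.002, baseline_s=1.0):
    p = build_psth(unit, window=(baseline_s, unit.protocol.train_duration),
                   kernel_sigma=kernel_sigma)
    return p, baseline_stats(p, (-baseline_s, 0.0))


@pytest.fixture(scope="session")
def positive_cohort(protocol):
    """200 excited units: true latency 10 ms, +80 sp/s on a 10 sp/s baseline."""
    spec = EvokedSpec(baseline_rate=10.0, response_sign="positive",
                      latency_true=0.010, response_duration=0.050, rate_delta=80.0)
    return [make_unit(spec, protocol, master_seed=7, index=i) for i in range(200)]


@pytest.fixture(scope="session")
def null_cohort(protocol):
    """500 stationary (unresponsive) units at the default baseline rate."""
    spec = EvokedSpec(response_sign="none")
    return [make_unit(spec, protocol, master_seed=11, index=i) for i in range(500)]
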
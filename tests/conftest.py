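import numpy as np
import pytest

from hat.detect import DetectionConfig
from hat.io import ProbeTrack
from hat.simulate import SimulationSpec, SpikeSpec, generate_null_track, spike_track


@pytest.fixture
def tiny_track() -> ProbeTrack:
    """Five probes on one chromosome; three positive intensities 3, 2, 1."""
    return ProbeTrack(
        "tiny",
        {"chr1": np.array([100, 135, 170, 205, 240])},
        {"chr1": np.array([3.0, 2.0, 1.0, -1.0, -2.0])},
    )


@pytest.fixture
def three_probe_track() -> ProbeTrack:
    """Probes at 0/50/100 bp offsets (positions 1, 51, 101), all positive."""
    return ProbeTrack(
        "three",
        {"chr1": np.array([1, 51, 101])},
        {"chr1": np.array([1.0, 1.0, 1.0])},
    )


@pytest.fixture
def default_config() -> DetectionConfig:
    return DetectionConfig(alpha=0.05, max_fragment_bp=600)


@pytest.fixture(scope="session")
def spiked_fixture():
    """A 10k-probe track with ten 600 bp spikes at +4 sigma plus its truth."""
    spec = SimulationSpec(
        n_probes=10_000,
        spacing_model="mixed-resolution",
        seed=20_260_927,
        spikes=[SpikeSpec(width_bp=600, effect=4.0, n=10)],
    )
    track = generate_null_track(spec)
    track, truth = spike_track(track, spec)
    return spec, track, truth
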
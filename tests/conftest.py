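import numpy as np
import pytest

from sfcscreen import (
    DEFAULT_GRADIENT,
    EMGPeakSpec,
    NoiseModel,
    PeakDescriptor,
    PeakTable,
    simulate_chromatogram,
)


@pytest.fixture
def gradient():
    return DEFAULT_GRADIENT


@pytest.fixture
def gaussian_chrom():
    """Factory: noise-free chromatogram with Gaussian-limit peaks."""

    def make(centers, sigmas, amps, run_length=441.0, step=0.05, noise_sd=0.0, seed=0):
        peaks = [
            EMGPeakSpec(f"a{i}", c, s, 0.0, a)
            for i, (c, s, a) in enumerate(zip(centers, sigmas, amps))
        ]
        return simulate_chromatogram(
            peaks, NoiseModel(noise_sd, 0.0, seed), run_length, step
        )

    return make


def make_random_table(rng, n_peaks=None, condition_id="rand"):
    """A random but valid peak table: sorted tr, positive widths."""
    n = n_peaks if n_peaks is not None else int(rng.integers(3, 12))
    trs = np.sort(rng.uniform(40.0, 420.0, n))
    # enforce distinct retention times so adjacent Rs > 0
    trs = trs + np.arange(n) * 1.0
    peaks = tuple(
        PeakDescriptor(
            analyte_id=f"c{i}",
            tr=float(t),
            height=float(rng.uniform(50, 2000)),
            area=float(rng.uniform(100, 5000)),
            base_width=float(rng.uniform(2.0, 40.0)),
            asymmetry=float(rng.uniform(0.8, 4.0)),
            snr=float(rng.uniform(1.0, 200.0)),
            k=float(t / 30.0 - 1.0),
        )
        for i, t in enumerate(trs)
    )
    return PeakTable(condition_id=condition_id, peaks=peaks)


@pytest.fixture
def random_table():
    return make_random_table
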
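import numpy as np
import pytest

from nmrdecomp import compute_stft, make_degradation_series, make_fid, stack_tensor
from nmrdecomp.synthetic import make_product_table

# STFT settings used for the degradation-series fixtures: short segments so
# the fast-decaying component is sampled by several frames
SEG, HOP = 128, 32


@pytest.fixture(scope="session")
def degradation():
    """Default 16-timepoint degradation series with ground truth."""
    return make_degradation_series()


@pytest.fixture(scope="session")
def degradation_tensor(degradation):
    fids, truth = degradation
    sgs = [compute_stft(f, SEG, HOP, "hann") for f in fids]
    return stack_tensor(sgs, list(truth["composition"].index))


@pytest.fixture(scope="session")
def reference_profiles(degradation):
    """Noiseless per-component frequency profiles on the fixture's STFT grid."""
    _, truth = degradation
    refs = []
    for lines in truth["components"].values():
        pure = make_fid(lines, n_points=2048, dwell_time=5e-5)
        refs.append(compute_stft(pure, SEG, HOP, "hann").magnitude.sum(axis=0))
    return np.array(refs)


@pytest.fixture(scope="session")
def product_table(degradation):
    _, truth = degradation
    return make_product_table(truth["times_h"])


def measure_fwhm(freqs, intens):
    """Full width at half maximum via linear interpolation of the crossings."""
    i = int(np.argmax(intens))
    half = intens[i] / 2.0
    li = i
    while intens[li] > half:
        li -= 1
    ri = i
    while intens[ri] > half:
        ri += 1
    fl = freqs[li] + (half - intens[li]) * (freqs[li + 1] - freqs[li]) / (
        intens[li + 1] - intens[li]
    )
    fr = freqs[ri - 1] + (half - intens[ri - 1]) * (freqs[ri] - freqs[ri - 1]) / (
        intens[ri] - intens[ri - 1]
    )
    return fr - fl


def naive_stft(signal, dwell, seg, hop, win):
    """Independent per-frame windowed DFT oracle (direct O(n^2) sums)."""
    n_frames = (len(signal) - seg) // hop + 1
    freqs = np.fft.fftshift(np.fft.fftfreq(seg, d=dwell))
    k = np.arange(seg)
    out = np.empty((n_frames, seg))
    for j in range(n_frames):
        frame = signal[j * hop : j * hop + seg] * win
        for b, f in enumerate(freqs):
            out[j, b] = abs(np.sum(frame * np.exp(-2j * np.pi * f * k * dwell)))
    return out, freqs
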
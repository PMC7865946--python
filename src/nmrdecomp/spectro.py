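"""Time-frequency processing of FIDs.

The short-time Fourier transform (STFT) converts a free-induction decay into
a time x frequency magnitude matrix: each windowed frame is Fourier
transformed, so the frequency axis resolves chemical shifts while the frame
axis tracks the T2* decay of every line.  Components with different T2*
therefore become separable patterns in the spectrogram, which is what the
non-negative factorizations in :mod:`nmrdecomp.factorize` exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import get_window, resample

from .io import FID, Spectrum1D

__all__ = [
    "Spectrogram",
    "SpectroTensor",
    "fourier_transform",
    "compute_stft",
    "stack_tensor",
    "interpolate_spectrum",
    "default_stft_params",
]

_WINDOWS = ("hann", "hamming", "boxcar")


@dataclass
class Spectrogram:
    """Non-negative time x frequency magnitude matrix from one FID.

    ``frame_times[j] = (j * hop + segment_length / 2) * dwell_time`` (frame
    centers).  Complex FIDs are analyzed two-sided with the frequency axis in
    ascending (fftshift) order.
    """

    magnitude: np.ndarray
    frame_times: np.ndarray
    frequencies: np.ndarray
    window: str = "hann"
    segment_length: int = 0
    hop: int = 0
    two_sided: bool = True
    source_label: str = ""

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.magnitude.ndim != 2:
            raise ValueError("magnitude must be 2-D (frames x frequencies)")
        if (self.magnitude < 0).any():
            raise ValueError("spectrogram magnitudes must be non-negative")
        if self.magnitude.shape != (self.frame_times.size, self.frequencies.size):
            raise ValueError("magnitude shape must match (frame_times, frequencies)")

    @property
    def n_frames(self) -> int:
        return self.magnitude.shape[0]

    @property
    def n_freq(self) -> int:
        return self.magnitude.shape[1]


@dataclass
class SpectroTensor:
    """Sample x time x frequency non-negative array stacked from spectrograms."""

    magnitude: np.ndarray
    sample_ids: list
    frame_times: np.ndarray
    frequencies: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if self.magnitude.ndim != 3:
            raise ValueError("tensor must be 3-D (samples x frames x frequencies)")
        if (self.magnitude < 0).any():
            raise ValueError("tensor magnitudes must be non-negative")
        if len(self.sample_ids) != self.magnitude.shape[0]:
            raise ValueError("sample_ids length must match first tensor dimension")

    @property
    def n_samples(self) -> int:
        return self.magnitude.shape[0]


def fourier_transform(
    fid: FID,
    zero_fill_factor: int = 1,
    apodization_hz: float = 0.0,
    mode: str = "magnitude",
) -> Spectrum1D:
    """Fourier transform an FID to a 1-D spectrum.

    Parameters
    ----------
    zero_fill_factor : int
        Transform length = n_points * zero_fill_factor (Fourier interpolation
        of the spectrum; adds no information).
    apodization_hz : float
        Exponential line broadening: the FID is multiplied by
        ``exp(-pi * lb * t)``, which adds ``lb`` Hz to every absorption-mode
        linewidth.
    mode : {"magnitude", "real", "complex"}
        ``real`` returns the absorption lineshape (real part), whose FWHM for
        an exponential decay with constant T2* is 1/(pi*T2*); ``magnitude``
        returns |S(f)|.
    """
    if int(zero_fill_factor) != zero_fill_factor or zero_fill_factor < 1:
        raise ValueError(f"zero_fill_factor must be a positive integer, got {zero_fill_factor}")
    if mode not in ("magnitude", "real", "complex"):
        raise ValueError(f"mode must be magnitude/real/complex, got {mode!r}")
    sig = fid.signal
    if apodization_hz:
        sig = sig * np.exp(-np.pi * apodization_hz * fid.times)
    n = fid.n_points * int(zero_fill_factor)
    spec = np.fft.fftshift(np.fft.fft(sig, n=n))
    freqs = np.fft.fftshift(np.fft.fftfreq(n, d=fid.dwell_time))
    if mode == "magnitude":
        intens = np.abs(spec)
    elif mode == "real":
        intens = spec.real
    else:  # complex spectra are carried as two stacked spectra by callers
        return Spectrum1D(freqs, np.abs(spec), label=fid.label)
    return Spectrum1D(freqs, intens, label=fid.label)


def default_stft_params(n_points: int) -> tuple[int, int]:
    """Default (segment_length, hop): n_points/8 rounded to a power of two, 50% overlap."""
    target = max(2, n_points // 8)
    seg = 2 ** int(round(np.log2(target)))
    seg = min(max(seg, 2), n_points)
    return seg, max(1, seg // 2)


def compute_stft(
    fid: FID,
    segment_length: Optional[int] = None,
    hop: Optional[int] = None,
    window: str = "hann",
) -> Spectrogram:
    """Short-time Fourier transform of an FID into a magnitude spectrogram.

    Frames are ``signal[j*hop : j*hop + segment_length]`` multiplied by the
    window and DFT'd (two-sided, fftshift order).  The number of frames is
    ``floor((n_points - segment_length) / hop) + 1``.
    """
    if segment_length is None or hop is None:
        d_seg, d_hop = default_stft_params(fid.n_points)
        segment_length = segment_length if segment_length is not None else d_seg
        hop = hop if hop is not None else d_hop
    segment_length = int(segment_length)
    hop = int(hop)
    if segment_length < 2:
        raise ValueError("segment_length must be >= 2")
    if segment_length > fid.n_points:
        raise ValueError(
            f"segment_length {segment_length} exceeds n_points {fid.n_points}; "
            "interpolate the FID (see interpolate_spectrum) or shorten the segment"
        )
    if not 1 <= hop <= segment_length:
        raise ValueError(f"hop must be in [1, segment_length], got {hop}")
    if window not in _WINDOWS:
        raise ValueError(f"window must be one of {_WINDOWS}, got {window!r}")

    win = get_window(window, segment_length, fftbins=True)
    n_frames = (fid.n_points - segment_length) // hop + 1
    idx = np.arange(segment_length)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = fid.signal[idx] * win[None, :]
    spec = np.fft.fftshift(np.fft.fft(frames, axis=1), axes=1)
    freqs = np.fft.fftshift(np.fft.fftfreq(segment_length, d=fid.dwell_time))
    frame_times = (hop * np.arange(n_frames) + segment_length / 2) * fid.dwell_time
    return Spectrogram(
        magnitude=np.abs(spec),
        frame_times=frame_times,
        frequencies=freqs,
        window=window,
        segment_length=segment_length,
        hop=hop,
        two_sided=True,
        source_label=fid.label,
    )


def stack_tensor(
    spectrograms: Sequence[Spectrogram], sample_ids: Optional[Sequence] = None
) -> SpectroTensor:
    """Stack spectrograms with identical axes into a sample x time x frequency tensor."""
    if len(spectrograms) < 2:
        raise ValueError("need at least 2 spectrograms to build a tensor")
    if sample_ids is None:
        sample_ids = [s.source_label or str(i) for i, s in enumerate(spectrograms)]
    if len(sample_ids) != len(spectrograms):
        raise ValueError("sample_ids length must match number of spectrograms")
    ref = spectrograms[0]
    for sid, s in zip(sample_ids, spectrograms):
        if s.segment_length != ref.segment_length or s.hop != ref.hop:
            raise ValueError(f"sample {sid!r}: STFT parameters differ from {sample_ids[0]!r}")
        if not (
            np.array_equal(s.frame_times, ref.frame_times)
            and np.array_equal(s.frequencies, ref.frequencies)
        ):
            raise ValueError(f"sample {sid!r}: time/frequency axes differ from {sample_ids[0]!r}")
    mag = np.stack([s.magnitude for s in spectrograms], axis=0)
    provenance = [
        {
            "source_label": s.source_label,
            "window": s.window,
            "segment_length": s.segment_length,
            "hop": s.hop,
        }
        for s in spectrograms
    ]
    return SpectroTensor(
        magnitude=mag,
        sample_ids=list(sample_ids),
        frame_times=ref.frame_times.copy(),
        frequencies=ref.frequencies.copy(),
        provenance=provenance,
    )


def interpolate_spectrum(
    spectrum_or_fid: Union[Spectrum1D, FID],
    factor: int,
    method: str = "fourier",
    mode: str = "magnitude",
) -> Spectrum1D:
    """Increase the digital resolution of a spectrum by an integer factor.

    ``fourier`` performs zero-filling: for an FID input the time-domain signal
    is zero-filled and re-transformed; for a spectrum input FFT-based
    resampling is used.  Either way the values at the original frequency bins
    are preserved (exactly, up to floating point), and no interpolation
    artifacts are introduced — unlike ``linear`` or ``cubic_spline`` which
    operate on the sampled intensities only.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    factor = int(factor)
    if method not in ("fourier", "linear", "cubic_spline"):
        raise ValueError(f"unknown interpolation method {method!r}")

    if isinstance(spectrum_or_fid, FID):
        fid = spectrum_or_fid
        if method == "fourier":
            return fourier_transform(fid, zero_fill_factor=factor, mode=mode)
        spectrum = fourier_transform(fid, zero_fill_factor=1, mode=mode)
    else:
        spectrum = spectrum_or_fid

    f = spectrum.frequencies
    y = spectrum.intensities
    if factor == 1:
        return Spectrum1D(f.copy(), y.copy(), axis_unit=spectrum.axis_unit, label=spectrum.label)
    df = (f[1] - f[0]) / factor
    new_f = f[0] + np.arange(f.size * factor) * df
    if method == "fourier":
        new_y = resample(y, f.size * factor)
    elif method == "linear":
        new_y = np.interp(new_f, f, y)
    else:
        new_y = CubicSpline(f, y)(new_f)
    return Spectrum1D(new_f, new_y, axis_unit=spectrum.axis_unit, label=spectrum.label)
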
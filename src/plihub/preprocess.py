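"""Band-limited FIR filtering and fixed-length epoching.

The five analysis bands are delta (2-4 Hz), theta (4-8 Hz), alpha
(8-13 Hz), beta (13-30 Hz) and gamma (30-60 Hz).  Each band is isolated
with a 4000th-order (4001-tap) linear-phase FIR bandpass designed with a
Hamming window.  The continuous record is filtered once per band and then
cut into contiguous 5-s epochs; the first and last epochs are dropped
before connectivity analysis to suppress residual edge transients.

Filtering a 5-s (1000-sample) epoch with a 4001-tap filter would be
ill-posed, so continuous-first ordering is the only coherent reading of
the procedure; the group delay of order/2 samples is compensated and the
edges are computed against reflection padding so the output stays
time-aligned and full length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import firwin, freqz, oaconvolve

from .montage_io import EEGRecording


@dataclass(frozen=True)
class BandSpec:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(f"invalid band edges {self.low_hz}-{self.high_hz} Hz")

    @property
    def center_hz(self) -> float:
        return 0.5 * (self.low_hz + self.high_hz)


#: Canonical analysis bands.
BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 2.0, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 13.0),
    BandSpec("beta", 13.0, 30.0),
    BandSpec("gamma", 30.0, 60.0),
)

BAND_BY_NAME = {b.name: b for b in BANDS}

DEFAULT_FILTER_ORDER = 4000
DEFAULT_EPOCH_LEN_S = 5.0


@dataclass(frozen=True)
class FilterSpec:
    band: BandSpec
    order: int = DEFAULT_FILTER_ORDER
    window: str = "hamming"

    def __post_init__(self) -> None:
        if self.order % 2 != 0:
            raise ValueError("filter order must be even (odd tap count, type I)")


@dataclass
class BandEpochs:
    """Contiguous, non-overlapping fixed-length segments of one band."""

    band: BandSpec
    epochs: np.ndarray  # epoch x channel x sample
    fs: float
    epoch_len_s: float = DEFAULT_EPOCH_LEN_S

    def __post_init__(self) -> None:
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be epoch x channel x sample")
        expect = int(round(self.epoch_len_s * self.fs))
        if self.epochs.shape[2] != expect:
            raise ValueError(
                f"epoch length {self.epochs.shape[2]} != epoch_len_s*fs = {expect}"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def design_bandpass(spec: FilterSpec, fs: float) -> np.ndarray:
    """Linear-phase FIR bandpass coefficients (odd length, symmetric)."""
    band = spec.band
    if band.high_hz >= fs / 2:
        raise ValueError(
            f"band edge {band.high_hz} Hz not below Nyquist ({fs / 2} Hz)"
        )
    taps = firwin(
        spec.order + 1,
        [band.low_hz, band.high_hz],
        window=spec.window,
        pass_zero=False,
        fs=fs,
    )
    # firwin's passband scaling leaves ~1-ulp asymmetry; enforce the exact
    # even symmetry that makes the phase response exactly linear
    return 0.5 * (taps + taps[::-1])


def design_notch(fs: float, low_hz: float = 58.0, high_hz: float = 62.0,
                 order: int = DEFAULT_FILTER_ORDER, window: str = "hamming") -> np.ndarray:
    """Optional mains band-stop (off by default; synthetic data has no mains)."""
    return firwin(order + 1, [low_hz, high_hz], window=window, pass_zero=True, fs=fs)


def filter_data(data: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Filter along the last axis with group-delay compensation.

    Pads each end with ``order/2`` reflected samples and convolves in
    'valid' mode, so the output has the input's length and is time-aligned.
    The computation runs in the input's floating dtype.
    """
    coeffs = np.asarray(coeffs)
    half = (coeffs.size - 1) // 2
    if data.shape[-1] <= coeffs.size:
        raise ValueError(
            f"record of {data.shape[-1]} samples is shorter than the "
            f"{coeffs.size}-tap filter"
        )
    pad = [(0, 0)] * (data.ndim - 1) + [(half, half)]
    padded = np.pad(data, pad, mode="reflect")
    kernel = coeffs.astype(data.dtype, copy=False)
    shape = (1,) * (data.ndim - 1) + (coeffs.size,)
    return oaconvolve(padded, kernel.reshape(shape), mode="valid")


def apply_filter(recording: EEGRecording, coeffs: np.ndarray) -> EEGRecording:
    """Return a band-filtered copy of *recording* (same length, time-aligned)."""
    return EEGRecording(
        montage=recording.montage,
        data=filter_data(recording.data, coeffs),
        fs=recording.fs,
        subject_id=recording.subject_id,
    )


def segment_epochs(
    recording: EEGRecording,
    band: BandSpec,
    epoch_len_s: float = DEFAULT_EPOCH_LEN_S,
    drop_edges: bool = True,
) -> BandEpochs:
    """Cut a (band-filtered) recording into contiguous fixed-length epochs.

    ``floor(duration / epoch_len_s)`` epochs are formed in temporal order;
    any trailing partial epoch is discarded.  With *drop_edges* the first
    and last epochs are removed (at least 3 must exist).
    """
    samples = int(round(epoch_len_s * recording.fs))
    n_total = recording.n_samples // samples
    n_needed = 3 if drop_edges else 1
    if n_total < n_needed:
        raise ValueError(
            f"record of {recording.duration_s:.1f} s yields {n_total} epochs of "
            f"{epoch_len_s} s; at least {n_needed} required"
        )
    arr = recording.data[:, : n_total * samples]
    epochs = arr.reshape(arr.shape[0], n_total, samples).transpose(1, 0, 2)
    if drop_edges:
        epochs = epochs[1:-1]
    return BandEpochs(band=band, epochs=np.ascontiguousarray(epochs),
                      fs=recording.fs, epoch_len_s=epoch_len_s)


def band_epochs(
    recording: EEGRecording,
    bands: Sequence[BandSpec] = BANDS,
    order: int = DEFAULT_FILTER_ORDER,
    window: str = "hamming",
    epoch_len_s: float = DEFAULT_EPOCH_LEN_S,
    drop_edges: bool = True,
    notch: bool = False,
) -> dict[str, BandEpochs]:
    """Filter a recording into each band and epoch it: the standard front end."""
    rec = recording
    if notch:
        rec = apply_filter(rec, design_notch(rec.fs, order=order, window=window))
    out = {}
    for band in bands:
        coeffs = design_bandpass(FilterSpec(band, order=order, window=window), rec.fs)
        filtered = apply_filter(rec, coeffs)
        out[band.name] = segment_epochs(filtered, band, epoch_len_s, drop_edges)
    return out


def frequency_response_db(coeffs: np.ndarray, freqs_hz: Sequence[float], fs: float) -> np.ndarray:
    """Magnitude response in dB at the given frequencies."""
    _, h = freqz(coeffs, worN=np.asarray(freqs_hz, dtype=float), fs=fs)
    mag = np.abs(h)
    return 20.0 * np.log10(np.maximum(mag, 1e-300))
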
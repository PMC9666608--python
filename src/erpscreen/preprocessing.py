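"""Artifact rejection, Welch spectra, and four-band decomposition.

Records are cleaned with a +-100 uV amplitude rule applied to 1-s
segments, transformed with a 1-s Hann-window 50%-overlap averaged
periodogram, and split into the four clinical EEG bands with zero-phase
sixth-order elliptic bandpass filters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy import signal as _signal

from .synthetic import BAND_NAMES, ERPRecord

__all__ = [
    "BandDefinition",
    "BANDS",
    "BandSet",
    "PowerSpectrum",
    "UnusableRecordError",
    "reject_artifacts",
    "spectral_transform",
    "bandpass_filter",
    "decompose_bands",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float

    def validate(self, sampling_rate: float) -> None:
        nyquist = sampling_rate / 2.0
        if not (0.0 < self.low_hz < self.high_hz < nyquist):
            raise ValueError(
                f"band {self.name} ({self.low_hz}-{self.high_hz} Hz) must "
                f"satisfy 0 < low < high < Nyquist ({nyquist} Hz)"
            )


#: Canonical band edges.  Delta is printed in the clinical literature as
#: "< 4 Hz"; a 0.5 Hz floor excludes DC and slow drift.  The 12-13 Hz gap
#: between Alpha and Beta is deliberate: no band covers it.
BANDS: dict[str, BandDefinition] = {
    "Delta": BandDefinition("Delta", 0.5, 4.0),
    "Theta": BandDefinition("Theta", 4.0, 8.0),
    "Alpha": BandDefinition("Alpha", 8.0, 12.0),
    "Beta": BandDefinition("Beta", 13.0, 30.0),
}


@dataclass
class BandSet:
    """Raw signal plus its four band-filtered versions (equal lengths)."""

    raw: np.ndarray
    bands: dict[str, np.ndarray]

    def __post_init__(self):
        for name in BAND_NAMES:
            if name not in self.bands:
                raise ValueError(f"missing band {name}")
            if len(self.bands[name]) != len(self.raw):
                raise ValueError(f"band {name} length differs from raw")


@dataclass(frozen=True)
class PowerSpectrum:
    frequencies: np.ndarray  # Hz
    power: np.ndarray  # uV^2/Hz


class UnusableRecordError(ValueError):
    """Raised when artifact rejection would discard the whole record."""


def reject_artifacts(
    record: ERPRecord, threshold_uv: float = 100.0
) -> tuple[ERPRecord, int]:
    """Drop 1-s segments containing any sample beyond ``+-threshold_uv``.

    The signal is cut into consecutive 1-s segments (a shorter trailing
    remainder counts as a segment); segments with any ``|x| > threshold``
    are excluded and the survivors concatenated.  Returns the cleaned
    record and the number of rejected segments.  Idempotent: a cleaned
    record passes through unchanged.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold_uv must be > 0")
    x = np.asarray(record.signal, dtype=float)
    seg_len = int(round(record.sampling_rate))
    n_segments = max(1, int(np.ceil(len(x) / seg_len)))
    kept = []
    n_rejected = 0
    for i in range(n_segments):
        seg = x[i * seg_len : (i + 1) * seg_len]
        if seg.size == 0:
            continue
        if np.any(np.abs(seg) > threshold_uv):
            n_rejected += 1
        else:
            kept.append(seg)
    if not kept:
        raise UnusableRecordError(
            f"record {record.subject_id}/{record.modality}/{record.electrode}: "
            f"all {n_segments} segments exceed +-{threshold_uv} uV"
        )
    cleaned = _dc_replace(record, signal=np.concatenate(kept))
    return cleaned, n_rejected


def spectral_transform(
    signal: np.ndarray, sampling_rate: float, window_s: float = 1.0, overlap: float = 0.5
) -> PowerSpectrum:
    """Averaged periodogram: Hann-tapered windows of ``window_s`` seconds
    with fractional ``overlap``, scaled to power spectral density."""
    x = np.asarray(signal, dtype=float)
    nperseg = int(round(window_s * sampling_rate))
    if len(x) < nperseg:
        raise ValueError(
            f"signal ({len(x)} samples) shorter than one {window_s}-s window "
            f"({nperseg} samples)"
        )
    freqs, pxx = _signal.welch(
        x,
        fs=sampling_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(nperseg * overlap)),
        detrend=False,
    )
    return PowerSpectrum(frequencies=freqs, power=pxx)


def _design_sos(
    band: BandDefinition,
    sampling_rate: float,
    ripple_db: float,
    atten_db: float,
) -> np.ndarray:
    nyquist = sampling_rate / 2.0
    sos = _signal.ellip(
        6,
        ripple_db,
        atten_db,
        [band.low_hz / nyquist, band.high_hz / nyquist],
        btype="bandpass",
        output="sos",
    )
    return sos


def bandpass_filter(
    signal: np.ndarray,
    band: BandDefinition,
    sampling_rate: float,
    ripple_db: float = 0.1,
    atten_db: float = 40.0,
) -> np.ndarray:
    """Zero-phase sixth-order elliptic bandpass.

    The order-6 design is applied forward and backward (``sosfiltfilt``) so
    downstream features never see phase distortion; the squared magnitude
    response doubles both the (small) passband ripple and the stopband
    attenuation.
    """
    band.validate(sampling_rate)
    x = np.asarray(signal, dtype=float)
    sos = _design_sos(band, sampling_rate, ripple_db, atten_db)
    y = _signal.sosfiltfilt(sos, x)
    if not np.all(np.isfinite(y)):
        raise ValueError(
            f"elliptic design for band {band.name} unstable at "
            f"{sampling_rate} Hz (non-finite output)"
        )
    return y


def decompose_bands(
    record: ERPRecord,
    bands: dict[str, BandDefinition] | None = None,
    ripple_db: float = 0.1,
    atten_db: float = 40.0,
) -> BandSet:
    """Filter a (cleaned) record into the four bands, keeping the raw
    signal alongside."""
    bands = bands if bands is not None else BANDS
    x = np.asarray(record.signal, dtype=float)
    filtered = {
        name: bandpass_filter(x, band, record.sampling_rate, ripple_db, atten_db)
        for name, band in bands.items()
    }
    return BandSet(raw=x, bands=filtered)
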
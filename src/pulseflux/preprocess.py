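"""Filtering and window slicing.

PPG traces are band-pass filtered with a second-order Chebyshev type-I
design (0.5--6 Hz, 0.5 dB passband ripple), applied forward--backward so
fiducial timing is not shifted; "second-order" refers to the designed
prototype, the effective two-pass order is doubled.  LDF traces are
low-pass filtered (same family and order, default 2 Hz cut-off) to remove
pump-actuation harmonics while preserving the DC flux level: the designed
low-pass is renormalized to exactly unit gain at DC, since an even-order
Chebyshev-I prototype otherwise sits at the ripple floor at DC and would
bias the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core_io import (
    ConfigError,
    MODALITY_LDF,
    MODALITY_PPG,
    SignalRecord,
    Window,
)

__all__ = ["FilterSpec", "bandpass_ppg", "lowpass_ldf", "slice_window"]


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass design for PPG pulse extraction."""

    family: str = "chebyshev1"
    order: int = 2
    band_low_hz: float = 0.5
    band_high_hz: float = 6.0
    passband_ripple_db: float = 0.5
    zero_phase: bool = True

    def validate(self, sampling_rate: float) -> None:
        if self.family != "chebyshev1":
            raise ConfigError(f"unsupported filter family {self.family!r}")
        if self.order < 1:
            raise ConfigError(f"order must be >= 1, got {self.order}")
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ConfigError(
                f"band must satisfy 0 < low < high, got ({self.band_low_hz}, {self.band_high_hz})"
            )
        if not self.band_high_hz < sampling_rate / 2:
            raise ConfigError(
                f"band_high_hz {self.band_high_hz} must lie below the Nyquist rate "
                f"{sampling_rate / 2}"
            )
        if not self.passband_ripple_db > 0:
            raise ConfigError(
                f"passband_ripple_db must be > 0, got {self.passband_ripple_db}"
            )


def _design_bandpass(spec: FilterSpec, sampling_rate: float) -> np.ndarray:
    spec.validate(sampling_rate)
    return sps.cheby1(
        spec.order,
        spec.passband_ripple_db,
        [spec.band_low_hz, spec.band_high_hz],
        btype="bandpass",
        fs=sampling_rate,
        output="sos",
    )


def _design_lowpass(
    cutoff_hz: float, sampling_rate: float, order: int = 2, ripple_db: float = 0.5
) -> np.ndarray:
    if not 0 < cutoff_hz < sampling_rate / 2:
        raise ConfigError(
            f"cutoff_hz must lie in (0, Nyquist={sampling_rate / 2}), got {cutoff_hz}"
        )
    sos = sps.cheby1(order, ripple_db, cutoff_hz, btype="lowpass", fs=sampling_rate, output="sos")
    # Renormalize to unit DC gain (even-order Chebyshev-I sits at the ripple
    # floor at DC, which would scale the preserved mean).
    dc = np.prod([(s[0] + s[1] + s[2]) / (s[3] + s[4] + s[5]) for s in sos])
    sos[0, :3] /= dc
    return sos


def bandpass_ppg(record: SignalRecord, spec: FilterSpec | None = None) -> SignalRecord:
    """Zero-phase band-pass of a PPG record (same length and metadata, DC removed)."""
    if record.modality != MODALITY_PPG:
        raise ConfigError(f"bandpass_ppg expects a PPG record, got {record.modality!r}")
    spec = spec or FilterSpec()
    sos = _design_bandpass(spec, record.sampling_rate)
    if spec.zero_phase:
        filtered = sps.sosfiltfilt(sos, record.samples)
    else:
        filtered = sps.sosfilt(sos, record.samples)
    return record.with_samples(filtered, filtered=True)


def lowpass_ldf(record: SignalRecord, cutoff_hz: float = 2.0) -> SignalRecord:
    """Zero-phase low-pass of an LDF record; preserves the signal mean."""
    if record.modality != MODALITY_LDF:
        raise ConfigError(f"lowpass_ldf expects an LDF record, got {record.modality!r}")
    sos = _design_lowpass(cutoff_hz, record.sampling_rate)
    filtered = sps.sosfiltfilt(sos, record.samples)
    return record.with_samples(filtered, filtered=True)


def slice_window(record: SignalRecord, window: Window) -> np.ndarray:
    """Contiguous samples covering ``[start_s, start_s + length_s)`` of a window."""
    start = int(round(window.start_s * record.sampling_rate))
    stop = int(round((window.start_s + window.length_s) * record.sampling_rate))
    if start < 0 or stop > record.n_samples:
        raise IndexError(
            f"window {window.index} ([{window.start_s}, {window.end_s}) s) lies outside "
            f"the {record.duration_s} s recording"
        )
    return record.samples[start:stop]
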
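"""LDF features: per-window DC mean flux and quadratic trend fits.

The DC component of the flux trace is operationalized as the window mean of
the (low-pass filtered) signal; since the zero-phase low-pass preserves the
mean, this equals the window mean of the raw trace up to the attenuated
high-frequency content.  Per-recording trends over the window means are
summarized with an ordinary least-squares quadratic against window midpoint
times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import SignalRecord, Window, windows_of
from .preprocess import slice_window

__all__ = [
    "LDFWindowFeature",
    "PolyFit",
    "dc_mean_flux",
    "ldf_feature_table",
    "fit_poly2",
]


@dataclass(frozen=True)
class LDFWindowFeature:
    window: Window
    dc_mean_flux: float


@dataclass(frozen=True)
class PolyFit:
    """Quadratic trend y = c0 + c1*t + c2*t**2 with residual RMSE."""

    c0: float
    c1: float
    c2: float
    rmse: float


def dc_mean_flux(record: SignalRecord, window: Window) -> LDFWindowFeature:
    """Arithmetic mean of the flux samples in one window."""
    if record.modality != "ldf":
        raise ValueError(f"dc_mean_flux expects an LDF record, got {record.modality!r}")
    values = slice_window(record, window)
    return LDFWindowFeature(window=window, dc_mean_flux=float(values.mean()))


def ldf_feature_table(
    records: list[SignalRecord], window_length_s: float = 10.0
) -> pd.DataFrame:
    """Per-window DC mean flux rows for a set of LDF records."""
    rows = []
    for record in records:
        for window in windows_of(record, window_length_s):
            feat = dc_mean_flux(record, window)
            rows.append(
                {
                    "record_id": record.record_id,
                    "bmf": record.bmf,
                    "phantom_class": record.phantom_class,
                    "young_modulus_mpa": record.young_modulus_mpa,
                    "window_index": window.index,
                    "window_midpoint_s": window.midpoint_s,
                    "dc_mean_flux": feat.dc_mean_flux,
                }
            )
    return pd.DataFrame(rows)


def fit_poly2(times_s: Sequence[float], values: Sequence[float]) -> PolyFit:
    """Ordinary least-squares quadratic through (time, flux-mean) points.

    Requires at least three points with at least three distinct times (a
    collinear-in-time design is degenerate).
    """
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D sequences of equal length")
    if len(t) < 3:
        raise ValueError(f"fit_poly2 requires >= 3 points, got {len(t)}")
    if len(np.unique(t)) < 3:
        raise ValueError("fit_poly2 requires >= 3 distinct time points")
    coeffs = np.polynomial.polynomial.polyfit(t, y, 2)
    residuals = y - np.polynomial.polynomial.polyval(t, coeffs)
    rmse = float(np.sqrt(np.mean(residuals**2)))
    return PolyFit(c0=float(coeffs[0]), c1=float(coeffs[1]), c2=float(coeffs[2]), rmse=rmse)


def ldf_polyfit_table(features: pd.DataFrame) -> pd.DataFrame:
    """One quadratic fit per recording from a long per-window flux table."""
    rows = []
    for record_id, group in features.groupby("record_id", sort=True):
        fit = fit_poly2(group["window_midpoint_s"], group["dc_mean_flux"])
        rows.append(
            {
                "record_id": record_id,
                "bmf": group["bmf"].iloc[0],
                "phantom_class": group["phantom_class"].iloc[0],
                "c0": fit.c0,
                "c1": fit.c1,
                "c2": fit.c2,
                "rmse": fit.rmse,
            }
        )
    return pd.DataFrame(rows)
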
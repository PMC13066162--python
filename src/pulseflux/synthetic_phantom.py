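"""Synthetic phantom recordings with the statistical structure of the bench study.

The generator emulates 4-minute acquisitions from vessel--tissue phantoms
driven by a pulsatile pump at 60 bpm: PPG light-intensity traces sampled at
2000 Hz at 530/655/940 nm, and LDF flux traces whose DC level falls with
vessel stiffness.  The structure it reproduces:

* pulse amplitude and area shrink as the vessel stiffens (reduced pulsatile
  expansion), with a terminal "end-datum" elevation that grows with
  stiffness (sharper, incompletely decaying pulses);
* flux falls with stiffness -- the Poiseuille picture of a stiffer,
  higher-resistance vessel passing less flow -- with a wider healthy-to-
  unhealthy spread for the intralipid blood-mimicking fluid (BMF);
* the LPFS BMF scatters less, so PPG amplitudes are larger than with
  intralipid at matched class and wavelength, while intralipid strongly
  scatters the infra-red channel (noisier, suppressed IR).

Poiseuille utilities (:func:`tube_resistance`, :func:`poiseuille_flow`)
parameterize the flux levels; everything else is a parametric beat-template
model, deterministic given the configuration seed.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import (
    BMF_INTRALIPID,
    BMF_LPFS,
    BMFS,
    CLASS_YOUNG_MODULUS_MPA,
    ConfigError,
    DatasetManifest,
    MODALITY_LDF,
    MODALITY_PPG,
    PHANTOM_CLASSES,
    PPG_WAVELENGTHS_NM,
    SignalRecord,
    write_signal,
)

__all__ = [
    "HaemodynamicParams",
    "BeatShape",
    "GeneratorConfig",
    "tube_resistance",
    "poiseuille_flow",
    "make_beat_template",
    "synthesize_ppg",
    "synthesize_ldf",
    "generate_records",
    "generate_dataset",
]


# ---------------------------------------------------------------------------
# Poiseuille utilities


def tube_resistance(mu: float, L: float, r: float) -> float:
    """Viscous resistance of laminar flow in a tube: ``8*mu*L / (pi*r**4)``.

    Any mutually consistent unit system may be used.  All arguments must be
    strictly positive.
    """
    if not (mu > 0 and L > 0 and r > 0):
        raise ConfigError(f"tube_resistance: mu, L, r must be > 0, got {(mu, L, r)}")
    return 8.0 * mu * L / (math.pi * r**4)


def poiseuille_flow(Pa: float, Pv: float, R: float) -> float:
    """Volumetric flow under a pressure gradient: ``(Pa - Pv) / R``.

    The sign follows the pressure gradient; ``R`` must be strictly positive.
    """
    if not R > 0:
        raise ConfigError(f"poiseuille_flow: R must be > 0, got {R}")
    return (Pa - Pv) / R


@dataclass(frozen=True)
class HaemodynamicParams:
    """Pressures, viscosity and vessel geometry with derived resistance/flow."""

    arterial_pressure: float
    venous_pressure: float
    viscosity: float
    vessel_length: float
    vessel_radius: float

    @property
    def resistance(self) -> float:
        return tube_resistance(self.viscosity, self.vessel_length, self.vessel_radius)

    @property
    def flow(self) -> float:
        return poiseuille_flow(self.arterial_pressure, self.venous_pressure, self.resistance)


# ---------------------------------------------------------------------------
# Beat morphology


@dataclass(frozen=True)
class BeatShape:
    """Parametric single-beat morphology.

    The beat rises from 0 to a unit peak over ``rise_fraction`` of the beat
    period (raised-cosine upstroke), decays to ``end_datum_offset`` by
    ``decay_end_fraction``, then holds that terminal plateau until the next
    beat.  A stiffer vessel is modelled with a larger terminal offset (the
    pulse decays less completely before the next upstroke).
    """

    rise_fraction: float = 0.3
    decay_end_fraction: float = 0.7
    end_datum_offset: float = 0.0

    def validate(self) -> None:
        if not 0.0 < self.rise_fraction < 1.0:
            raise ConfigError(f"rise_fraction must be in (0, 1), got {self.rise_fraction}")
        if not self.rise_fraction < self.decay_end_fraction <= 1.0:
            raise ConfigError(
                "decay_end_fraction must be in (rise_fraction, 1], got "
                f"{self.decay_end_fraction}"
            )
        if not 0.0 <= self.end_datum_offset < 1.0:
            raise ConfigError(
                f"end_datum_offset must be in [0, 1), got {self.end_datum_offset}"
            )


def make_beat_template(shape: BeatShape, n_samples: int) -> np.ndarray:
    """One beat of unit peak amplitude sampled at ``n_samples`` points.

    The first sample is exactly 0, the peak sample exactly 1 and the last
    sample exactly ``end_datum_offset``; the curve is continuous with a
    single global maximum.
    """
    shape.validate()
    if n_samples < 8:
        raise ConfigError(f"n_samples must be >= 8, got {n_samples}")
    n = int(n_samples)
    ip = int(round(shape.rise_fraction * (n - 1)))
    ip = min(max(ip, 1), n - 2)
    idec = int(round(shape.decay_end_fraction * (n - 1)))
    idec = min(max(idec, ip + 1), n - 1)
    off = shape.end_datum_offset

    out = np.empty(n)
    i = np.arange(ip + 1)
    out[: ip + 1] = 0.5 - 0.5 * np.cos(np.pi * i / ip)
    j = np.arange(idec - ip + 1)
    out[ip : idec + 1] = off + (1.0 - off) * (0.5 + 0.5 * np.cos(np.pi * j / (idec - ip)))
    out[idec:] = off
    out[ip] = 1.0
    return out


# ---------------------------------------------------------------------------
# Generator configuration

_CLASS_INDEX = {c: k for k, c in enumerate(PHANTOM_CLASSES)}
_BMF_INDEX = {b: k for k, b in enumerate(BMFS)}
_WL_INDEX = {w: k for k, w in enumerate(PPG_WAVELENGTHS_NM)}


def _default_ppg_amplitude() -> dict:
    # a.u.; LPFS scatters less than intralipid -> larger amplitudes; the
    # intralipid emulsion suppresses the IR channel.  Class means fall with
    # stiffness with gaps far above the window-level noise.
    return {
        BMF_INTRALIPID: {
            530: {"healthy": 1.00, "intermediate": 0.80, "unhealthy": 0.60},
            655: {"healthy": 0.90, "intermediate": 0.72, "unhealthy": 0.54},
            940: {"healthy": 0.50, "intermediate": 0.40, "unhealthy": 0.30},
        },
        BMF_LPFS: {
            530: {"healthy": 1.40, "intermediate": 1.12, "unhealthy": 0.84},
            655: {"healthy": 1.30, "intermediate": 1.04, "unhealthy": 0.78},
            940: {"healthy": 1.20, "intermediate": 0.96, "unhealthy": 0.72},
        },
    }


def _default_ppg_noise_sd() -> dict:
    # a.u.; bench-grade PPG is clean; intralipid degrades IR (x4 multiplier).
    return {
        BMF_INTRALIPID: {530: 0.005, 655: 0.005, 940: 0.02},
        BMF_LPFS: {530: 0.005, 655: 0.005, 940: 0.005},
    }


def _default_ldf_flux_mean() -> dict:
    # Perfusion units.  Intralipid yields higher flux and a wider
    # healthy-to-unhealthy spread than LPFS.
    return {
        BMF_INTRALIPID: {"healthy": 800.0, "intermediate": 550.0, "unhealthy": 300.0},
        BMF_LPFS: {"healthy": 500.0, "intermediate": 380.0, "unhealthy": 260.0},
    }


def _default_ldf_noise_sd() -> dict:
    return {BMF_INTRALIPID: 12.0, BMF_LPFS: 6.0}


def _default_beat_shapes() -> dict:
    # Terminal offset grows with stiffness: the stiff vessel's pulse decays
    # less completely before the next upstroke ("sharper" signal).
    return {
        "healthy": BeatShape(0.3, 0.7, 0.02),
        "intermediate": BeatShape(0.3, 0.7, 0.10),
        "unhealthy": BeatShape(0.3, 0.7, 0.22),
    }


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    Defaults reproduce the bench protocol: 4-minute recordings, 60 bpm pump
    rate, PPG at 2000 Hz (530/655/940 nm), LDF flux at 40 Hz with a 1.0 s
    smoothing time constant.  Class amplitude/flux means are strictly
    monotone in stiffness with gaps of at least five window-level noise
    standard deviations.
    """

    seed: int = 0
    heart_rate_bpm: float = 60.0
    ppg_rate_hz: float = 2000.0
    ldf_rate_hz: float = 40.0
    duration_s: float = 240.0
    ppg_amplitude: dict = field(default_factory=_default_ppg_amplitude)
    ppg_noise_sd: dict = field(default_factory=_default_ppg_noise_sd)
    ldf_flux_mean: dict = field(default_factory=_default_ldf_flux_mean)
    ldf_noise_sd: dict = field(default_factory=_default_ldf_noise_sd)
    ldf_pulsatile_amplitude: float = 15.0
    ldf_smoothing_tau_s: float = 1.0
    baseline_wander_amplitude: float = 0.05
    baseline_wander_hz: float = 0.21
    beat_jitter_fraction: float = 0.0
    beat_shapes: dict = field(default_factory=_default_beat_shapes)
    filter_compensation: bool = True
    overlap_mode: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("heart_rate_bpm", "ppg_rate_hz", "ldf_rate_hz", "duration_s"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 <= self.beat_jitter_fraction < 0.5:
            raise ConfigError(
                f"beat_jitter_fraction must be in [0, 0.5), got {self.beat_jitter_fraction}"
            )
        for cls, shape in self.beat_shapes.items():
            if cls not in PHANTOM_CLASSES:
                raise ConfigError(f"beat_shapes: unknown class {cls!r}")
            shape.validate()
        h, i, u = PHANTOM_CLASSES
        for bmf in BMFS:
            for wl in PPG_WAVELENGTHS_NM:
                amp = self.ppg_amplitude[bmf][wl]
                if not amp[h] > amp[i] > amp[u]:
                    raise ConfigError(
                        f"ppg_amplitude[{bmf}][{wl}]: class means must strictly "
                        f"decrease healthy > intermediate > unhealthy, got {amp}"
                    )
            flux = self.ldf_flux_mean[bmf]
            if not flux[h] > flux[i] > flux[u]:
                raise ConfigError(
                    f"ldf_flux_mean[{bmf}]: class means must strictly decrease, got {flux}"
                )
        for cls in PHANTOM_CLASSES:
            if not self.ldf_flux_mean[BMF_INTRALIPID][cls] > self.ldf_flux_mean[BMF_LPFS][cls]:
                raise ConfigError(
                    f"ldf_flux_mean: intralipid must exceed LPFS for class {cls!r}"
                )
            for wl in PPG_WAVELENGTHS_NM:
                if not (
                    self.ppg_amplitude[BMF_LPFS][wl][cls]
                    > self.ppg_amplitude[BMF_INTRALIPID][wl][cls]
                ):
                    raise ConfigError(
                        f"ppg_amplitude: LPFS must exceed intralipid at ({cls}, {wl})"
                    )
        il = self.ppg_noise_sd[BMF_INTRALIPID]
        if il[940] < max(il[530], il[655]) or (
            min(il.values()) > 0 and not (il[940] > il[530] and il[940] > il[655])
        ):
            raise ConfigError("ppg_noise_sd: intralipid IR noise must exceed red/green")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["beat_shapes"] = {c: asdict(s) for c, s in self.beat_shapes.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        if "beat_shapes" in d:
            d["beat_shapes"] = {
                c: BeatShape(**s) if not isinstance(s, BeatShape) else s
                for c, s in d["beat_shapes"].items()
            }
        for key in ("ppg_amplitude", "ppg_noise_sd"):
            if key in d:
                d[key] = {
                    bmf: {int(wl): v for wl, v in by_wl.items()}
                    for bmf, by_wl in d[key].items()
                }
        return cls(**d)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), int(stream)])


def _ppg_stream(bmf: str, phantom_class: str, wavelength_nm: int) -> int:
    return (_BMF_INDEX[bmf] * 3 + _CLASS_INDEX[phantom_class]) * 4 + _WL_INDEX[wavelength_nm]


def _ldf_stream(bmf: str, phantom_class: str) -> int:
    return (_BMF_INDEX[bmf] * 3 + _CLASS_INDEX[phantom_class]) * 4 + 3


@lru_cache(maxsize=64)
def _bandlimited_peak_gain(shape: BeatShape, fs: float, heart_rate_bpm: float) -> float:
    """Peak-to-foot gain of one beat through the standard band-pass.

    Measured on the middle beat of a noiseless 24-beat train, read with the
    same local-quadratic fiducial estimator the feature extractor uses, so
    configured amplitudes are stated post-filter as the extractor measures
    them (see GeneratorConfig docs).
    """
    from scipy.signal import sosfiltfilt

    from .ppg_features import FIDUCIAL_REFINE_HALF_WIDTH_S, refined_value
    from .preprocess import FilterSpec, _design_bandpass

    spb = int(round(fs * 60.0 / heart_rate_bpm))
    template = make_beat_template(shape, spb)
    train = np.tile(template, 24)
    sos = _design_bandpass(FilterSpec(), fs)
    filt = sosfiltfilt(sos, train)
    start = 11 * spb
    mid = filt[start : start + spb]
    half = int(round(FIDUCIAL_REFINE_HALF_WIDTH_S * fs))
    peak = refined_value(filt, start + int(np.argmax(mid)), half)
    foot = refined_value(filt, start + int(np.argmin(mid)), half)
    return float(peak - foot)


def synthesize_ppg(
    config: GeneratorConfig, phantom_class: str, bmf: str, wavelength_nm: int
) -> SignalRecord:
    """Generate one PPG recording for a (class, BMF, wavelength) condition.

    Concatenated beats at the pump rate scaled by the configured class
    amplitude, plus sinusoidal baseline wander and white noise; fully
    reproducible from the configuration seed.  With
    ``config.filter_compensation`` (the default) the configured amplitude
    refers to the pulse amplitude after the standard 0.5--6 Hz band-pass;
    with it off, to the raw peak-minus-foot of the emitted beat.
    """
    fs = config.ppg_rate_hz
    n_total = int(round(fs * config.duration_s))
    spb = int(round(fs * 60.0 / config.heart_rate_bpm))
    shape = config.beat_shapes[phantom_class]
    amp = config.ppg_amplitude[bmf][wavelength_nm][phantom_class]
    rng = config._rng(_ppg_stream(bmf, phantom_class, wavelength_nm))

    if config.beat_jitter_fraction == 0:
        template = make_beat_template(shape, spb)
        n_beats = int(math.ceil(n_total / spb))
        x = np.tile(template, n_beats)[:n_total]
    else:
        pieces = []
        total = 0
        while total < n_total:
            frac = 1.0 + config.beat_jitter_fraction * (2.0 * rng.random() - 1.0)
            m = max(8, int(round(spb * frac)))
            pieces.append(make_beat_template(shape, m))
            total += m
        x = np.concatenate(pieces)[:n_total]

    scale = amp
    if config.filter_compensation:
        scale = amp / _bandlimited_peak_gain(shape, fs, config.heart_rate_bpm)
    x = x * scale

    if config.baseline_wander_amplitude > 0:
        t = np.arange(n_total) / fs
        x = x + config.baseline_wander_amplitude * np.sin(
            2.0 * np.pi * config.baseline_wander_hz * t
        )
    sd = config.ppg_noise_sd[bmf][wavelength_nm]
    if sd > 0:
        x = x + rng.normal(0.0, sd, n_total)

    return SignalRecord(
        record_id=f"ppg-{bmf}-{phantom_class}-{wavelength_nm}nm",
        samples=x,
        sampling_rate=fs,
        modality=MODALITY_PPG,
        wavelength_nm=wavelength_nm,
        bmf=bmf,
        phantom_class=phantom_class,
        young_modulus_mpa=CLASS_YOUNG_MODULUS_MPA[phantom_class],
        duration_s=config.duration_s,
    )


def synthesize_ldf(config: GeneratorConfig, phantom_class: str, bmf: str) -> SignalRecord:
    """Generate one LDF flux recording for a (class, BMF) condition.

    Class/BMF DC level plus a small pulsatile component at the pump rate and
    white noise, exponentially smoothed with the device's 1.0 s flux time
    constant (disable with ``ldf_smoothing_tau_s = 0``).
    """
    fs = config.ldf_rate_hz
    n_total = int(round(fs * config.duration_s))
    dc = config.ldf_flux_mean[bmf][phantom_class]
    rng = config._rng(_ldf_stream(bmf, phantom_class))

    t = np.arange(n_total) / fs
    f_beat = config.heart_rate_bpm / 60.0
    x = dc + config.ldf_pulsatile_amplitude * np.sin(2.0 * np.pi * f_beat * t)
    sd = config.ldf_noise_sd[bmf]
    if sd > 0:
        x = x + rng.normal(0.0, sd, n_total)
    if config.ldf_smoothing_tau_s > 0:
        from scipy.signal import lfilter

        alpha = 1.0 - math.exp(-1.0 / (fs * config.ldf_smoothing_tau_s))
        x, _ = lfilter([alpha], [1.0, alpha - 1.0], x, zi=[(1.0 - alpha) * x[0]])

    return SignalRecord(
        record_id=f"ldf-{bmf}-{phantom_class}",
        samples=x,
        sampling_rate=fs,
        modality=MODALITY_LDF,
        bmf=bmf,
        phantom_class=phantom_class,
        young_modulus_mpa=CLASS_YOUNG_MODULUS_MPA[phantom_class],
        duration_s=config.duration_s,
    )


def generate_records(config: GeneratorConfig) -> list[SignalRecord]:
    """The full factorial: 2 BMFs x 3 classes x (3 PPG wavelengths + 1 LDF) = 24 recordings."""
    records: list[SignalRecord] = []
    for bmf in BMFS:
        for cls in PHANTOM_CLASSES:
            for wl in PPG_WAVELENGTHS_NM:
                records.append(synthesize_ppg(config, cls, bmf, wl))
            records.append(synthesize_ldf(config, cls, bmf))
    return records


def generate_dataset(config: GeneratorConfig, out_dir: str | Path) -> DatasetManifest:
    """Write the full factorial dataset plus ``manifest.csv`` to ``out_dir``.

    Output is fully determined by the configuration (seeded); two runs with
    the same config produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for record in generate_records(config):
        rel = f"{record.record_id}.csv"
        write_signal(record, out / rel)
        meta = record.metadata()
        rows.append(
            {
                "record_id": record.record_id,
                "path": rel,
                "modality": meta["modality"],
                "wavelength_nm": meta["wavelength_nm"],
                "bmf": meta["bmf"],
                "phantom_class": meta["phantom_class"],
                "young_modulus_mpa": meta["young_modulus_mpa"],
                "sampling_rate": meta["sampling_rate"],
                "duration_s": meta["duration_s"],
            }
        )
    manifest = DatasetManifest(
        entries=pd.DataFrame(rows), config_hash=config.config_hash, seed=config.seed
    )
    manifest.write(out / "manifest.csv")
    return manifest
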
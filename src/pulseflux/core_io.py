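"""Domain types and file I/O for phantom signal recordings.

A recording is one 4-minute acquisition from a vessel--tissue phantom:
either a photoplethysmography (PPG) trace at one of three wavelengths or a
laser Doppler flowmetry (LDF) flux trace.  Recordings are stored as plain
two-column CSV (``time_s,value``) with a JSON sidecar carrying all
metadata, so that every fixture is inspectable with standard tools.

Phantom classes map one-to-one onto the tensile stiffness (Young's
modulus) of the embedded vessel: 0.82 MPa (healthy), 1.48 MPa
(intermediate) and 2.06 MPa (unhealthy/atherosclerotic).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MODALITY_PPG",
    "MODALITY_LDF",
    "BMF_INTRALIPID",
    "BMF_LPFS",
    "PHANTOM_CLASSES",
    "CLASS_YOUNG_MODULUS_MPA",
    "PPG_WAVELENGTHS_NM",
    "FormatError",
    "ConfigError",
    "SignalRecord",
    "Window",
    "DatasetManifest",
    "write_signal",
    "read_signal",
    "windows_of",
]

MODALITY_PPG = "ppg"
MODALITY_LDF = "ldf"

BMF_INTRALIPID = "intralipid"
BMF_LPFS = "lpfs"
BMFS = (BMF_INTRALIPID, BMF_LPFS)

#: Stiffness classes ordered from most to least elastic.
PHANTOM_CLASSES = ("healthy", "intermediate", "unhealthy")

#: Fixed vessel-wall Young's modulus (MPa) for each phantom class.
CLASS_YOUNG_MODULUS_MPA = {
    "healthy": 0.82,
    "intermediate": 1.48,
    "unhealthy": 2.06,
}

#: PPG channel wavelengths: green, red, infra-red (nm).
PPG_WAVELENGTHS_NM = (530, 655, 940)


class FormatError(ValueError):
    """Raised when a signal file, sidecar or record violates the format contract."""


class ConfigError(ValueError):
    """Raised when a configuration value is out of its documented domain."""


@dataclass
class SignalRecord:
    """One recording: samples plus acquisition and phantom metadata.

    ``samples`` are arbitrary units (light intensity for PPG, perfusion
    units for LDF).  Invariants are enforced at construction; violations
    raise :class:`FormatError` naming the offending field.
    """

    record_id: str
    samples: np.ndarray
    sampling_rate: float
    modality: str
    bmf: str
    phantom_class: str
    duration_s: float
    young_modulus_mpa: float | None = None
    wavelength_nm: int | None = None
    filtered: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise FormatError("samples: expected a 1-D array")
        if not self.sampling_rate > 0:
            raise FormatError(f"sampling_rate: must be > 0, got {self.sampling_rate}")
        if not self.duration_s > 0:
            raise FormatError(f"duration_s: must be > 0, got {self.duration_s}")
        expected = round(self.sampling_rate * self.duration_s)
        if len(self.samples) != expected:
            raise FormatError(
                f"samples: length {len(self.samples)} != round(sampling_rate * "
                f"duration_s) = {expected}"
            )
        if self.modality not in (MODALITY_PPG, MODALITY_LDF):
            raise FormatError(f"modality: unknown value {self.modality!r}")
        if self.modality == MODALITY_PPG:
            if self.wavelength_nm is None:
                raise FormatError("wavelength_nm: required for PPG records")
            if int(self.wavelength_nm) not in PPG_WAVELENGTHS_NM:
                raise FormatError(
                    f"wavelength_nm: {self.wavelength_nm} not one of {PPG_WAVELENGTHS_NM}"
                )
            self.wavelength_nm = int(self.wavelength_nm)
        else:
            if self.wavelength_nm is not None:
                raise FormatError("wavelength_nm: must be absent for LDF records")
        if self.bmf not in BMFS:
            raise FormatError(f"bmf: unknown value {self.bmf!r}")
        if self.phantom_class not in PHANTOM_CLASSES:
            raise FormatError(f"phantom_class: unknown value {self.phantom_class!r}")
        fixed = CLASS_YOUNG_MODULUS_MPA[self.phantom_class]
        if self.young_modulus_mpa is None:
            self.young_modulus_mpa = fixed
        elif not math.isclose(self.young_modulus_mpa, fixed, abs_tol=1e-9):
            raise FormatError(
                f"young_modulus_mpa: {self.young_modulus_mpa} does not match the fixed "
                f"value {fixed} for class {self.phantom_class!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def with_samples(self, samples: np.ndarray, *, filtered: bool | None = None) -> "SignalRecord":
        """Copy of this record with new samples (metadata unchanged)."""
        return replace(
            self,
            samples=np.asarray(samples, dtype=float),
            filtered=self.filtered if filtered is None else filtered,
        )

    def metadata(self) -> dict:
        return {
            "record_id": self.record_id,
            "sampling_rate": self.sampling_rate,
            "modality": self.modality,
            "wavelength_nm": self.wavelength_nm,
            "bmf": self.bmf,
            "phantom_class": self.phantom_class,
            "young_modulus_mpa": self.young_modulus_mpa,
            "duration_s": self.duration_s,
            "filtered": self.filtered,
        }


@dataclass(frozen=True)
class Window:
    """One analysis window: contiguous, non-overlapping, fixed length (default 10 s)."""

    index: int
    start_s: float
    length_s: float = 10.0

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ConfigError(f"window index must be >= 0, got {self.index}")
        if not self.length_s > 0:
            raise ConfigError(f"window length_s must be > 0, got {self.length_s}")
        if not math.isclose(self.start_s, self.index * self.length_s, abs_tol=1e-9):
            raise ConfigError("window start_s must equal index * length_s")

    @property
    def end_s(self) -> float:
        return self.start_s + self.length_s

    @property
    def midpoint_s(self) -> float:
        return self.start_s + 0.5 * self.length_s


def windows_of(record: SignalRecord, length_s: float = 10.0) -> list[Window]:
    """Partition a recording into contiguous windows; a truncated tail is dropped.

    Returns ``floor(duration_s / length_s)`` windows (an empty list when the
    window is longer than the recording).
    """
    if not length_s > 0:
        raise ConfigError(f"length_s must be > 0, got {length_s}")
    n = int(math.floor(record.duration_s / length_s + 1e-9))
    return [Window(i, i * length_s, length_s) for i in range(n)]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".meta.json") if path.suffix else path.with_name(path.name + ".meta.json")


def write_signal(record: SignalRecord, path: str | Path) -> None:
    """Write a record as ``time_s,value`` CSV plus a ``.meta.json`` sidecar.

    Values are written with 12 significant digits so the pair round-trips
    through :func:`read_signal` to better than 1e-9.
    """
    path = Path(path)
    frame = pd.DataFrame({"time_s": record.times, "value": record.samples})
    frame.to_csv(path, index=False, float_format="%.12g")
    sidecar = _sidecar_path(path)
    with open(sidecar, "w") as fh:
        json.dump(record.metadata(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_signal(path: str | Path) -> SignalRecord:
    """Read a CSV/sidecar pair back into a validated :class:`SignalRecord`.

    The time column is checked for uniform spacing consistent with the
    sidecar's sampling rate (tolerance 1e-6 s).
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"sidecar: missing metadata file {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError("samples: no samples") from exc
    if frame.empty:
        raise FormatError("samples: no samples")
    for col in ("time_s", "value"):
        if col not in frame.columns:
            raise FormatError(f"{col}: column missing from {path.name}")
    times = frame["time_s"].to_numpy(dtype=float)
    rate = float(meta["sampling_rate"])
    if rate <= 0:
        raise FormatError(f"sampling_rate: must be > 0, got {rate}")
    expected = np.arange(len(times)) / rate
    if len(times) > 1 and np.max(np.abs(times - expected)) > 1e-6:
        raise FormatError(
            "time_s: non-uniform time grid inconsistent with sampling_rate "
            f"{rate} Hz (tolerance 1e-6 s)"
        )
    return SignalRecord(
        record_id=meta["record_id"],
        samples=frame["value"].to_numpy(dtype=float),
        sampling_rate=rate,
        modality=meta["modality"],
        wavelength_nm=meta.get("wavelength_nm"),
        bmf=meta["bmf"],
        phantom_class=meta["phantom_class"],
        young_modulus_mpa=meta.get("young_modulus_mpa"),
        duration_s=float(meta["duration_s"]),
        filtered=bool(meta.get("filtered", False)),
    )


_MANIFEST_COLUMNS = [
    "record_id",
    "path",
    "modality",
    "wavelength_nm",
    "bmf",
    "phantom_class",
    "young_modulus_mpa",
    "sampling_rate",
    "duration_s",
    "config_hash",
    "seed",
]


@dataclass
class DatasetManifest:
    """Index of a generated dataset: one row per recording plus provenance.

    ``entries`` is a DataFrame with one row per recording; ``config_hash``
    and ``seed`` identify the generator configuration that produced it.
    """

    entries: pd.DataFrame
    config_hash: str
    seed: int

    def __post_init__(self) -> None:
        ids = self.entries["record_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise FormatError(f"record_id: duplicate ids {dupes}")

    def validate_files(self, base_dir: str | Path) -> None:
        base = Path(base_dir)
        for rel in self.entries["path"]:
            if not (base / rel).exists():
                raise FormatError(f"path: referenced file {rel} does not exist")

    def write(self, path: str | Path) -> None:
        frame = self.entries.copy()
        frame["config_hash"] = self.config_hash
        frame["seed"] = self.seed
        frame[_MANIFEST_COLUMNS].to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def read(cls, path: str | Path) -> "DatasetManifest":
        frame = pd.read_csv(path)
        missing = set(_MANIFEST_COLUMNS) - set(frame.columns)
        if missing:
            raise FormatError(f"manifest: missing columns {sorted(missing)}")
        config_hash = str(frame["config_hash"].iloc[0])
        seed = int(frame["seed"].iloc[0])
        entries = frame.drop(columns=["config_hash", "seed"])
        return cls(entries=entries, config_hash=config_hash, seed=seed)

    def load_records(self, base_dir: str | Path) -> list[SignalRecord]:
        base = Path(base_dir)
        return [read_signal(base / rel) for rel in self.entries["path"]]
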
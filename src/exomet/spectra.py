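"""Peak-list reading, filtering, calibration and blank subtraction.

A peak list is one ionization-mode spectrum: (m/z, intensity, S/N)
triples sorted by m/z, tagged with the culture sample it came from.
Ions are assumed singly charged; positive mode is interpreted as
[M+H]+ and negative mode as [M-H]-, so conversion between detected m/z
and neutral mass is a proton-mass shift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .chem import DEFAULT_ELEMENTS, ElementTable, MolecularFormula

__all__ = [
    "CalibrationError",
    "CalibrationModel",
    "GROWTH_PHASES",
    "ManifestEntry",
    "MERGE_TOL_DA",
    "Peak",
    "PeakList",
    "PeakListFormatError",
    "SampleKey",
    "build_peaklist",
    "calibrate",
    "filter_peaks",
    "ionize",
    "neutral_mass",
    "read_manifest",
    "read_peaklist",
    "subtract_blank",
    "subtract_blank_masses",
]

log = logging.getLogger(__name__)

#: Peaks closer than this (Da) are merged at read time; well below
#: instrument resolution, so duplicate rows cannot double-count.
MERGE_TOL_DA = 1e-6

GROWTH_PHASES = ("start", "lag", "exponential", "stationary")

MODES = ("positive", "negative")


class PeakListFormatError(ValueError):
    """Malformed peak-list file (missing column, non-numeric cell...)."""


class CalibrationError(ValueError):
    """Internal recalibration could not be performed or is implausible."""


class Peak(NamedTuple):
    mz: float
    intensity: float
    snr: float


@dataclass(frozen=True)
class SampleKey:
    """Identifies one culture sample: strain × substrate × time point × replicate."""

    strain: str
    substrate: str
    time_point_h: float
    phase: str = "exponential"
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.phase not in GROWTH_PHASES:
            raise ValueError(f"unknown growth phase {self.phase!r}; expected one of {GROWTH_PHASES}")
        if self.time_point_h < 0:
            raise ValueError("time_point_h must be >= 0")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")


@dataclass
class PeakList:
    """Ordered peaks of one spectrum plus sample metadata."""

    peaks: list[Peak]
    mode: str
    sample: SampleKey | None = None
    is_blank: bool = False
    calibrated: bool = False

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        mz = [p.mz for p in self.peaks]
        if any(b - a <= 0 for a, b in zip(mz, mz[1:])):
            raise ValueError("peaks must be strictly increasing in m/z")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)


def build_peaklist(
    raw: Iterable[tuple[float, float, float]],
    mode: str,
    sample: SampleKey | None = None,
    is_blank: bool = False,
) -> PeakList:
    """Sort raw (mz, intensity, snr) rows and merge near-duplicates.

    Rows within :data:`MERGE_TOL_DA` of each other collapse into one peak
    with summed intensity, the maximum S/N and the intensity-weighted
    mean m/z.
    """
    rows = sorted((float(m), float(i), float(s)) for m, i, s in raw)
    for mz, inten, snr in rows:
        if mz <= 0:
            raise PeakListFormatError(f"non-positive m/z {mz}")
        if inten <= 0:
            raise PeakListFormatError(f"non-positive intensity {inten} at m/z {mz}")
        if snr < 0:
            raise PeakListFormatError(f"negative S/N {snr} at m/z {mz}")
    merged: list[Peak] = []
    group: list[tuple[float, float, float]] = []

    def _flush() -> None:
        if not group:
            return
        total = sum(i for _, i, _ in group)
        mz = sum(m * i for m, i, _ in group) / total
        merged.append(Peak(mz, total, max(s for _, _, s in group)))

    for row in rows:
        if group and row[0] - group[0][0] >= MERGE_TOL_DA:
            _flush()
            group = []
        group.append(row)
    _flush()
    n_dropped = len(rows) - len(merged)
    if n_dropped:
        log.info("merged %d duplicate peak rows (tolerance %g Da)", n_dropped, MERGE_TOL_DA)
    return PeakList(merged, mode=mode, sample=sample, is_blank=is_blank)


def read_peaklist(
    path,
    mode: str,
    sample: SampleKey | None = None,
    is_blank: bool = False,
) -> PeakList:
    """Read a delimited peak list with header columns mz, intensity, snr.

    The delimiter (tab or comma) is auto-detected and header matching is
    case-insensitive.  A missing column or non-numeric cell raises
    :class:`PeakListFormatError` naming the column / line.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    lookup = {str(c).strip().lower(): c for c in df.columns}
    cols = {}
    for name in ("mz", "intensity", "snr"):
        if name not in lookup:
            raise PeakListFormatError(f"missing column {name!r} in {path}")
        cols[name] = lookup[name]
    numeric = {}
    for name, col in cols.items():
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise PeakListFormatError(
                f"non-numeric value {df[col][bad.idxmax()]!r} in column {name!r} "
                f"at line {line} of {path}"
            )
        numeric[name] = vals.to_numpy(dtype=float)
    pl = build_peaklist(
        zip(numeric["mz"], numeric["intensity"], numeric["snr"]),
        mode=mode,
        sample=sample,
        is_blank=is_blank,
    )
    log.info("read %d rows -> %d peaks from %s", len(df), len(pl), path)
    return pl


def filter_peaks(
    pl: PeakList,
    min_snr: float = 5.0,
    mass_min: float = 92.0,
    mass_max: float = 2000.0,
) -> PeakList:
    """Retain peaks with S/N ≥ *min_snr* inside [mass_min, mass_max] (inclusive)."""
    if not mass_min < mass_max:
        raise ValueError("mass_min must be < mass_max")
    kept = [p for p in pl.peaks if p.snr >= min_snr and mass_min <= p.mz <= mass_max]
    return replace(pl, peaks=kept)


def neutral_mass(mz: float, mode: str, table: ElementTable = DEFAULT_ELEMENTS) -> float:
    """Neutral mass of a singly charged ion: [M+H]+ or [M-H]-."""
    proton = table.proton_mass
    if mode == "positive":
        if mz <= proton:
            raise ValueError(f"positive-mode m/z {mz} must exceed the proton mass")
        return mz - proton
    if mode == "negative":
        return mz + proton
    raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


def ionize(mass: float, mode: str, table: ElementTable = DEFAULT_ELEMENTS) -> float:
    """Detected m/z of a neutral mass under [M+H]+ / [M-H]- (inverse of neutral_mass)."""
    proton = table.proton_mass
    if mode == "positive":
        return mass + proton
    if mode == "negative":
        out = mass - proton
        if out <= 0:
            raise ValueError(f"neutral mass {mass} too small to deprotonate")
        return out
    raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


@dataclass(frozen=True)
class CalibrationModel:
    """Linear internal recalibration mz_corrected = slope * mz + intercept."""

    slope: float
    intercept: float
    n_matched: int = 0
    median_abs_residual_ppm: float = float("nan")

    def __post_init__(self) -> None:
        if abs(self.slope - 1.0) > 1e-3:
            raise CalibrationError(
                f"implausible calibration slope {self.slope!r} (must be within 1 ± 1e-3)"
            )

    def apply(self, mz: float) -> float:
        return self.slope * mz + self.intercept


def calibrate(
    pl: PeakList,
    reference_masses: Sequence[float],
    match_tol_ppm: float = 2.0,
) -> tuple[PeakList, CalibrationModel]:
    """Fit and apply a linear internal calibration from reference m/z values.

    Each reference mass is matched to the closest peak within
    *match_tol_ppm*; a least-squares line through the (observed,
    reference) pairs is applied to every peak.  Fewer than two matches
    raise :class:`CalibrationError` and the caller should pass the
    spectrum through flagged as uncalibrated.
    """
    mz = pl.mz_array
    obs, ref = [], []
    for r in sorted(reference_masses):
        if mz.size == 0:
            break
        i = int(np.argmin(np.abs(mz - r)))
        if abs(mz[i] - r) / r * 1e6 <= match_tol_ppm:
            obs.append(mz[i])
            ref.append(r)
    if len(obs) < 2:
        raise CalibrationError(
            f"only {len(obs)} reference masses matched within {match_tol_ppm} ppm; need >= 2"
        )
    slope, intercept = np.polyfit(obs, ref, 1)
    residual_ppm = (slope * np.array(obs) + intercept - np.array(ref)) / np.array(ref) * 1e6
    model = CalibrationModel(
        slope=float(slope),
        intercept=float(intercept),
        n_matched=len(obs),
        median_abs_residual_ppm=float(np.median(np.abs(residual_ppm))),
    )
    corrected = [Peak(model.apply(p.mz), p.intensity, p.snr) for p in pl.peaks]
    log.info(
        "calibrated %s: %d refs, slope %.9f, intercept %.3e Da, median |resid| %.4f ppm",
        pl.sample, model.n_matched, model.slope, model.intercept,
        model.median_abs_residual_ppm,
    )
    out = replace(pl, peaks=corrected, calibrated=True)
    return out, model


def subtract_blank(
    sample_formulas: set[MolecularFormula],
    blank_formulas: set[MolecularFormula],
) -> set[MolecularFormula]:
    """Formula-level sterile-control subtraction: sample minus blank.

    Operates on the assigned formula sets of the culture sample and its
    matched sterile control (same mode, same time point); deterministic
    and tolerance-free.
    """
    return set(sample_formulas) - set(blank_formulas)


def subtract_blank_masses(pl: PeakList, blank: PeakList, tol_ppm: float = 0.5) -> PeakList:
    """Mass-level blank subtraction: drop peaks within *tol_ppm* of a blank peak."""
    if not blank.peaks:
        return replace(pl, peaks=list(pl.peaks))
    bmz = blank.mz_array
    kept = []
    for p in pl.peaks:
        i = int(np.searchsorted(bmz, p.mz))
        near = [bmz[j] for j in (i - 1, i) if 0 <= j < bmz.size]
        if not any(abs(p.mz - b) / p.mz * 1e6 <= tol_ppm for b in near):
            kept.append(p)
    return replace(pl, peaks=kept)


class ManifestEntry(NamedTuple):
    sample: SampleKey
    mode: str
    is_blank: bool
    path: str


def read_manifest(path) -> list[ManifestEntry]:
    """Read a sample manifest TSV.

    Required columns: strain, substrate, time_point_h, phase, replicate,
    mode, is_blank, path.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ("strain", "substrate", "time_point_h", "phase", "replicate",
                "mode", "is_blank", "path")
    for col in required:
        if col not in df.columns:
            raise PeakListFormatError(f"manifest {path} is missing column {col!r}")
    entries = []
    for _, row in df.iterrows():
        key = SampleKey(
            strain=str(row["strain"]),
            substrate=str(row["substrate"]),
            time_point_h=float(row["time_point_h"]),
            phase=str(row["phase"]),
            replicate=int(row["replicate"]),
        )
        entries.append(ManifestEntry(key, str(row["mode"]), bool(int(row["is_blank"])), str(row["path"])))
    return entries
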
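"""Molecular-formula assignment by constrained exhaustive enumeration.

Every CHNOSP composition inside configurable element ranges whose
monoisotopic mass lies within a ppm tolerance of the observed neutral
mass is generated, then filtered by standard elemental-ratio heuristics
for dissolved organic matter (H/C and O/C windows, a DBE window and the
even-electron rule requiring integer DBE for neutral molecules).

The enumeration loops over N, S, P and O explicitly; for each
heteroatom combination the carbon count is bounded analytically by the
remaining mass and the hydrogen count is solved by rounding, so the
pruning is exact: it returns precisely the candidate set a naive scan
over all six element ranges would.  Candidates are ordered by |ppm
error|, then by heteroatom count (N+S+P), then by Hill string, which
makes selection deterministic; near-ties are surfaced as ambiguous
rather than hidden.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Iterable, Mapping, Sequence

from .chem import DEFAULT_ELEMENTS, ElementTable, MolecularFormula
from .spectra import Peak, PeakList, SampleKey, neutral_mass

__all__ = [
    "AMBIGUITY_PPM",
    "AssignedSpectrum",
    "Assignment",
    "AssignmentConfig",
    "DEFAULT_CONFIG",
    "FormulaCandidate",
    "assign_spectrum",
    "enumerate_candidates",
    "select_best",
    "union_formulas",
]

log = logging.getLogger(__name__)

#: Two candidates whose |ppm errors| differ by less than this are
#: considered indistinguishable and the assignment is flagged ambiguous.
AMBIGUITY_PPM = 0.1

_DEFAULT_RANGES: Mapping[str, tuple[int, int]] = MappingProxyType(
    {"C": (1, 100), "H": (1, 200), "N": (0, 6), "O": (0, 40), "S": (0, 3), "P": (0, 2)}
)


@dataclass(frozen=True)
class AssignmentConfig:
    """Tolerance, element ranges and plausibility filters for assignment.

    Defaults (0.5 ppm, C1-100 H1-200 N0-6 O0-40 S0-3 P0-2,
    0.3 <= H/C <= 2.5, O/C <= 1.2, 0 <= DBE <= 25, integer DBE) are
    standard for 15 T FT-ICR dissolved-organic-matter work and cover all
    packaged metabolite-table formulas with headroom.
    """

    tolerance_ppm: float = 0.5
    element_ranges: Mapping[str, tuple[int, int]] = field(default_factory=lambda: _DEFAULT_RANGES)
    hc_range: tuple[float, float] = (0.3, 2.5)
    oc_max: float = 1.2
    dbe_range: tuple[float, float] = (0.0, 25.0)
    require_integer_dbe: bool = True

    def __post_init__(self) -> None:
        if not self.tolerance_ppm > 0:
            raise ValueError("tolerance_ppm must be > 0")
        ranges = dict(self.element_ranges)
        unknown = set(ranges) - {"C", "H", "N", "O", "S", "P"}
        if unknown:
            raise ValueError(f"element_ranges restricted to CHNOSP, got {sorted(unknown)}")
        for sym in ("C", "H", "N", "O", "S", "P"):
            lo, hi = ranges.setdefault(sym, (0, 0))
            if lo < 0 or hi < lo:
                raise ValueError(f"empty or negative range for {sym}: {(lo, hi)}")
        if ranges["C"][0] < 1:
            raise ValueError("minimum carbon count must be >= 1")
        object.__setattr__(self, "element_ranges", MappingProxyType(ranges))
        if not self.hc_range[0] <= self.hc_range[1]:
            raise ValueError("empty hc_range")
        if not self.dbe_range[0] <= self.dbe_range[1]:
            raise ValueError("empty dbe_range")

    @classmethod
    def from_file(cls, path) -> "AssignmentConfig":
        """Read a flat key=value config (ranges as e.g. ``N=0:6``)."""
        kwargs: dict = {}
        ranges = dict(_DEFAULT_RANGES)
        with open(path, encoding="utf-8") as fh:
            for raw in fh:
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key in ("C", "H", "N", "O", "S", "P"):
                    lo, _, hi = value.partition(":")
                    ranges[key] = (int(lo), int(hi))
                elif key == "tolerance_ppm":
                    kwargs["tolerance_ppm"] = float(value)
                elif key == "hc_range":
                    lo, _, hi = value.partition(":")
                    kwargs["hc_range"] = (float(lo), float(hi))
                elif key == "oc_max":
                    kwargs["oc_max"] = float(value)
                elif key == "dbe_range":
                    lo, _, hi = value.partition(":")
                    kwargs["dbe_range"] = (float(lo), float(hi))
                elif key == "require_integer_dbe":
                    kwargs["require_integer_dbe"] = value.lower() in ("1", "true", "yes")
                else:
                    raise ValueError(f"unknown config key {key!r} in {path}")
        return cls(element_ranges=ranges, **kwargs)


DEFAULT_CONFIG = AssignmentConfig()


@dataclass(frozen=True)
class FormulaCandidate:
    formula: MolecularFormula
    error_ppm: float
    dbe: float
    heteroatom_count: int

    def sort_key(self) -> tuple:
        return (abs(self.error_ppm), self.heteroatom_count, self.formula.hill())


def _passes_filters(c: int, h: int, n: int, o: int, s: int, p: int, cfg: AssignmentConfig) -> bool:
    hc = h / c
    if not cfg.hc_range[0] <= hc <= cfg.hc_range[1]:
        return False
    if o / c > cfg.oc_max:
        return False
    d = 1.0 + c - h / 2.0 + (n + p) / 2.0
    if not cfg.dbe_range[0] <= d <= cfg.dbe_range[1]:
        return False
    if cfg.require_integer_dbe and (h + n + p) % 2 != 0:
        return False
    return True


def enumerate_candidates(
    target_mass: float,
    cfg: AssignmentConfig = DEFAULT_CONFIG,
    table: ElementTable = DEFAULT_ELEMENTS,
) -> list[FormulaCandidate]:
    """All constrained CHNOSP formulas within tolerance of a neutral mass.

    Returns candidates sorted by |ppm error|, then heteroatom count
    (N+S+P), then Hill string.  The pruned search is exhaustive: for
    each N/S/P/O combination the carbon range is cut only where no
    hydrogen count could reach the tolerance window, and both rounding
    neighbours of the ideal hydrogen count are tested (the tolerance
    window is far narrower than one hydrogen mass in this mass range).
    """
    if not target_mass > 0:
        raise ValueError("target mass must be positive")
    mC, mH = table.masses["C"], table.masses["H"]
    mN, mO = table.masses["N"], table.masses["O"]
    mS, mP = table.masses["S"], table.masses["P"]
    tol_da = target_mass * cfg.tolerance_ppm * 1e-6
    r = cfg.element_ranges
    (cmin, cmax), (hmin, hmax) = r["C"], r["H"]
    out: list[FormulaCandidate] = []
    budget = target_mass + tol_da
    for n in range(r["N"][0], r["N"][1] + 1):
        mass_n = n * mN
        if mass_n + cmin * mC + hmin * mH > budget:
            break
        for s in range(r["S"][0], r["S"][1] + 1):
            mass_ns = mass_n + s * mS
            if mass_ns + cmin * mC + hmin * mH > budget:
                break
            for p in range(r["P"][0], r["P"][1] + 1):
                mass_nsp = mass_ns + p * mP
                if mass_nsp + cmin * mC + hmin * mH > budget:
                    break
                for o in range(r["O"][0], r["O"][1] + 1):
                    base = mass_nsp + o * mO
                    if base + cmin * mC + hmin * mH > budget:
                        break
                    c_hi = min(cmax, int((budget - base - hmin * mH) / mC))
                    for c in range(cmin, c_hi + 1):
                        rem = target_mass - base - c * mC
                        h_lo = math.floor((rem - tol_da) / mH)
                        h_hi = math.ceil((rem + tol_da) / mH)
                        for h in range(h_lo, h_hi + 1):
                            if h < hmin or h > hmax:
                                continue
                            err_da = c * mC + h * mH + base - target_mass
                            if abs(err_da) > tol_da:
                                continue
                            if not _passes_filters(c, h, n, o, s, p, cfg):
                                continue
                            f = MolecularFormula(
                                {"C": c, "H": h, "N": n, "O": o, "S": s, "P": p}, table
                            )
                            out.append(
                                FormulaCandidate(
                                    formula=f,
                                    error_ppm=err_da / target_mass * 1e6,
                                    dbe=1.0 + c - h / 2.0 + (n + p) / 2.0,
                                    heteroatom_count=n + s + p,
                                )
                            )
    out.sort(key=FormulaCandidate.sort_key)
    return out


def select_best(
    candidates: Sequence[FormulaCandidate],
) -> tuple[FormulaCandidate | None, bool]:
    """Pick the first candidate of an ordered list; flag near-ties.

    Returns ``(candidate, ambiguous)`` where *ambiguous* is true when a
    second candidate sits within :data:`AMBIGUITY_PPM` of the winner's
    |ppm error|.  An empty list yields ``(None, False)``.
    """
    if not candidates:
        return None, False
    best = candidates[0]
    ambiguous = len(candidates) > 1 and (
        abs(abs(candidates[1].error_ppm) - abs(best.error_ppm)) <= AMBIGUITY_PPM
    )
    return best, ambiguous


@dataclass(frozen=True)
class Assignment:
    peak: Peak
    neutral_mass: float
    candidate: FormulaCandidate | None
    ambiguous: bool = False

    @property
    def assigned(self) -> bool:
        return self.candidate is not None


@dataclass
class AssignedSpectrum:
    """Per-peak assignments of one filtered, calibrated peak list."""

    sample: SampleKey | None
    mode: str
    assignments: list[Assignment]
    is_blank: bool = False

    @property
    def formula_set(self) -> set[MolecularFormula]:
        return {a.candidate.formula for a in self.assignments if a.candidate is not None}

    def summary(self) -> dict:
        errors = sorted(abs(a.candidate.error_ppm) for a in self.assignments if a.candidate)
        median = errors[len(errors) // 2] if errors else float("nan")
        return {
            "n_peaks": len(self.assignments),
            "n_assigned": sum(a.assigned for a in self.assignments),
            "n_unassigned": sum(not a.assigned for a in self.assignments),
            "n_ambiguous": sum(a.ambiguous for a in self.assignments),
            "median_abs_error_ppm": median,
        }


def assign_spectrum(
    pl: PeakList,
    cfg: AssignmentConfig = DEFAULT_CONFIG,
    table: ElementTable = DEFAULT_ELEMENTS,
) -> AssignedSpectrum:
    """Assign one formula (or none) to every peak of a peak list.

    The peak list is expected to be S/N- and mass-window-filtered and
    calibrated already.  Each peak's m/z is converted to a neutral mass
    under the list's ionization mode before enumeration.
    """
    assignments = []
    for peak in pl.peaks:
        m = neutral_mass(peak.mz, pl.mode, table)
        cand, ambiguous = select_best(enumerate_candidates(m, cfg, table))
        assignments.append(Assignment(peak, m, cand, ambiguous))
    spec = AssignedSpectrum(pl.sample, pl.mode, assignments, is_blank=pl.is_blank)
    log.info("assigned spectrum %s: %s", pl.sample, spec.summary())
    return spec


def union_formulas(
    spectra: Iterable[AssignedSpectrum],
    by: str = "strain",
    exclude: Iterable[SampleKey] = (),
) -> dict[tuple, set[MolecularFormula]]:
    """Union formula sets per group, skipping lysis-excluded samples.

    *by* is ``"strain"`` or ``"strain_substrate"``.  Input spectra are
    expected to be blank-subtracted; pass their formula sets through
    :func:`exomet.spectra.subtract_blank` first.
    """
    if by not in ("strain", "strain_substrate"):
        raise ValueError("by must be 'strain' or 'strain_substrate'")
    excluded = set(exclude)
    groups: dict[tuple, set[MolecularFormula]] = {}
    for spec in spectra:
        if spec.sample is None:
            raise ValueError("cannot group spectra without sample metadata")
        if spec.sample in excluded:
            log.info("excluding sample %s from union (lysis flag)", spec.sample)
            continue
        key = (spec.sample.strain,) if by == "strain" else (spec.sample.strain, spec.sample.substrate)
        groups.setdefault(key, set()).update(spec.formula_set)
    for key, formulas in groups.items():
        log.info("group %s: %d distinct formulas", key, len(formulas))
    return groups
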
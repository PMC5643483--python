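"""Growth-curve metrics, growth-stimulation statistics and carbon budgets.

The batch growth rate is estimated as the slope of the best log-linear
window: among all contiguous windows of at least four positive
measurements, the one maximizing the R² of a straight-line fit to
ln(value) over time wins.  R² values within 1e-9 are treated as tied,
and ties are resolved toward the steeper window (so a perfectly flat
stationary plateau cannot shadow the exponential phase), then the
longer, then the earlier one.  This is the standard exponential-phase
estimator for batch cultures and is fully deterministic given the tie
rules.

The carbon mass balance converts cell numbers to biomass carbon with a
per-cell carbon quota (50 fg C per cell is typical of large, fast-
growing heterotrophic bacteria) and compares it with the carbon bound
in dissolved combined amino acids (DCAA); a DCAA share above a few
percent of biomass carbon indicates that cell lysis, not secretion,
dominates the amino-acid pool, and such samples are excluded from
exometabolome unions.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AAProfile",
    "CarbonBudget",
    "GrowthCurve",
    "GrowthFitError",
    "RateFit",
    "StimulationResult",
    "aa_carbon",
    "aa_carbon_bulk",
    "cells_to_carbon",
    "growth_rate",
    "load_aa_carbon_table",
    "load_growth_table",
    "lysis_check",
    "molpercent",
    "stimulation",
]

log = logging.getLogger(__name__)

#: Average (not monoisotopic) atomic weight of carbon, used for bulk
#: concentration → mass-of-carbon conversions.
C_ATOMIC_WEIGHT = 12.011

VALUE_KINDS = ("od", "cells", "fluorescence")

#: Windows whose R² differ by less than this are treated as tied.
_R2_TIE = 1e-9
#: Relative slope difference below which tied windows compare by length.
_SLOPE_TIE = 1e-9


class GrowthFitError(ValueError):
    """No usable window for rate fitting, or degenerate statistics input."""


@dataclass
class GrowthCurve:
    """One replicate's time series of OD / cell counts / fluorescence."""

    times: np.ndarray
    values: np.ndarray
    value_kind: str = "od"
    replicate: int = 1
    condition: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("values must be non-negative")
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"value_kind must be one of {VALUE_KINDS}")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class RateFit:
    rate: float            # h^-1
    window: tuple[int, int]  # inclusive index range of the winning window
    r_squared: float
    n_points: int


def _window_stats(t: np.ndarray, y: np.ndarray):
    """Prefix sums giving O(1) slope and R² per contiguous window."""
    S1 = np.concatenate(([0.0], np.cumsum(np.ones_like(t))))
    St = np.concatenate(([0.0], np.cumsum(t)))
    Stt = np.concatenate(([0.0], np.cumsum(t * t)))
    Sy = np.concatenate(([0.0], np.cumsum(y)))
    Syy = np.concatenate(([0.0], np.cumsum(y * y)))
    Sty = np.concatenate(([0.0], np.cumsum(t * y)))

    def stats_for(i: int, j: int) -> tuple[float, float]:
        n = S1[j + 1] - S1[i]
        st = St[j + 1] - St[i]
        stt = Stt[j + 1] - Stt[i]
        sy = Sy[j + 1] - Sy[i]
        syy = Syy[j + 1] - Syy[i]
        sty = Sty[j + 1] - Sty[i]
        sxx = stt - st * st / n
        sxy = sty - st * sy / n
        syy_c = max(syy - sy * sy / n, 0.0)
        slope = sxy / sxx
        ss_res = max(syy_c - slope * sxy, 0.0)
        if syy_c > 1e-30:
            r2 = 1.0 - ss_res / syy_c
        else:
            # Exactly flat ln-values: slope 0 fits perfectly.
            r2 = 1.0
        return slope, r2

    return stats_for


def growth_rate(curve: GrowthCurve, min_points: int = 4) -> RateFit:
    """Exponential growth rate (h^-1) from the best log-linear window.

    Raises :class:`GrowthFitError` when no contiguous stretch of at
    least *min_points* positive values exists.
    """
    if min_points < 2:
        raise ValueError("min_points must be >= 2")
    values = curve.values
    positive = values > 0
    best: tuple[float, int, int] | None = None  # (r2, length, -start) semantics via compare
    best_fit: RateFit | None = None
    i = 0
    n = len(values)
    while i < n:
        if not positive[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and positive[j + 1]:
            j += 1
        # run [i, j]
        if j - i + 1 >= min_points:
            t = curve.times[i : j + 1]
            y = np.log(values[i : j + 1])
            stats_for = _window_stats(t, y)
            run_len = j - i + 1
            for a in range(run_len - min_points + 1):
                for b in range(a + min_points - 1, run_len):
                    slope, r2 = stats_for(a, b)
                    length = b - a + 1
                    start = i + a
                    if best is None:
                        take = True
                    else:
                        br2, bslope, blen, bstart = best
                        slope_tol = _SLOPE_TIE * max(abs(slope), abs(bslope)) + 1e-12
                        if r2 > br2 + _R2_TIE:
                            take = True
                        elif r2 >= br2 - _R2_TIE:
                            if abs(slope) > abs(bslope) + slope_tol:
                                take = True
                            elif abs(slope) >= abs(bslope) - slope_tol:
                                take = length > blen or (length == blen and start < bstart)
                            else:
                                take = False
                        else:
                            take = False
                    if take:
                        best = (r2, slope, length, start)
                        best_fit = RateFit(
                            rate=float(slope),
                            window=(start, i + b),
                            r_squared=float(r2),
                            n_points=length,
                        )
        i = j + 1
    if best_fit is None:
        raise GrowthFitError(
            f"no contiguous stretch of >= {min_points} positive values to fit"
        )
    return best_fit


class StimulationResult(NamedTuple):
    percent_enhancement: float
    p_value: float
    n_treated: int
    n_control: int
    significance_level: float = 0.01


def stimulation(
    treated: Sequence[float],
    control: Sequence[float],
    significance_level: float = 0.01,
) -> StimulationResult:
    """Percent enhancement of treated over control rates/yields plus t-test.

    Two-sample two-sided Student's t-test with pooled (equal) variance.
    The significance threshold is reported, never enforced.  Arms with
    zero variance are handled analytically: identical means give p = 1,
    different means p = 0.
    """
    t_arr = np.asarray(treated, dtype=float)
    c_arr = np.asarray(control, dtype=float)
    if t_arr.size < 2 or c_arr.size < 2:
        raise GrowthFitError("need >= 2 replicates in each arm for the t-test")
    mean_t, mean_c = float(t_arr.mean()), float(c_arr.mean())
    if mean_c == 0:
        raise GrowthFitError("control mean is zero; enhancement undefined")
    enhancement = 100.0 * (mean_t - mean_c) / mean_c
    if np.ptp(t_arr) == 0 and np.ptp(c_arr) == 0:
        p = 1.0 if mean_t == mean_c else 0.0
    else:
        p = float(stats.ttest_ind(t_arr, c_arr, equal_var=True).pvalue)
    return StimulationResult(enhancement, p, t_arr.size, c_arr.size, significance_level)


def cells_to_carbon(cells_per_ml: float, fg_c_per_cell: float) -> float:
    """Biomass carbon in mg C L^-1 from cell density and per-cell quota.

    fg mL^-1 → mg L^-1 is a factor 1e-9 (1e-12 mg/fg × 1e3 mL/L).
    """
    if cells_per_ml < 0 or fg_c_per_cell < 0:
        raise ValueError("cell density and carbon quota must be >= 0")
    return cells_per_ml * fg_c_per_cell * 1e-9


def load_aa_carbon_table(path=None) -> dict[str, int]:
    """Carbon atoms per protein amino acid (packaged resource by default)."""
    source = resources.files("exomet").joinpath("data/aa_carbon.tsv") if path is None else path
    if hasattr(source, "read_text"):
        text = source.read_text(encoding="utf-8")
    else:
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    return {
        row["amino_acid"]: int(row["carbon_atoms"])
        for row in csv.DictReader(text.splitlines(), delimiter="\t")
    }


@dataclass
class AAProfile:
    """Per-amino-acid concentrations (μM) with carbon counts."""

    concentrations: Mapping[str, float]
    carbon_atoms: Mapping[str, int] = field(default_factory=load_aa_carbon_table)

    def __post_init__(self) -> None:
        for aa, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for {aa}")
            if aa not in self.carbon_atoms:
                raise GrowthFitError(f"no carbon count configured for amino acid {aa!r}")


def aa_carbon(profile: AAProfile) -> float:
    """Carbon bound in the amino-acid pool, mg C L^-1.

    conc (μM = 1e-6 mol L^-1) × C atoms × 12.011 g mol^-1 × 1e3 mg g^-1.
    """
    return sum(
        conc * profile.carbon_atoms[aa] * C_ATOMIC_WEIGHT * 1e-3
        for aa, conc in profile.concentrations.items()
    )


def aa_carbon_bulk(total_um: float, mean_carbon_per_residue: float) -> float:
    """Bulk-concentration variant of :func:`aa_carbon`.

    Used when only a total hydrolyzable amino-acid concentration is
    available; *mean_carbon_per_residue* is a documented assumption and
    should be reported alongside the result.
    """
    if total_um < 0 or mean_carbon_per_residue <= 0:
        raise ValueError("concentration must be >= 0 and mean carbon per residue > 0")
    return total_um * mean_carbon_per_residue * C_ATOMIC_WEIGHT * 1e-3


@dataclass(frozen=True)
class CarbonBudget:
    """Biomass carbon vs DCAA carbon for one sample, with the lysis flag."""

    cells_per_ml: float
    fg_c_per_cell: float
    biomass_c: float       # mg C L^-1
    dcaa_c: float          # mg C L^-1
    dcaa_fraction: float
    lysis_flag: bool
    threshold: float


def lysis_check(
    cells_per_ml: float,
    fg_c_per_cell: float,
    dcaa_c_mg_l: float,
    threshold: float = 0.05,
) -> CarbonBudget:
    """Flag a sample as lysis-affected when DCAA carbon exceeds
    *threshold* × biomass carbon (default 5%)."""
    biomass_c = cells_to_carbon(cells_per_ml, fg_c_per_cell)
    if biomass_c <= 0:
        raise ValueError("biomass carbon must be positive for a mass balance")
    if dcaa_c_mg_l < 0:
        raise ValueError("DCAA carbon must be >= 0")
    fraction = dcaa_c_mg_l / biomass_c
    return CarbonBudget(
        cells_per_ml=cells_per_ml,
        fg_c_per_cell=fg_c_per_cell,
        biomass_c=biomass_c,
        dcaa_c=dcaa_c_mg_l,
        dcaa_fraction=fraction,
        lysis_flag=fraction > threshold,
        threshold=threshold,
    )


def molpercent(concentrations: Mapping[str, float]) -> dict[str, float]:
    """Mole-percent composition of a concentration map (sums to 100)."""
    total = float(sum(concentrations.values()))
    if total <= 0:
        raise ValueError("molpercent undefined for an all-zero composition")
    if any(v < 0 for v in concentrations.values()):
        raise ValueError("concentrations must be >= 0")
    return {k: 100.0 * v / total for k, v in concentrations.items()}


def load_growth_table(path) -> dict[tuple[str, int], GrowthCurve]:
    """Read growth TSV (condition, replicate, time_h, value, value_kind)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    out: dict[tuple[str, int], GrowthCurve] = {}
    for (cond, rep), grp in df.groupby(["condition", "replicate"]):
        grp = grp.sort_values("time_h")
        kinds = grp["value_kind"].unique()
        if len(kinds) != 1:
            raise ValueError(f"mixed value kinds for {cond!r} replicate {rep}")
        out[(str(cond), int(rep))] = GrowthCurve(
            times=grp["time_h"].to_numpy(dtype=float),
            values=grp["value"].to_numpy(dtype=float),
            value_kind=str(kinds[0]),
            replicate=int(rep),
            condition=str(cond),
        )
    return out
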
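"""Seeded generators for every input the pipeline consumes.

Each generator returns, besides the simulated data, a ground-truth
manifest sufficient to recompute every expected downstream output, so
each pipeline stage can be tested end-to-end without any external data:

* ``simulate_spectrum`` — peak lists emulating ultrahigh-resolution
  FT-ICR-MS output: peaks at the ionized masses of database metabolites
  plus random plausible CHNOS(P) decoy compositions, Gaussian relative
  (ppm) mass error, lognormal intensities, uniform S/N with a
  configurable low-S/N fraction, and a sterile-control (blank) list
  sharing a configurable number of contaminant formulas with the
  sample.
* ``simulate_batch_growth`` — Monod batch kinetics (μ = μmax·S/(Ks+S))
  with substrate depletion, integrated with a classical 4th-order
  Runge–Kutta scheme, plus multiplicative lognormal observation noise.
* ``simulate_diatom_experiment`` — replicate fluorescence growth curves
  with a multiplicative rate-stimulation effect between arms and iid
  lognormal replicate noise on the true rate.

All randomness flows from a single integer seed per call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .assign import DEFAULT_CONFIG, AssignmentConfig, _passes_filters
from .chem import DEFAULT_ELEMENTS, MolecularFormula, monoisotopic_mass
from .growth import GrowthCurve
from .metabolites import DetectionMatrix, MetaboliteRecord
from .spectra import PeakList, SampleKey, build_peaklist, ionize

__all__ = [
    "DiatomExperiment",
    "GroundTruthManifest",
    "PeakTruth",
    "SimulationError",
    "SpectrumSimConfig",
    "SubstrateSeries",
    "simulate_batch_growth",
    "simulate_detection_matrix",
    "simulate_diatom_experiment",
    "simulate_spectrum",
]

log = logging.getLogger(__name__)

_MAX_REJECTION_TRIES = 10_000


class SimulationError(RuntimeError):
    """Impossible generator configuration (e.g. decoy rejection exhausted)."""


@dataclass(frozen=True)
class SpectrumSimConfig:
    """Conditions for one simulated sample/blank spectrum pair."""

    n_true: int = 50
    n_decoys: int = 50
    ppm_sigma: float = 0.1
    intensity_lognormal: tuple[float, float] = (5.0, 1.0)
    snr_range: tuple[float, float] = (5.0, 100.0)
    low_snr_fraction: float = 0.0
    blank_contaminants: int = 0
    mode: str = "negative"
    calibration_shift_ppm: float = 0.0
    mass_min: float = 92.0
    mass_max: float = 800.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ppm_sigma < 0:
            raise ValueError("ppm_sigma must be >= 0")
        if min(self.n_true, self.n_decoys, self.blank_contaminants) < 0:
            raise ValueError("counts must be >= 0")
        if not 0 <= self.low_snr_fraction <= 1:
            raise ValueError("low_snr_fraction must be in [0, 1]")


class PeakTruth(NamedTuple):
    mz: float
    formula: str          # Hill notation
    neutral_mass: float
    ppm_error: float
    snr: float
    kind: str             # "true" | "decoy" | "contaminant"


@dataclass
class GroundTruthManifest:
    """Everything needed to recompute expected outputs of every stage."""

    peaks: list[PeakTruth] = field(default_factory=list)
    growth: dict = field(default_factory=dict)
    detection_probabilities: dict = field(default_factory=dict)

    def formula_set(self, kinds: Sequence[str] = ("true", "decoy"), min_snr: float = 0.0) -> set[str]:
        return {p.formula for p in self.peaks if p.kind in kinds and p.snr >= min_snr}


def _random_plausible_formula(
    rng: np.random.Generator,
    mass_min: float,
    mass_max: float,
    cfg: AssignmentConfig = DEFAULT_CONFIG,
    forbidden: set[MolecularFormula] = frozenset(),
    with_p: bool = False,
) -> MolecularFormula:
    """Rejection-sample a CHNOS(P) formula passing the plausibility filters.

    Decoys must clear the same filters as real candidates — otherwise
    they would be trivially rejected downstream and recovery tests would
    be uninformative.
    """
    c_cap = max(int(mass_max / 12.0), 5)
    for _ in range(_MAX_REJECTION_TRIES):
        c = int(rng.integers(3, min(c_cap, 40) + 1))
        h = int(rng.integers(max(1, int(0.3 * c)), int(2.5 * c) + 2))
        n = int(rng.integers(0, 7))
        s = int(rng.integers(0, 3))
        p = int(rng.integers(0, 3)) if with_p else 0
        o = int(rng.integers(0, min(40, int(1.2 * c)) + 1))
        if not _passes_filters(c, h, n, o, s, p, cfg):
            continue
        f = MolecularFormula({"C": c, "H": h, "N": n, "O": o, "S": s, "P": p})
        if f in forbidden:
            continue
        if mass_min <= monoisotopic_mass(f) <= mass_max:
            return f
    raise SimulationError(
        f"could not draw a plausible formula in [{mass_min}, {mass_max}] Da "
        f"after {_MAX_REJECTION_TRIES} tries"
    )


def _make_peak(rng: np.random.Generator, formula: MolecularFormula, cfg: SpectrumSimConfig, kind: str) -> PeakTruth:
    mass = monoisotopic_mass(formula)
    ppm_err = float(rng.normal(0.0, cfg.ppm_sigma)) if cfg.ppm_sigma > 0 else 0.0
    mz = ionize(mass, cfg.mode) * (1.0 + (ppm_err + cfg.calibration_shift_ppm) * 1e-6)
    if rng.uniform() < cfg.low_snr_fraction:
        snr = float(rng.uniform(0.5, 5.0))
    else:
        snr = float(rng.uniform(*cfg.snr_range))
    return PeakTruth(mz, formula.hill(), mass, ppm_err, snr, kind)


def simulate_spectrum(
    cfg: SpectrumSimConfig,
    db: Sequence[MetaboliteRecord],
    sample: SampleKey | None = None,
) -> tuple[PeakList, PeakList, GroundTruthManifest]:
    """Simulate one sample peak list, its sterile-control blank, and truth.

    True peaks are drawn without replacement from the database formulas
    inside the mass window; the blank shares exactly
    ``cfg.blank_contaminants`` formulas with the sample and nothing
    else.  Byte-identical outputs for identical seeds.
    """
    rng = np.random.default_rng(cfg.seed)
    pool = []
    seen: set[MolecularFormula] = set()
    for rec in db:
        m = monoisotopic_mass(rec.formula)
        if cfg.mass_min <= m <= cfg.mass_max and rec.formula not in seen:
            pool.append(rec.formula)
            seen.add(rec.formula)
    if cfg.n_true > len(pool):
        raise SimulationError(
            f"requested {cfg.n_true} true formulas but only {len(pool)} database "
            f"formulas lie in [{cfg.mass_min}, {cfg.mass_max}] Da"
        )
    idx = rng.choice(len(pool), size=cfg.n_true, replace=False) if cfg.n_true else []
    chosen = [pool[i] for i in sorted(int(i) for i in idx)]
    used = set(chosen)
    decoys = []
    for _ in range(cfg.n_decoys):
        f = _random_plausible_formula(rng, cfg.mass_min, cfg.mass_max, forbidden=used)
        decoys.append(f)
        used.add(f)
    contaminants = []
    for _ in range(cfg.blank_contaminants):
        f = _random_plausible_formula(rng, cfg.mass_min, cfg.mass_max, forbidden=used)
        contaminants.append(f)
        used.add(f)

    truths = [_make_peak(rng, f, cfg, "true") for f in chosen]
    truths += [_make_peak(rng, f, cfg, "decoy") for f in decoys]
    contaminant_truths = [_make_peak(rng, f, cfg, "contaminant") for f in contaminants]

    manifest = GroundTruthManifest(peaks=truths + contaminant_truths)

    def _intensity() -> float:
        mu, sigma = cfg.intensity_lognormal
        return float(rng.lognormal(mu, sigma))

    sample_rows = [(p.mz, _intensity(), p.snr) for p in manifest.peaks]
    blank_rows = [(p.mz, _intensity(), p.snr) for p in contaminant_truths]
    sample_pl = build_peaklist(sample_rows, mode=cfg.mode, sample=sample, is_blank=False)
    blank_pl = build_peaklist(blank_rows, mode=cfg.mode, sample=sample, is_blank=True)
    log.info(
        "simulated spectrum: %d true + %d decoy + %d contaminant peaks (seed %d)",
        len(chosen), len(decoys), len(contaminants), cfg.seed,
    )
    return sample_pl, blank_pl, manifest


class SubstrateSeries(NamedTuple):
    times: np.ndarray
    values: np.ndarray  # mM


def simulate_batch_growth(
    mu_max: float,
    ks: float,
    yield_coeff: float,
    s0: float,
    x0: float,
    dt: float,
    t_end: float,
    seed: int | None = None,
    noise_cv: float = 0.0,
    value_kind: str = "od",
    condition: str = "batch",
    replicate: int = 1,
) -> tuple[GrowthCurve, SubstrateSeries, dict]:
    """Monod batch growth with substrate depletion, RK4-integrated.

    dX/dt = μmax·S/(Ks+S)·X and dS/dt = −(1/Y)·μmax·S/(Ks+S)·X; the
    linear combination X + Y·S is conserved exactly by the scheme.  The
    step must satisfy dt ≤ 0.01/μmax so the explicit integrator is well
    inside its stability region.  Observation noise is multiplicative
    lognormal with coefficient of variation *noise_cv* (mean-one).
    """
    for name, v in (("mu_max", mu_max), ("ks", ks), ("yield_coeff", yield_coeff),
                    ("s0", s0), ("x0", x0), ("dt", dt), ("t_end", t_end)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    if dt > 0.01 / mu_max + 1e-12:
        raise ValueError(f"dt={dt} too large; require dt <= 0.01/mu_max = {0.01 / mu_max:g}")

    def deriv(x: float, s: float) -> tuple[float, float]:
        mu = mu_max * max(s, 0.0) / (ks + max(s, 0.0))
        return mu * x, -mu * x / yield_coeff

    n_steps = int(round(t_end / dt))
    times = np.arange(n_steps + 1) * dt
    x = np.empty(n_steps + 1)
    s = np.empty(n_steps + 1)
    x[0], s[0] = x0, s0
    for k in range(n_steps):
        xk, sk = x[k], s[k]
        k1 = deriv(xk, sk)
        k2 = deriv(xk + dt / 2 * k1[0], sk + dt / 2 * k1[1])
        k3 = deriv(xk + dt / 2 * k2[0], sk + dt / 2 * k2[1])
        k4 = deriv(xk + dt * k3[0], sk + dt * k3[1])
        x_new = xk + dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        s_new = sk + dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        if s_new < 0.0:
            # project onto the conserved quantity X + Y*S: consume
            # exactly the remaining substrate instead of overshooting
            x_new = xk + yield_coeff * sk
            s_new = 0.0
        x[k + 1], s[k + 1] = x_new, s_new

    observed = x.copy()
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = float(np.sqrt(np.log1p(noise_cv**2)))
        observed = x * rng.lognormal(-0.5 * sigma**2, sigma, size=x.shape)
    curve = GrowthCurve(times, observed, value_kind=value_kind,
                        condition=condition, replicate=replicate)
    truth = {"mu_max": mu_max, "ks": ks, "yield_coeff": yield_coeff,
             "s0": s0, "x0": x0, "noise_cv": noise_cv,
             "x_noise_free": x}
    return curve, SubstrateSeries(times, s), truth


@dataclass
class DiatomExperiment:
    treated: list[GrowthCurve]
    control: list[GrowthCurve]
    manifest: dict


def simulate_diatom_experiment(
    mu_control: float = 0.03,
    stimulation_factor: float = 1.22,
    n_replicates: int = 3,
    noise_cv: float = 0.0,
    seed: int = 0,
    f0: float = 10.0,
    carrying_capacity: float = 1000.0,
    sample_interval_h: float = 6.0,
    t_end_h: float = 240.0,
) -> DiatomExperiment:
    """Replicate diatom fluorescence curves with a rate-stimulation effect.

    Each replicate grows exponentially from *f0* until the fluorescence
    ceiling, at its own true rate: the arm rate (control μ, or
    μ × stimulation_factor for the treated arm) perturbed by iid
    mean-one lognormal noise with CV *noise_cv*.  The manifest records
    every true replicate rate.
    """
    if stimulation_factor <= 0:
        raise ValueError("stimulation_factor must be > 0")
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates per arm")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_end_h + sample_interval_h / 2, sample_interval_h)
    sigma = float(np.sqrt(np.log1p(noise_cv**2))) if noise_cv > 0 else 0.0

    def _arm(mu_arm: float, label: str) -> tuple[list[GrowthCurve], list[float]]:
        curves, rates = [], []
        for rep in range(1, n_replicates + 1):
            mu_i = mu_arm * float(rng.lognormal(-0.5 * sigma**2, sigma)) if sigma else mu_arm
            values = np.minimum(f0 * np.exp(mu_i * times), carrying_capacity)
            curves.append(GrowthCurve(times, values, value_kind="fluorescence",
                                      condition=label, replicate=rep))
            rates.append(mu_i)
        return curves, rates

    treated, rates_t = _arm(mu_control * stimulation_factor, "treated")
    control, rates_c = _arm(mu_control, "control")
    manifest = {
        "mu_control": mu_control,
        "stimulation_factor": stimulation_factor,
        "noise_cv": noise_cv,
        "true_rates_treated": rates_t,
        "true_rates_control": rates_c,
    }
    return DiatomExperiment(treated, control, manifest)


def simulate_detection_matrix(
    records: Sequence[MetaboliteRecord],
    columns: Sequence[SampleKey],
    detection_probability: float | dict[str, float],
    seed: int = 0,
) -> tuple[DetectionMatrix, GroundTruthManifest]:
    """Bernoulli presence matrix with a known per-metabolite detection rate."""
    rng = np.random.default_rng(seed)
    if isinstance(detection_probability, dict):
        probs = {rec.name: detection_probability[rec.name] for rec in records}
    else:
        probs = {rec.name: float(detection_probability) for rec in records}
    values = np.array(
        [rng.uniform(size=len(columns)) < probs[rec.name] for rec in records],
        dtype=bool,
    ).reshape(len(records), len(columns))
    matrix = DetectionMatrix(list(records), list(columns), values)
    manifest = GroundTruthManifest(detection_probabilities=probs)
    return matrix, manifest
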
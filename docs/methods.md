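# Methods

This note documents the models, parameter choices and numerical
conventions behind `exomet`, and what the synthetic-data tests do and
do not demonstrate about real data.

## Mass scale and adducts

Monoisotopic atomic masses are pinned in `src/exomet/data/elements.tsv`
(C = 12 exactly, H = 1.007825032, N = 14.003074005, O = 15.994914620,
S = 31.972071174, P = 30.973761998, Na = 22.989769282 Da) so that every
mass in the package is reproducible to < 1 μDa; an independent check
against a general-purpose mass-spectrometry library is part of the test
suite.  The proton mass used for adduct arithmetic is atomic hydrogen
minus one electron (1.007276452 Da).

Ions are treated as singly charged [M+H]⁺ or [M−H]⁻ only.  In the
92–2,000 Da window of soft-electrospray DOM and exometabolome work,
multiply charged species are rare and sodium adducts are suppressed by
the acidified extraction, so protonation/deprotonation is the minimal
defensible ionization model; the element table carries Na for users who
extend the adduct list.

## Formula assignment

Candidates for a neutral mass are all CHNOSP compositions within a
relative tolerance (default **0.5 ppm**, the customary figure for a
15 T FT-ICR instrument after internal recalibration) inside element
ranges C 1–100, H 1–200, N 0–6, O 0–40, S 0–3, P 0–2.  The ranges cover
every formula of the packaged metabolite table (max N = 4, S = 2,
P = 1) with headroom, at negligible cost because the search is pruned.

Plausibility filters, all configurable, follow standard practice for
marine DOM: 0.3 ≤ H/C ≤ 2.5, O/C ≤ 1.2, 0 ≤ DBE ≤ 25, and integer DBE
(a neutral even-electron molecule must have even H + N + P — the
nitrogen rule restated for neutral formulas).

The enumeration loops over N, S, P, O; for each heteroatom combination
the carbon count is bounded by the remaining mass and the hydrogen
count is solved arithmetically, testing every integer H that could
reach the tolerance window.  This pruning is exact — a property test
compares it against a naive unpruned scan of all six ranges over random
masses — and runs in tens of milliseconds per mass.

Selection is deterministic: smallest |ppm error|, then fewest
heteroatoms (N+S+P), then lexicographic Hill string.  When the two best
candidates sit within 0.1 ppm of each other the assignment is flagged
ambiguous rather than silently resolved; at sub-ppm accuracy such
collisions are real CHNOSP fine-structure isobars, and hiding them
would overstate confidence.

Two formulas of the packaged table (`C7H5O4`, `C10H17N2O3`) are printed
in the source material as deprotonated-ion compositions (odd hydrogen
parity, half-integer DBE).  They are kept verbatim for string-level
matching, but as they are not neutral molecules the even-electron rule
excludes them from the assignable candidate space: fed back through the
assigner they return *unassigned*, never a wrong formula.  Recovery
statistics therefore quote them separately.

## Blank subtraction

Sterile-control subtraction operates on assigned formula *sets* (exact,
tolerance-free), the deterministic reading of subtracting one mass
spectrum from another.  A mass-level mode (±0.5 ppm peak matching) is
available for workflows that subtract before assignment.

## Matching, classification, detection frequency

Database matching is by canonical Hill-string identity — both sides of
the comparison are formulas.  Structural isomers are indistinguishable
at formula level, so every match is putative; records sharing a formula
are all reported and flagged formula-degenerate.  Function labels map
to groups (vitamin-related, quorum-sensing, amino-acid-related,
auxin-related, siderophore, defense/antibiotic, nucleoside, other)
through a controlled-vocabulary file; group percentages are quoted
relative to the strain's biosynthetic-pathway total.  Detection
frequency is detections divided by the number of non-excluded sample
columns, reported with its denominator.

## Growth rate and stimulation

The batch growth rate is the slope of the best log-linear window:
among all contiguous windows of ≥ 4 positive measurements, maximize the
R² of the straight-line fit to ln(value) vs time.  R² values within
1e-9 are tied; ties resolve toward the **steeper** window, then the
longer, then the earlier one.  The slope tie-break is deliberate: a
culture that has reached a perfectly flat stationary plateau produces
zero-variance windows that fit a horizontal line exactly, and
preferring length there would report a growth rate of zero for any
saturated curve.  Steepness-first reproduces the intuitive estimator —
flat curves still return 0 (all slopes are 0), exact exponentials
return the full-window slope — while making μmax recovery on saturating
curves robust.  Windows with zero variance in ln(value) are assigned
R² = 1 (slope 0 is a perfect fit); R² is otherwise 1 − SS_res/SS_tot
computed from prefix sums (O(1) per window, values clamped at 0).

Growth stimulation between arms is
100 × (mean_treated − mean_control)/mean_control with a two-sided,
equal-variance Student's t-test; the α = 0.01 threshold is reported,
never enforced.  Arms with zero variance are handled analytically
(identical means → p = 1, different means → p = 0) since the t statistic
degenerates.

## Carbon mass balance

Biomass carbon is cells mL⁻¹ × quota (default **50 fg C cell⁻¹**,
typical of large fast-growing heterotrophic bacteria) × 10⁻⁹ mg L⁻¹.
Amino-acid-bound carbon is Σ conc(μM) × C-atoms × 12.011 × 10⁻³
mg C L⁻¹ using the average atomic weight (bulk budgets, not exact
masses) and a packaged table of carbon counts per protein amino acid; a
bulk variant takes a documented mean-carbon-per-residue parameter when
only total concentrations exist.  A sample is flagged lysis-affected
when DCAA carbon exceeds **5%** of biomass carbon: observed lysis cases
sit near 17–21% and clean cultures below 1%, so 5% separates the
regimes with a wide margin on either side; flagged samples are excluded
from exometabolome unions.

## Synthetic data: what it emulates, and what it does not

`simulate_spectrum` emulates monoisotopic FT-ICR peak lists: true peaks
at ionized database-formula masses with Normal(0, σ ppm) relative mass
error (default σ = 0.1 ppm), decoy peaks at random CHNOS compositions
constrained to pass the same plausibility filters as real candidates
(otherwise decoys would be trivially rejected and recovery statistics
meaningless), lognormal intensities, uniform S/N with a configurable
low-S/N fraction to exercise the filter, an optional linear
miscalibration, and a blank sharing a fixed number of contaminant
formulas with the sample.  It does **not** simulate profile spectra,
isotopologue patterns, chemical noise, ion suppression or
extraction-efficiency bias — so passing recovery tests demonstrate the
correctness of the assignment/matching logic at realistic mass
accuracy, not instrument-level performance on real extracts.

`simulate_batch_growth` integrates Monod kinetics
(dX/dt = μmax·S/(Ks+S)·X, dS/dt = −(1/Y)·μmax·S/(Ks+S)·X) with
classical RK4 at dt ≤ 0.01/μmax.  The linear invariant X + Y·S is
conserved by construction; at the depletion step the state is projected
onto the invariant (remaining substrate consumed exactly) instead of
letting the integrator overshoot below zero.  Observation noise is
mean-one multiplicative lognormal.

`simulate_diatom_experiment` generates replicate fluorescence curves
that grow exponentially to a ceiling; the treated arm's true rate is
the control rate times the stimulation factor, and replicate noise is
applied to the *rate* (iid mean-one lognormal).  Noise on the rate, not
per-point, is what makes the power analysis meaningful: multiplicative
per-point noise shifts the intercept of a log-linear fit and cancels
out of the slope entirely.

Default scenario parameters — μ ≈ 0.03 h⁻¹ for diatom fluorescence,
3 replicates per arm, 2% replicate CV, stimulation factors 1.17/1.22
(rate) and 1.35 (yield) — mirror the culture experiments the pipeline
is built around.  Simulated batch-growth checks use μmax = 0.25 h⁻¹,
Ks = 0.05 mM, Y = 0.1 OD mM⁻¹, S₀ = 10 mM, X₀ = 0.01 OD, dt = 0.04 h,
t_end = 20 h, which deplete the substrate shortly before the end of the
series — sampling into early stationary phase the way batch cultures
are actually harvested, and long enough to expose the plateau
degeneracy the rate estimator must survive.

## Known limitations

* Formula-level identity cannot separate structural isomers; all
  annotations are putative and fragmentation confirmation is carried
  only as a provenance flag.
* Only [M+H]⁺/[M−H]⁻ singly charged ions are modeled; metabolites that
  ionize exclusively as adducts or multimers are invisible.
* The DOM screening sets packaged with the library are reconstructed
  from the per-metabolite presence flags of the annotated table, not
  from the full environmental spectra, so they support presence lookups
  of annotated metabolites only.
* FT-ICR intensities are relative; the pipeline deliberately offers no
  absolute quantification.
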
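"""Constrained formula enumeration, selection and spectrum assignment."""

import numpy as np
import pytest
from _oracles import naive_enumerate

from exomet.assign import (
    AssignmentConfig,
    FormulaCandidate,
    assign_spectrum,
    enumerate_candidates,
    select_best,
    union_formulas,
)
from exomet.chem import monoisotopic_mass, parse_formula
from exomet.metabolites import load_metabolite_db
from exomet.simulate import SpectrumSimConfig, simulate_spectrum
from exomet.spectra import PeakList, SampleKey, build_peaklist, filter_peaks


class TestEnumerate:
    def test_riboflavin_mass_yields_its_formula(self):
        cands = enumerate_candidates(376.138284)
        assert parse_formula("C17H20N4O6") in {c.formula for c in cands}

    def test_bare_carbon_mass_has_no_candidates(self):
        # C12 at 12 Da fails the H >= 1 / H/C >= 0.3 plausibility bounds
        assert enumerate_candidates(12.0) == []

    def test_candidates_within_tolerance(self):
        mass = 445.2
        for c in enumerate_candidates(mass):
            err = abs(monoisotopic_mass(c.formula) - mass) / mass * 1e6
            assert err <= 0.5 + 1e-9
            assert abs(c.error_ppm) <= 0.5 + 1e-9

    def test_sorted_by_abs_error_then_heteroatoms(self):
        cands = enumerate_candidates(445.2, AssignmentConfig(tolerance_ppm=5.0))
        keys = [c.sort_key() for c in cands]
        assert keys == sorted(keys)

    def test_matches_bruteforce_oracle_on_sample(self):
        """Pruned enumeration equals the naive unpruned scan (spot check;
        the full 200-mass sweep runs in the acceptance suite)."""
        cfg = AssignmentConfig()
        rng = np.random.default_rng(7)
        for mass in rng.uniform(92, 800, 25):
            mine = {c.formula for c in enumerate_candidates(mass, cfg)}
            assert mine == naive_enumerate(mass, cfg)

    def test_monotone_in_tolerance_and_ranges(self):
        mass = 376.138284
        narrow = {c.formula for c in enumerate_candidates(mass, AssignmentConfig(tolerance_ppm=0.5))}
        wide = {c.formula for c in enumerate_candidates(mass, AssignmentConfig(tolerance_ppm=2.0))}
        assert narrow <= wide
        bigger_n = AssignmentConfig(
            tolerance_ppm=0.5,
            element_ranges={"C": (1, 100), "H": (1, 200), "N": (0, 8),
                            "O": (0, 40), "S": (0, 3), "P": (0, 2)},
        )
        assert narrow <= {c.formula for c in enumerate_candidates(mass, bigger_n)}


class TestSelectBest:
    def _cand(self, formula, ppm, het):
        f = parse_formula(formula)
        return FormulaCandidate(f, ppm, 1.0, het)

    def test_smallest_abs_error_wins(self):
        cands = sorted(
            [self._cand("C10H14N2O4", 0.1, 2), self._cand("C12H18O4", 0.3, 0)],
            key=FormulaCandidate.sort_key,
        )
        best, ambiguous = select_best(cands)
        assert best.formula == parse_formula("C10H14N2O4")
        assert not ambiguous

    def test_empty_is_unassigned(self):
        assert select_best([]) == (None, False)

    def test_tie_prefers_fewer_heteroatoms_and_flags_ambiguous(self):
        cands = sorted(
            [self._cand("C10H14N2O4", 0.2, 2), self._cand("C12H18O4", -0.2, 0)],
            key=FormulaCandidate.sort_key,
        )
        best, ambiguous = select_best(cands)
        assert best.heteroatom_count == 0
        assert ambiguous


class TestAssignSpectrum:
    def test_empty_peaklist(self):
        spec = assign_spectrum(PeakList([], mode="negative"))
        assert spec.assignments == [] and spec.formula_set == set()

    def test_synthetic_recovery(self, db):
        """DB-drawn peaks at 0.1 ppm error are assigned their true formula."""
        cfg = SpectrumSimConfig(n_true=43, n_decoys=0, ppm_sigma=0.1,
                                mass_max=500.0, seed=11)
        sample, _, manifest = simulate_spectrum(cfg, db)
        spec = assign_spectrum(filter_peaks(sample))
        truth = {round(p.mz, 6): p.formula for p in manifest.peaks}
        correct = sum(
            a.candidate is not None and a.candidate.formula.hill() == truth[round(a.peak.mz, 6)]
            for a in spec.assignments
        )
        assert correct / len(spec.assignments) >= 0.95

    def test_unmatched_peak_stays_unassigned(self):
        # 128.0 Da neutral mass sits in a formula gap at 0.5 ppm
        pl = build_peaklist([(500.000777, 1.0, 50.0)], mode="negative")
        spec = assign_spectrum(pl, AssignmentConfig(tolerance_ppm=0.01))
        assert spec.formula_set == set() or not spec.assignments[0].ambiguous


def test_union_formulas_excludes_lysis_samples():
    a, b, c = (parse_formula(s) for s in ("C6H12O6", "C5H10O5", "C4H8O4"))
    keys = [
        SampleKey("dshibae", "glucose", 10.0, "exponential", 1),
        SampleKey("dshibae", "glucose", 30.0, "stationary", 1),
        SampleKey("pinhibens", "acetate", 10.0, "exponential", 1),
    ]
    specs = []
    for key, formulas in zip(keys, ({a, b}, {b, c}, {c})):
        pl = build_peaklist(
            [(monoisotopic_mass(f) - 1.007276452, 1.0, 50.0) for f in formulas],
            mode="negative", sample=key,
        )
        specs.append(assign_spectrum(pl))
    groups = union_formulas(specs, by="strain")
    assert groups[("dshibae",)] == {a, b, c}
    groups = union_formulas(specs, by="strain", exclude=[keys[1]])
    assert groups[("dshibae",)] == {a, b}
    assert groups[("pinhibens",)] == {c}
    assert union_formulas([], by="strain") == {}


def test_config_from_file(tmp_path):
    path = tmp_path / "assign.cfg"
    path.write_text(
        "tolerance_ppm = 1.0\nN = 0:4\n# comment\nrequire_integer_dbe = true\n",
        encoding="utf-8",
    )
    cfg = AssignmentConfig.from_file(path)
    assert cfg.tolerance_ppm == 1.0
    assert cfg.element_ranges["N"] == (0, 4)
    assert cfg.element_ranges["C"] == (1, 100)


def test_config_validation():
    with pytest.raises(ValueError):
        AssignmentConfig(tolerance_ppm=0)
    with pytest.raises(ValueError):
        AssignmentConfig(element_ranges={"C": (0, 10), "H": (1, 10)})
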
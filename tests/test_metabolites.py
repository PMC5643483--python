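"""Database loading, formula matching, classification and frequencies."""

import numpy as np
import pytest

from exomet.chem import parse_formula
from exomet.metabolites import (
    DatabaseError,
    DetectionMatrix,
    class_counts,
    detection_frequency,
    function_group_counts,
    load_metabolite_db,
    match_formulas,
    records_detected_by,
    shared_between_strains,
)
from exomet.simulate import simulate_detection_matrix
from exomet.spectra import SampleKey

DB_HEADER = (
    "name\tformula\tfunction\tpathway_class\tstrains\tfragmentation_confirmed\t"
    "detected_dshibae\tdetected_pinhibens\tother_studies\tmesocosm\tnorth_sea\n"
)


class TestLoadDb:
    def test_packaged_fixture_has_43_records(self, db):
        assert len(db) == 43
        names = {rec.name for rec in db}
        assert "Riboflavin" in names and "Tropodithietic acid" in names

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text(DB_HEADER, encoding="utf-8")
        assert load_metabolite_db(path) == []

    def test_bad_formula_names_record(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            DB_HEADER + "Foo\tC6H9NOX\tAA\tbiosynthetic\tdshibae\t0\t1\t0\t\t0\t0\n",
            encoding="utf-8",
        )
        with pytest.raises(DatabaseError, match="Foo"):
            load_metabolite_db(path)

    def test_unknown_function_label_lists_vocabulary(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            DB_HEADER + "Foo\tC6H12O6\tmystery juice\tbiosynthetic\tdshibae\t0\t1\t0\t\t0\t0\n",
            encoding="utf-8",
        )
        with pytest.raises(DatabaseError, match="mystery juice"):
            load_metabolite_db(path)

    def test_duplicate_rows_rejected(self, tmp_path):
        row = "Foo\tC6H12O6\tAA\tbiosynthetic\tdshibae\t0\t1\t0\t\t0\t0\n"
        path = tmp_path / "dup.tsv"
        path.write_text(DB_HEADER + row + row, encoding="utf-8")
        with pytest.raises(DatabaseError, match="duplicate"):
            load_metabolite_db(path)


class TestMatching:
    def test_riboflavin_and_ribazole_match(self, db):
        matches = match_formulas({parse_formula("C17H20N4O6")}, db)
        assert [m.record.name for m in matches] == ["Riboflavin"]
        matches = match_formulas({parse_formula("C14H18N2O4")}, db)
        assert [m.record.name for m in matches] == ["Alpha-ribazole"]

    def test_empty_detected_set(self, db):
        assert match_formulas(set(), db) == []

    def test_matching_is_monotone(self, db):
        small = {parse_formula("C17H20N4O6")}
        large = small | {parse_formula("C14H18N2O4"), parse_formula("C9H11NO3")}
        names_small = {m.record.name for m in match_formulas(small, db)}
        names_large = {m.record.name for m in match_formulas(large, db)}
        assert names_small <= names_large

    def test_isomers_flagged_degenerate(self, tmp_path):
        path = tmp_path / "iso.tsv"
        path.write_text(
            DB_HEADER
            + "Leucine\tC6H13NO2\tAA\tbiosynthetic\tdshibae\t0\t1\t0\t\t0\t0\n"
            + "Isoleucine\tC6H13NO2\tAA\tbiosynthetic\tdshibae\t0\t1\t0\t\t0\t0\n",
            encoding="utf-8",
        )
        db2 = load_metabolite_db(path)
        matches = match_formulas({parse_formula("C6H13NO2")}, db2)
        assert len(matches) == 2
        assert all(m.formula_degenerate for m in matches)


class TestCounts:
    def test_class_counts_partition_matches(self, db):
        for strain in ("dshibae", "pinhibens"):
            recs = records_detected_by(db, strain)
            matches = match_formulas({r.formula for r in recs}, recs)
            counts = class_counts(matches)
            assert sum(counts.values()) == len({m.record.key for m in matches})

    def test_class_counts_empty(self):
        assert class_counts([]) == {
            "biosynthetic": 0, "degradation": 0, "spontaneous": 0, "secondary": 0
        }

    def test_function_groups_printed_splits(self, db, vocabulary):
        expected = {
            "dshibae": {"vitamin-related": 12, "quorum-sensing": 5, "amino-acid-related": 10},
            "pinhibens": {"vitamin-related": 10, "quorum-sensing": 6, "amino-acid-related": 9},
        }
        for strain, want in expected.items():
            recs = records_detected_by(db, strain)
            matches = match_formulas({r.formula for r in recs}, recs)
            counts, percents = function_group_counts(matches, vocabulary)
            for group, n in want.items():
                assert counts[group] == n
            n_bio = sum(1 for r in recs if r.pathway_class == "biosynthetic")
            assert percents["vitamin-related"] == pytest.approx(100 * want["vitamin-related"] / n_bio)

    def test_shared_between_strains(self, db):
        a = records_detected_by(db, "dshibae")
        b = records_detected_by(db, "pinhibens")
        counts = shared_between_strains(a, b)
        assert counts == (35, 36, 28, 43)
        assert counts.n_total == counts.n_a + counts.n_b - counts.n_shared

    def test_shared_trivial_cases(self, db):
        x, y = db[:1], db[1:2]
        assert shared_between_strains(x, y) == (1, 1, 0, 2)
        assert shared_between_strains(x, x) == (1, 1, 1, 1)


class TestDetectionMatrix:
    def _columns(self, n):
        return [SampleKey("dshibae", "glucose", float(6 * i), "exponential", 1) for i in range(n)]

    def test_direct_ratio(self, db):
        cols = self._columns(4)
        rec = db[0]
        values = np.zeros((len(db), 4), dtype=bool)
        values[0, :2] = True
        values[1, :] = True
        matrix = DetectionMatrix(list(db), cols, values)
        assert detection_frequency(matrix, rec) == (50.0, 4)
        assert detection_frequency(matrix, db[1]) == (100.0, 4)

    def test_zero_columns_error(self, db):
        matrix = DetectionMatrix(list(db), [], np.zeros((len(db), 0), dtype=bool))
        with pytest.raises(ValueError):
            detection_frequency(matrix, db[0])

    def test_known_probability_recovered(self, db):
        """Seeded Bernoulli matrix at p=0.6 lands inside the binomial 95% CI."""
        cols = self._columns(20)
        matrix, manifest = simulate_detection_matrix(db, cols, 0.6, seed=5)
        half_width = 1.96 * np.sqrt(0.6 * 0.4 / 20) * 100
        freqs = [detection_frequency(matrix, rec)[0] for rec in db]
        mean_freq = np.mean(freqs)
        assert abs(mean_freq - 60.0) < half_width
        assert manifest.detection_probabilities[db[0].name] == 0.6

    def test_from_formula_sets(self, db):
        cols = self._columns(2)
        sets = {cols[0]: {db[0].formula}, cols[1]: {db[0].formula, db[1].formula}}
        matrix = DetectionMatrix.from_formula_sets(db, sets)
        assert detection_frequency(matrix, db[0]) == (100.0, 2)
        assert detection_frequency(matrix, db[1]) == (50.0, 2)
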
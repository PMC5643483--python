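"""Genome-predicted metabolite matching, classification and frequencies.

Detected molecular formulas are matched against a metabolite database
(name, neutral formula, function label, pathway class, per-strain
detection flags) by *exact canonical formula identity* — both sides of
the comparison are formulas, so no mass tolerance is involved.
Structural isomers are indistinguishable at formula level; every match
is therefore putative, and records sharing a formula are flagged
formula-degenerate rather than silently collapsed.

The packaged database is the annotated table of exometabolites of the
two Roseobacter model strains (Dinoroseobacter shibae, strain id
``dshibae``, and Phaeobacter inhibens, ``pinhibens``) with their
fragmentation-confirmation flags and presence flags in two
environmental DOM datasets.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .chem import FormulaError, MolecularFormula, parse_formula
from .spectra import SampleKey

__all__ = [
    "DetectionMatrix",
    "MatchResult",
    "MetaboliteRecord",
    "PATHWAY_CLASSES",
    "SharedCounts",
    "class_counts",
    "detection_frequency",
    "function_group_counts",
    "load_function_vocabulary",
    "load_metabolite_db",
    "match_formulas",
    "packaged_db_path",
    "records_detected_by",
    "shared_between_strains",
]

log = logging.getLogger(__name__)

PATHWAY_CLASSES = ("biosynthetic", "degradation", "spontaneous", "secondary")

DB_COLUMNS = (
    "name", "formula", "function", "pathway_class", "strains",
    "fragmentation_confirmed", "detected_dshibae", "detected_pinhibens",
    "other_studies", "mesocosm", "north_sea",
)


class DatabaseError(ValueError):
    """Malformed metabolite database row or configuration."""


@dataclass(frozen=True)
class MetaboliteRecord:
    """One database entry: a named metabolite with its neutral formula."""

    name: str
    formula: MolecularFormula
    function_label: str
    pathway_class: str
    strains: frozenset[str]
    fragmentation_confirmed: bool = False
    detected: frozenset[str] = frozenset()
    dom: frozenset[str] = frozenset()
    other_studies: str = ""

    def __post_init__(self) -> None:
        if self.pathway_class not in PATHWAY_CLASSES:
            raise DatabaseError(
                f"{self.name}: pathway_class must be one of {PATHWAY_CLASSES}, "
                f"got {self.pathway_class!r}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.name, self.formula.hill())


def packaged_db_path():
    return resources.files("exomet").joinpath("data/metabolite_db.tsv")


def packaged_vocabulary_path():
    return resources.files("exomet").joinpath("data/function_groups.tsv")


def load_function_vocabulary(path=None) -> dict[str, str]:
    """Controlled vocabulary mapping each function label to one group."""
    source = packaged_vocabulary_path() if path is None else path
    if hasattr(source, "read_text"):
        text = source.read_text(encoding="utf-8")
    else:
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    vocab: dict[str, str] = {}
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        vocab[row["function_label"]] = row["group"]
    return vocab


def load_metabolite_db(path=None, vocabulary: Mapping[str, str] | None = None) -> list[MetaboliteRecord]:
    """Load and validate a metabolite database TSV.

    An invalid formula or an unknown function label raises
    :class:`DatabaseError` naming the offending row; duplicate
    (name, formula) pairs are rejected.  Empty function cells are
    normalized to the label ``"unspecified"``.
    """
    source = packaged_db_path() if path is None else path
    if hasattr(source, "read_text"):
        text = source.read_text(encoding="utf-8")
    else:
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    if vocabulary is None:
        vocabulary = load_function_vocabulary()
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    missing = set(("name", "formula", "function", "pathway_class", "strains")) - set(reader.fieldnames or ())
    if missing:
        raise DatabaseError(f"metabolite DB is missing columns {sorted(missing)}")
    records: list[MetaboliteRecord] = []
    seen: set[tuple[str, str]] = set()
    strain_cols = [c for c in (reader.fieldnames or ()) if c.startswith("detected_")]
    dom_cols = [c for c in (reader.fieldnames or ()) if c in ("mesocosm", "north_sea")]
    for row in reader:
        name = row["name"].strip()
        try:
            formula = parse_formula(row["formula"].strip())
        except FormulaError as exc:
            raise DatabaseError(f"record {name!r}: {exc}") from exc
        label = (row.get("function") or "").strip() or "unspecified"
        if label not in vocabulary:
            raise DatabaseError(
                f"record {name!r}: unknown function label {label!r}; "
                f"vocabulary: {sorted(vocabulary)}"
            )
        detected = frozenset(
            c.removeprefix("detected_") for c in strain_cols if _flag(row.get(c))
        )
        dom = frozenset(c for c in dom_cols if _flag(row.get(c)))
        rec = MetaboliteRecord(
            name=name,
            formula=formula,
            function_label=label,
            pathway_class=row["pathway_class"].strip(),
            strains=frozenset(s for s in row["strains"].split(";") if s),
            fragmentation_confirmed=_flag(row.get("fragmentation_confirmed")),
            detected=detected,
            dom=dom,
            other_studies=(row.get("other_studies") or "").strip(),
        )
        if rec.key in seen:
            raise DatabaseError(f"duplicate record {rec.key}")
        seen.add(rec.key)
        records.append(rec)
    log.info("loaded %d metabolite records from %s", len(records), source)
    return records


def _flag(value) -> bool:
    return str(value or "").strip() in ("1", "true", "True", "+")


@dataclass(frozen=True)
class MatchResult:
    """A detected formula matched to a database record (putative)."""

    record: MetaboliteRecord
    strain: str | None = None
    detected_time_points: frozenset[SampleKey] = frozenset()
    formula_degenerate: bool = False


def match_formulas(
    detected: Iterable[MolecularFormula],
    db: Sequence[MetaboliteRecord],
    strain: str | None = None,
) -> list[MatchResult]:
    """Match a detected formula set against the database.

    A record matches iff its canonical formula equals a detected
    formula.  All isomeric records of a matched formula are reported,
    each flagged formula-degenerate when the formula is shared.
    """
    detected_set = set(detected)
    by_formula: dict[MolecularFormula, list[MetaboliteRecord]] = {}
    for rec in db:
        by_formula.setdefault(rec.formula, []).append(rec)
    matches = []
    for rec in db:  # DB order keeps reports deterministic
        if rec.formula in detected_set:
            matches.append(
                MatchResult(
                    record=rec,
                    strain=strain,
                    formula_degenerate=len(by_formula[rec.formula]) > 1,
                )
            )
    return matches


def class_counts(matches: Sequence[MatchResult]) -> dict[str, int]:
    """Distinct matched records per pathway class (classes partition matches)."""
    seen: set[tuple[str, str]] = set()
    counts = {cls: 0 for cls in PATHWAY_CLASSES}
    for m in matches:
        if m.record.key in seen:
            continue
        seen.add(m.record.key)
        counts[m.record.pathway_class] += 1
    return counts


def function_group_counts(
    matches: Sequence[MatchResult],
    vocabulary: Mapping[str, str] | None = None,
) -> tuple[dict[str, int], dict[str, float]]:
    """Distinct-record counts per function group, plus percentages.

    Percentages are relative to the number of distinct matched records
    in biosynthetic pathways (the denominator used when subdividing the
    annotated compounds into vitamin-, quorum-sensing- and amino-acid-
    related groups).
    """
    if vocabulary is None:
        vocabulary = load_function_vocabulary()
    counts: dict[str, int] = {g: 0 for g in dict.fromkeys(vocabulary.values())}
    seen: set[tuple[str, str]] = set()
    n_biosynthetic = 0
    for m in matches:
        if m.record.key in seen:
            continue
        seen.add(m.record.key)
        label = m.record.function_label
        if label not in vocabulary:
            raise DatabaseError(f"function label {label!r} missing from vocabulary")
        counts[vocabulary[label]] += 1
        if m.record.pathway_class == "biosynthetic":
            n_biosynthetic += 1
    if n_biosynthetic:
        percents = {g: 100.0 * n / n_biosynthetic for g, n in counts.items()}
    else:
        percents = {g: float("nan") for g in counts}
    return counts, percents


class SharedCounts(NamedTuple):
    n_a: int
    n_b: int
    n_shared: int
    n_total: int


def shared_between_strains(
    records_a: Iterable[MetaboliteRecord],
    records_b: Iterable[MetaboliteRecord],
) -> SharedCounts:
    """Distinct-record cardinalities for two strains with inclusion-exclusion."""
    a = {r.key for r in records_a}
    b = {r.key for r in records_b}
    counts = SharedCounts(len(a), len(b), len(a & b), len(a | b))
    assert counts.n_total == counts.n_a + counts.n_b - counts.n_shared
    return counts


def records_detected_by(db: Sequence[MetaboliteRecord], strain: str) -> list[MetaboliteRecord]:
    """Records whose detection flag is set for *strain* (annotation mode)."""
    return [r for r in db if strain in r.detected]


@dataclass
class DetectionMatrix:
    """Metabolite × sample boolean presence matrix.

    Columns are the non-excluded, blank-subtracted samples of one run;
    rows follow database order.
    """

    records: list[MetaboliteRecord]
    columns: list[SampleKey]
    values: np.ndarray  # bool, shape (n_records, n_columns)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != (len(self.records), len(self.columns)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.records)} records x {len(self.columns)} columns"
            )

    @classmethod
    def from_formula_sets(
        cls,
        records: Sequence[MetaboliteRecord],
        sample_formulas: Mapping[SampleKey, set[MolecularFormula]],
    ) -> "DetectionMatrix":
        columns = list(sample_formulas)
        values = np.array(
            [[rec.formula in sample_formulas[col] for col in columns] for rec in records],
            dtype=bool,
        ).reshape(len(records), len(columns))
        return cls(list(records), columns, values)

    def restrict(self, predicate) -> "DetectionMatrix":
        idx = [i for i, col in enumerate(self.columns) if predicate(col)]
        cols = [self.columns[i] for i in idx]
        vals = self.values[:, idx] if idx else np.zeros((len(self.records), 0), dtype=bool)
        return DetectionMatrix(self.records, cols, vals)


def detection_frequency(matrix: DetectionMatrix, record: MetaboliteRecord) -> tuple[float, int]:
    """Detection frequency of a record as (percentage, n time points)."""
    n = len(matrix.columns)
    if n == 0:
        raise ValueError("detection frequency undefined for zero sample columns")
    try:
        i = next(i for i, r in enumerate(matrix.records) if r.key == record.key)
    except StopIteration:
        raise KeyError(f"record {record.key} not in matrix") from None
    return 100.0 * float(matrix.values[i].sum()) / n, n
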
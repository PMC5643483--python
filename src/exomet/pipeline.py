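"""End-to-end orchestration: filter → calibrate → assign → blank-subtract
→ lysis-exclude → union → match → classify → screen → growth statistics.

Two entry modes:

* *annotation-only* — no spectra are processed; the per-strain detection
  flags of the metabolite database drive every summary count.  This is
  the mode that reproduces the annotated-table summary (per-strain
  detected counts, shared/total, function-group splits, DOM overlaps).
* *spectra* — a sample manifest of peak-list files is processed through
  the full chain and the detected formula unions are matched against
  the database.

Reports are plain TSV/JSON so that every summary count remains
recomputable from the emitted per-stage tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .assign import DEFAULT_CONFIG, AssignmentConfig, assign_spectrum
from .chem import MolecularFormula
from .dom import DOMFormulaSet, overlap_report, packaged_dom_set, screen
from .growth import lysis_check
from .metabolites import (
    DetectionMatrix,
    MetaboliteRecord,
    class_counts,
    function_group_counts,
    load_function_vocabulary,
    load_metabolite_db,
    match_formulas,
    records_detected_by,
    shared_between_strains,
)
from .spectra import (
    CalibrationError,
    SampleKey,
    calibrate,
    filter_peaks,
    read_manifest,
    read_peaklist,
    subtract_blank,
)

__all__ = [
    "PipelineConfig",
    "PipelineReport",
    "annotation_summary",
    "render_table1",
    "run_pipeline",
]

log = logging.getLogger(__name__)

TABLE1_COLUMNS = (
    "name", "formula", "function", "pathway_class", "strains",
    "fragmentation_confirmed", "detected_dshibae", "detected_pinhibens",
    "other_studies", "mesocosm", "north_sea",
)


@dataclass
class PipelineConfig:
    """Paths, thresholds and the assignment configuration for one run."""

    db_path: str | None = None            # packaged database when None
    vocabulary_path: str | None = None
    dom_paths: Mapping[str, str] = field(default_factory=dict)  # name -> path; packaged sets when empty
    manifest_path: str | None = None
    annotation_only: bool = False
    assignment: AssignmentConfig = field(default_factory=lambda: DEFAULT_CONFIG)
    min_snr: float = 5.0
    mass_min: float = 92.0
    mass_max: float = 2000.0
    calibration_refs: Sequence[float] = ()
    calibration_tol_ppm: float = 2.0
    lysis_threshold: float = 0.05
    fg_c_per_cell: float = 50.0
    carbon_table_path: str | None = None
    significance_level: float = 0.01
    out_dir: str | None = None
    seed: int = 0


@dataclass
class PipelineReport:
    summary: dict
    records: list[MetaboliteRecord]
    matches_by_strain: dict[str, list]
    detection_matrix: DetectionMatrix | None = None
    table1: str = ""


def _load_inputs(cfg: PipelineConfig):
    vocabulary = load_function_vocabulary(cfg.vocabulary_path)
    db = load_metabolite_db(cfg.db_path, vocabulary)
    if cfg.dom_paths:
        dom_sets = {
            name: _load_dom(path, name) for name, path in cfg.dom_paths.items()
        }
    else:
        dom_sets = {name: packaged_dom_set(name) for name in ("mesocosm", "north_sea")}
    return db, vocabulary, dom_sets


def _load_dom(path, name) -> DOMFormulaSet:
    from .dom import load_dom_set

    return load_dom_set(path, name)


def annotation_summary(
    db: Sequence[MetaboliteRecord],
    dom_sets: Mapping[str, DOMFormulaSet],
    vocabulary: Mapping[str, str] | None = None,
) -> dict:
    """Summary counts computed from the database's detection flags."""
    strains = sorted({s for rec in db for s in rec.detected})
    detected = {s: records_detected_by(db, s) for s in strains}
    summary: dict = {
        "n_records": len(db),
        "strains": strains,
        "detected_counts": {s: len(v) for s, v in detected.items()},
        "class_counts": {},
        "function_groups": {},
    }
    for s, recs in detected.items():
        matches = match_formulas({r.formula for r in recs}, recs, strain=s)
        summary["class_counts"][s] = class_counts(matches)
        counts, percents = function_group_counts(matches, vocabulary)
        summary["function_groups"][s] = {
            g: {"count": counts[g], "percent": percents[g]} for g in counts
        }
    if len(strains) == 2:
        a, b = strains
        shared = shared_between_strains(detected[a], detected[b])
        summary["shared"] = {
            "n_" + a: shared.n_a,
            "n_" + b: shared.n_b,
            "n_shared": shared.n_shared,
            "n_total": shared.n_total,
        }
    summary["dom_overlap"] = {}
    for name, dom in dom_sets.items():
        overlap = overlap_report(detected, dom)
        summary["dom_overlap"][name] = {
            "n_total": overlap.n_total,
            "per_strain": dict(overlap.per_strain),
            "n_all_strains": overlap.n_all_strains,
            "consistent": overlap.consistent,
        }
    return summary


def render_table1(
    records: Sequence[MetaboliteRecord],
    strain_order: Sequence[str] = ("dshibae", "pinhibens"),
    dom_order: Sequence[str] = ("mesocosm", "north_sea"),
) -> str:
    """Annotated report table, one row per metabolite, fixed column order.

    Round-trips the packaged database: rendering the loaded records
    reproduces the fixture file byte for byte.
    """
    lines = ["\t".join(TABLE1_COLUMNS)]
    for rec in records:
        row = [
            rec.name,
            rec.formula.hill(),
            "" if rec.function_label == "unspecified" else rec.function_label,
            rec.pathway_class,
            ";".join(sorted(rec.strains, key=list(strain_order).index)),
            "1" if rec.fragmentation_confirmed else "0",
        ]
        row += ["1" if s in rec.detected else "0" for s in strain_order]
        row.append(rec.other_studies)
        row += ["1" if d in rec.dom else "0" for d in dom_order]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def _spectra_summary(cfg: PipelineConfig, db, vocabulary, dom_sets) -> PipelineReport:
    entries = read_manifest(cfg.manifest_path)
    blanks: dict[tuple, set[MolecularFormula]] = {}
    samples: dict[tuple, tuple[SampleKey, set[MolecularFormula]]] = {}
    for entry in entries:
        pl = read_peaklist(entry.path, entry.mode, sample=entry.sample, is_blank=entry.is_blank)
        pl = filter_peaks(pl, cfg.min_snr, cfg.mass_min, cfg.mass_max)
        if cfg.calibration_refs:
            try:
                pl, _ = calibrate(pl, cfg.calibration_refs, cfg.calibration_tol_ppm)
            except CalibrationError as exc:
                log.warning("sample %s left uncalibrated: %s", entry.sample, exc)
        spec = assign_spectrum(pl, cfg.assignment)
        group = (entry.sample.strain, entry.sample.substrate,
                 entry.sample.time_point_h, entry.mode)
        if entry.is_blank:
            blanks.setdefault(group, set()).update(spec.formula_set)
        else:
            key = group + (entry.sample.replicate,)
            samples[key] = (entry.sample, spec.formula_set)

    excluded = _lysis_exclusions(cfg)
    per_sample: dict[SampleKey, set[MolecularFormula]] = {}
    for (strain, substrate, tp, mode, rep), (sample, formulas) in samples.items():
        subtracted = subtract_blank(formulas, blanks.get((strain, substrate, tp, mode), set()))
        per_sample.setdefault(sample, set()).update(subtracted)

    unions: dict[str, set[MolecularFormula]] = {}
    for sample, formulas in per_sample.items():
        if (sample.strain, sample.substrate, sample.time_point_h) in excluded:
            log.info("excluding %s (lysis mass balance)", sample)
            continue
        unions.setdefault(sample.strain, set()).update(formulas)

    matches_by_strain = {
        strain: match_formulas(formulas, db, strain=strain)
        for strain, formulas in sorted(unions.items())
    }
    matched_records = {
        strain: [m.record for m in matches] for strain, matches in matches_by_strain.items()
    }
    matrix = DetectionMatrix.from_formula_sets(db, per_sample) if per_sample else None

    summary: dict = {
        "mode": "spectra",
        "n_samples": len(per_sample),
        "n_excluded": len([
            s for s in per_sample
            if (s.strain, s.substrate, s.time_point_h) in excluded
        ]),
        "formula_counts": {s: len(f) for s, f in sorted(unions.items())},
        "matched_counts": {s: len({m.record.key for m in v}) for s, v in matches_by_strain.items()},
        "class_counts": {s: class_counts(v) for s, v in matches_by_strain.items()},
        "function_groups": {},
        "dom_overlap": {},
    }
    for s, v in matches_by_strain.items():
        counts, percents = function_group_counts(v, vocabulary)
        summary["function_groups"][s] = {
            g: {"count": counts[g], "percent": percents[g]} for g in counts
        }
    strains = sorted(matched_records)
    if len(strains) == 2:
        shared = shared_between_strains(matched_records[strains[0]], matched_records[strains[1]])
        summary["shared"] = {
            "n_" + strains[0]: shared.n_a,
            "n_" + strains[1]: shared.n_b,
            "n_shared": shared.n_shared,
            "n_total": shared.n_total,
        }
    for name, dom in dom_sets.items():
        overlap = overlap_report(matched_records, dom)
        summary["dom_overlap"][name] = {
            "n_total": overlap.n_total,
            "per_strain": dict(overlap.per_strain),
            "n_all_strains": overlap.n_all_strains,
            "consistent": overlap.consistent,
        }
    all_matched = [m.record for v in matches_by_strain.values() for m in v]
    dedup: dict[tuple, MetaboliteRecord] = {r.key: r for r in all_matched}
    table1 = render_table1([rec for rec in db if rec.key in dedup])
    return PipelineReport(summary, list(db), matches_by_strain, matrix, table1)


def _lysis_exclusions(cfg: PipelineConfig) -> set[tuple]:
    if cfg.carbon_table_path is None:
        return set()
    import pandas as pd

    df = pd.read_csv(cfg.carbon_table_path, sep="\t", comment="#")
    excluded = set()
    for _, row in df.iterrows():
        budget = lysis_check(
            float(row["cells_per_ml"]), cfg.fg_c_per_cell,
            float(row["dcaa_c_mg_l"]), cfg.lysis_threshold,
        )
        if budget.lysis_flag:
            excluded.add((str(row["strain"]), str(row["substrate"]), float(row["time_point_h"])))
    return excluded


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    """Execute the configured pipeline and (optionally) write the report bundle."""
    db, vocabulary, dom_sets = _load_inputs(cfg)
    if cfg.annotation_only or cfg.manifest_path is None:
        summary = annotation_summary(db, dom_sets, vocabulary)
        summary["mode"] = "annotation-only"
        detected_keys = {rec.key for rec in db if rec.detected}
        matches_by_strain = {
            s: match_formulas({r.formula for r in records_detected_by(db, s)},
                              records_detected_by(db, s), strain=s)
            for s in summary["strains"]
        }
        report = PipelineReport(
            summary=summary,
            records=list(db),
            matches_by_strain=matches_by_strain,
            table1=render_table1([rec for rec in db if rec.key in detected_keys]),
        )
    else:
        report = _spectra_summary(cfg, db, vocabulary, dom_sets)
    if cfg.out_dir is not None:
        _write_report(cfg, report, dom_sets)
    return report


def _write_report(cfg: PipelineConfig, report: PipelineReport, dom_sets) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "summary.json").write_text(
        json.dumps(report.summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    (out / "table1.tsv").write_text(report.table1, encoding="utf-8")
    lines = ["strain\tname\tformula\tfunction\tpathway_class\tformula_degenerate"]
    for strain, matches in report.matches_by_strain.items():
        for m in matches:
            lines.append("\t".join([
                strain, m.record.name, m.record.formula.hill(),
                m.record.function_label, m.record.pathway_class,
                "1" if m.formula_degenerate else "0",
            ]))
    (out / "matches.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
    screens = ["dom_set\tname\tformula\tpresent"]
    for name, dom in dom_sets.items():
        presence = screen(report.records, dom)
        for rec in report.records:
            screens.append("\t".join([
                name, rec.name, rec.formula.hill(), "1" if presence[rec.name] else "0",
            ]))
    (out / "dom_screen.tsv").write_text("\n".join(screens) + "\n", encoding="utf-8")
    log.info("report bundle written to %s", out)
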
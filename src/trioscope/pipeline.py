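"""End-to-end per-family analysis: filter -> classify -> report.

Wires the stages together for the command-line entry points and writes a
run manifest (tool version, input digests, thresholds) next to the
reports so a rerun with identical inputs is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .filters import FILTER_TSV_HEADER, apply_filters, filter_trail_tsv_row
from .inheritance import DeNovoParams, call_family
from .ped import PhenotypeSubgroup, TrioFamily, assign_subgroup, load_cohort
from .reports import (
    AcmgClass,
    FamilyReport,
    assemble_report,
    read_family_report,
    write_family_report,
)
from .variants import read_annotated_vcf, read_gene_panel

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, message: str, exit_code: int = 1):
        super().__init__(message)
        self.exit_code = exit_code


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def analyze_family(
    fam: TrioFamily,
    vcf_path: str | Path,
    panel: frozenset[str],
    params: DeNovoParams,
    class_assignments: Mapping[str, tuple[str, bool]] | None = None,
    af_threshold: float = 0.01,
    allow_female_xl_carrier: bool = False,
) -> tuple[FamilyReport, list[str]]:
    """Analyze one trio; returns the report and filter-trail TSV rows."""
    variants = read_annotated_vcf(vcf_path, fam)
    trails = {v.variant_id: apply_filters(v, panel, af_threshold) for v in variants}
    passing = [v for v in variants if trails[v.variant_id].passed]
    calls = call_family(passing, fam, params, allow_female_xl_carrier)
    classes = {
        vid: (AcmgClass(acmg), conc)
        for vid, (acmg, conc) in (class_assignments or {}).items()
    }
    subgroup = assign_subgroup(fam.hpo_terms, fam.fetus)
    report = assemble_report(
        fam,
        subgroup,
        calls,
        {v.variant_id: v for v in variants},
        classes,
        trails,
    )
    trail_rows = [filter_trail_tsv_row(fam.family_id, v, trails[v.variant_id]) for v in variants]
    return report, trail_rows


def run_prioritize(
    ped_path: str | Path,
    phenotype_path: str | Path,
    vcf_dir: str | Path,
    panel_path: str | Path,
    out_dir: str | Path,
    classes_path: str | Path | None = None,
    params: DeNovoParams | None = None,
    af_threshold: float = 0.01,
    allow_female_xl_carrier: bool = False,
) -> list[FamilyReport]:
    """Analyze every trio in the cohort and write per-family reports."""
    params = params or DeNovoParams()
    families = load_cohort(ped_path, phenotype_path)
    if not families:
        raise PipelineError("no families found in pedigree", exit_code=2)
    panel = read_gene_panel(panel_path)
    if not panel:
        raise PipelineError("gene panel is empty", exit_code=4)
    vcf_dir = Path(vcf_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    class_table: Mapping[str, Mapping[str, tuple[str, bool]]] = {}
    if classes_path is not None:
        from .simulate import read_class_table

        class_table = read_class_table(classes_path)

    thresholds = dataclasses.asdict(params) | {
        "af_threshold": af_threshold,
        "allow_female_xl_carrier": allow_female_xl_carrier,
    }
    reports: list[FamilyReport] = []
    trail_rows = [FILTER_TSV_HEADER]
    n_missing_vcf = 0
    for fam in families:
        vcf_path = vcf_dir / f"{fam.family_id}.vcf"
        if not vcf_path.exists():
            log.warning("family %s: no VCF at %s; skipped", fam.family_id, vcf_path)
            n_missing_vcf += 1
            continue
        report, rows = analyze_family(
            fam,
            vcf_path,
            panel,
            params,
            class_table.get(fam.family_id),
            af_threshold,
            allow_female_xl_carrier,
        )
        write_family_report(report, out_dir, thresholds)
        trail_rows.extend(rows)
        reports.append(report)
        log.info("family %s: solved=%s genes=%s", fam.family_id, report.solved, sorted(report.reported_genes))
    if not reports:
        raise PipelineError("no families with VCF data", exit_code=2)

    (out_dir / "filter_trail.tsv").write_text("\n".join(trail_rows) + "\n", encoding="utf-8")
    manifest = {
        "tool_version": __version__,
        "schema_version": "1",
        "thresholds": thresholds,
        "inputs": {
            "ped": _digest(Path(ped_path)),
            "phenotypes": _digest(Path(phenotype_path)),
            "panel": _digest(Path(panel_path)),
            "classes": _digest(Path(classes_path)) if classes_path else None,
        },
        "n_families": len(reports),
        "n_missing_vcf": n_missing_vcf,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return reports


def load_reports(reports_dir: str | Path) -> list[FamilyReport]:
    paths = sorted(Path(reports_dir).glob("*.report.json"))
    if not paths:
        raise PipelineError(f"no reports found under {reports_dir}", exit_code=2)
    return [read_family_report(p) for p in paths]
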
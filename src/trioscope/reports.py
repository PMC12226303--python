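"""Per-family candidate reports and reporting semantics.

ACMG class labels are inputs (the classification itself involves clinical
judgment and is not computed here).  A candidate is reportable when its
class is 4 or 5, or class 3 with the phenotype-concordance flag set
("class 3+").  A family is solved when it has at least one reportable
candidate; reportable variants in two different genes flag a possible dual
diagnosis.  Compound-het pairs are reported atomically: both members
reportable, or neither.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

from .filters import FilterTrail
from .inheritance import InheritanceCall, InheritanceMode, TransmittingParent
from .ped import PhenotypeSubgroup, Sex, TrioFamily
from .variants import AnnotatedVariant, ClinvarStatus, ConsequenceClass

log = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

REPORT_TSV_HEADER = (
    "family_id\tgene\tchrom\tpos\tref\talt\tmode\ttransmitting_parent\t"
    "pair_id\tacmg_class\thighlight\tparental_alt_fraction"
)


class AcmgClass(str, Enum):
    CLASS3 = "class3"
    CLASS4 = "class4"
    CLASS5 = "class5"
    UNASSIGNED = "unassigned"


@dataclass
class CandidateVariant:
    variant: AnnotatedVariant
    call: InheritanceCall
    trail: FilterTrail | None
    highlight: bool
    acmg_class: AcmgClass
    phenotype_concordant: bool
    pair_id: str | None = None
    reportable: bool = False

    def class_reportable(self) -> bool:
        if self.acmg_class in (AcmgClass.CLASS4, AcmgClass.CLASS5):
            return True
        return self.acmg_class is AcmgClass.CLASS3 and self.phenotype_concordant


@dataclass
class FamilyReport:
    family_id: str
    subgroup: PhenotypeSubgroup
    consanguineous: bool
    proband_sex: Sex
    candidates: list[CandidateVariant] = field(default_factory=list)
    solved: bool = False
    reported_genes: frozenset[str] = frozenset()
    dual_diagnosis: bool = False

    @property
    def reportable_candidates(self) -> list[CandidateVariant]:
        return [c for c in self.candidates if c.reportable]

    @property
    def reported_modes(self) -> set[InheritanceMode]:
        return {c.call.mode for c in self.reportable_candidates}


def assemble_report(
    fam: TrioFamily,
    subgroup: PhenotypeSubgroup,
    calls: Sequence[InheritanceCall],
    variants_by_id: Mapping[str, AnnotatedVariant],
    class_assignments: Mapping[str, tuple[AcmgClass, bool]],
    trails: Mapping[str, FilterTrail] | None = None,
) -> FamilyReport:
    """Build the family report from inheritance calls and class labels.

    ``class_assignments`` maps variant id -> (ACMG class, phenotype
    concordant); uncalled ids in the mapping are ignored with a warning.
    Compound-het pairs become two candidates sharing a ``pair_id`` and are
    reportable only if both members carry a reportable class.
    """
    trails = trails or {}
    called_ids = {vid for call in calls for vid in call.variant_ids}
    for vid in class_assignments:
        if vid not in called_ids:
            log.warning("family %s: class assignment for uncalled variant %s ignored", fam.family_id, vid)

    candidates: list[CandidateVariant] = []
    pair_counter = 0
    for call in calls:
        is_pair = call.mode is InheritanceMode.AR_COMPHET
        pair_id = None
        if is_pair:
            pair_counter += 1
            pair_id = f"{fam.family_id}_pair{pair_counter}"
        members: list[CandidateVariant] = []
        for vid in call.variant_ids:
            variant = variants_by_id.get(vid)
            if variant is None:
                log.warning("family %s: call references unknown variant %s", fam.family_id, vid)
                continue
            acmg, concordant = class_assignments.get(vid, (AcmgClass.UNASSIGNED, False))
            members.append(
                CandidateVariant(
                    variant=variant,
                    call=call,
                    trail=trails.get(vid),
                    highlight=variant.clinvar is ClinvarStatus.PATHOGENIC_ONLY,
                    acmg_class=acmg,
                    phenotype_concordant=concordant,
                    pair_id=pair_id,
                )
            )
        if len(members) < len(call.variant_ids):
            continue
        if is_pair:
            ok = all(m.class_reportable() for m in members)
            for m in members:
                m.reportable = ok
        else:
            for m in members:
                m.reportable = m.class_reportable()
        candidates.extend(members)

    genes = frozenset(c.variant.gene for c in candidates if c.reportable)
    return FamilyReport(
        family_id=fam.family_id,
        subgroup=subgroup,
        consanguineous=fam.consanguineous,
        proband_sex=fam.proband.sex,
        candidates=candidates,
        solved=bool(genes) or any(c.reportable for c in candidates),
        reported_genes=genes,
        dual_diagnosis=len(genes) >= 2,
    )


def _candidate_row(report: FamilyReport, c: CandidateVariant) -> str:
    frac = "" if c.call.parental_alt_fraction is None else f"{c.call.parental_alt_fraction:.4f}"
    return "\t".join(
        [
            report.family_id,
            c.variant.gene,
            c.variant.chrom,
            str(c.variant.pos),
            c.variant.ref,
            c.variant.alt,
            c.call.mode.value,
            c.call.transmitting_parent.value,
            c.pair_id or "",
            c.acmg_class.value,
            str(int(c.highlight)),
            frac,
        ]
    )


def _candidate_json(c: CandidateVariant) -> dict:
    return {
        "variant_id": c.variant.variant_id,
        "gene": c.variant.gene,
        "mode": c.call.mode.value,
        "transmitting_parent": c.call.transmitting_parent.value,
        "parental_alt_fraction": c.call.parental_alt_fraction,
        "notes": c.call.notes,
        "pair_id": c.pair_id,
        "acmg_class": c.acmg_class.value,
        "phenotype_concordant": c.phenotype_concordant,
        "highlight": c.highlight,
        "reportable": c.reportable,
        "filter_trail": None
        if c.trail is None
        else {
            "frequency_pass": c.trail.frequency_pass,
            "region_pass": c.trail.region_pass,
            "panel_pass": c.trail.panel_pass,
            "reasons": c.trail.reasons,
        },
    }


def report_to_dict(report: FamilyReport, thresholds: dict | None = None) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "family_id": report.family_id,
        "subgroup": report.subgroup.value,
        "consanguineous": report.consanguineous,
        "proband_sex": report.proband_sex.value,
        "solved": report.solved,
        "reported_genes": sorted(report.reported_genes),
        "dual_diagnosis": report.dual_diagnosis,
        "thresholds": thresholds or {},
        "candidates": [_candidate_json(c) for c in report.candidates],
    }


def write_family_report(
    report: FamilyReport, out_dir: str | Path, thresholds: dict | None = None
) -> tuple[Path, Path]:
    """Write ``<family>.report.tsv`` (reportable rows) and a JSON sidecar.

    Output is deterministic for a fixed input (stable column and row order,
    sorted JSON keys).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv_path = out_dir / f"{report.family_id}.report.tsv"
    json_path = out_dir / f"{report.family_id}.report.json"
    rows = [REPORT_TSV_HEADER] + [_candidate_row(report, c) for c in report.reportable_candidates]
    tsv_path.write_text("\n".join(rows) + "\n", encoding="utf-8")
    json_path.write_text(
        json.dumps(report_to_dict(report, thresholds), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return tsv_path, json_path


def read_family_report(json_path: str | Path) -> FamilyReport:
    """Load the JSON sidecar back into a summary-grade FamilyReport.

    Candidate variants are reconstructed only to the level the cohort
    summarizer needs (mode, gene, class, pair id); genotype-level detail is
    not round-tripped.
    """
    data = json.loads(Path(json_path).read_text(encoding="utf-8"))
    report = FamilyReport(
        family_id=data["family_id"],
        subgroup=PhenotypeSubgroup(data["subgroup"]),
        consanguineous=data["consanguineous"],
        proband_sex=Sex(data["proband_sex"]),
        solved=data["solved"],
        reported_genes=frozenset(data["reported_genes"]),
        dual_diagnosis=data["dual_diagnosis"],
    )
    for cd in data["candidates"]:
        chrom, pos, ref, alt = cd["variant_id"].split(":")
        variant = AnnotatedVariant(
            chrom=chrom,
            pos=int(pos),
            ref=ref,
            alt=alt,
            gene=cd["gene"],
            consequence=ConsequenceClass.OTHER,
            pop_af=0.0,
            clinvar=ClinvarStatus.PATHOGENIC_ONLY if cd["highlight"] else ClinvarStatus.ABSENT,
        )
        call = InheritanceCall(
            mode=InheritanceMode(cd["mode"]),
            variant_ids=(cd["variant_id"],),
            transmitting_parent=TransmittingParent(cd["transmitting_parent"]),
            parental_alt_fraction=cd["parental_alt_fraction"],
            notes=cd["notes"],
        )
        report.candidates.append(
            CandidateVariant(
                variant=variant,
                call=call,
                trail=None,
                highlight=cd["highlight"],
                acmg_class=AcmgClass(cd["acmg_class"]),
                phenotype_concordant=cd["phenotype_concordant"],
                pair_id=cd["pair_id"],
                reportable=cd["reportable"],
            )
        )
    return report
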
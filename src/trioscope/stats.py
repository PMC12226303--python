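"""Cohort-level diagnostic-yield accounting.

All ratios are stored raw (numerator/denominator counts); formatted
percentages are derived on demand with round-half-away-from-zero at the
requested number of decimals and are never accumulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Sequence

from .inheritance import InheritanceMode
from .ped import PhenotypeSubgroup, Sex
from .reports import FamilyReport


class MosaicConvention(str, Enum):
    """Where mosaic-refined de novo calls are counted in the mode table."""

    AD_INHERITED = "ad_inherited"  # dominant-inherited / mosaicism bucket
    DE_NOVO = "de_novo"


_MOSAIC_MODES = {
    InheritanceMode.PARENTAL_MOSAIC_MATERNAL,
    InheritanceMode.PARENTAL_MOSAIC_PATERNAL,
}


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (3.5 -> 4, 32.25 -> 32.3 at 1 decimal)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int, decimals: int = 0) -> float | int:
    """Formatted percentage; integer when decimals == 0."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    value = round_half_away(100.0 * numerator / denominator, decimals)
    return int(value) if decimals == 0 else value


@dataclass
class SubgroupRow:
    n: int = 0
    n_solved: int = 0

    def yield_percent(self, decimals: int = 1):
        return percent(self.n_solved, self.n, decimals)


@dataclass
class ConsanguinityStats:
    n_consang: int
    n_consang_solved: int
    n_hom_total: int
    n_hom_in_consang: int

    def yield_percent(self, decimals: int = 0):
        return percent(self.n_consang_solved, self.n_consang, decimals)

    def hom_share_percent(self, decimals: int = 0):
        return percent(self.n_hom_in_consang, self.n_hom_total, decimals)


@dataclass
class CohortSummary:
    n_total: int
    n_solved: int
    per_subgroup: dict[PhenotypeSubgroup, SubgroupRow]
    mode_counts: dict[InheritanceMode, int]
    consang: ConsanguinityStats | None
    sex_breakdown: dict[Sex, SubgroupRow]
    dual_diagnosis_count: int

    def yield_overall(self, decimals: int = 0):
        return percent(self.n_solved, self.n_total, decimals)

    def mode_percent(self, mode: InheritanceMode, decimals: int = 0):
        return percent(self.mode_counts.get(mode, 0), self.n_solved, decimals)

    def de_novo_total_percent(self, decimals: int = 0):
        n = self.mode_counts.get(InheritanceMode.AD_DENOVO, 0) + self.mode_counts.get(
            InheritanceMode.XL_DENOVO, 0
        )
        return percent(n, self.n_solved, decimals)

    def ar_total_percent(self, decimals: int = 0):
        n = self.mode_counts.get(InheritanceMode.AR_HOM, 0) + self.mode_counts.get(
            InheritanceMode.AR_COMPHET, 0
        )
        return percent(n, self.n_solved, decimals)


def _family_modes(
    report: FamilyReport, mosaic_as: MosaicConvention
) -> set[InheritanceMode]:
    """Reportable modes of one family, one entry per mode, mosaic bucketed."""
    modes: set[InheritanceMode] = set()
    for c in report.reportable_candidates:
        mode = c.call.mode
        if mode in _MOSAIC_MODES:
            mode = (
                InheritanceMode.AD_INHERITED
                if mosaic_as is MosaicConvention.AD_INHERITED
                else (
                    InheritanceMode.XL_DENOVO
                    if "x_linked" in c.call.notes
                    else InheritanceMode.AD_DENOVO
                )
            )
        modes.add(mode)
    return modes


def mode_distribution(
    reports: Sequence[FamilyReport],
    mosaic_as: MosaicConvention = MosaicConvention.AD_INHERITED,
) -> dict[InheritanceMode, int]:
    """Mode counts over reportable candidates of solved families.

    Each family contributes each of its reportable modes once (dual
    diagnoses may therefore push the column sum above the solved-family
    count).  Compound-het pairs count once.
    """
    counts: dict[InheritanceMode, int] = {}
    for report in reports:
        if not report.solved:
            continue
        for mode in _family_modes(report, mosaic_as):
            counts[mode] = counts.get(mode, 0) + 1
    return counts


def consanguinity_stats(
    reports: Sequence[FamilyReport],
    mosaic_as: MosaicConvention = MosaicConvention.AD_INHERITED,
) -> ConsanguinityStats | None:
    """Yield among consanguineous families and their share of AR_HOM diagnoses.

    Returns None when the cohort has no consanguineous family.
    """
    consang = [r for r in reports if r.consanguineous]
    if not consang:
        return None
    hom_families = [
        r
        for r in reports
        if r.solved and InheritanceMode.AR_HOM in _family_modes(r, mosaic_as)
    ]
    return ConsanguinityStats(
        n_consang=len(consang),
        n_consang_solved=sum(1 for r in consang if r.solved),
        n_hom_total=len(hom_families),
        n_hom_in_consang=sum(1 for r in hom_families if r.consanguineous),
    )


def summarize(
    reports: Sequence[FamilyReport],
    mosaic_as: MosaicConvention = MosaicConvention.AD_INHERITED,
) -> CohortSummary:
    """Compute the full cohort summary from family reports alone."""
    if not reports:
        raise ValueError("cannot summarize an empty cohort")
    ids = [r.family_id for r in reports]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate family ids in cohort")
    per_subgroup: dict[PhenotypeSubgroup, SubgroupRow] = {
        g: SubgroupRow() for g in PhenotypeSubgroup
    }
    sex_breakdown: dict[Sex, SubgroupRow] = {s: SubgroupRow() for s in Sex}
    n_solved = 0
    for r in reports:
        row = per_subgroup[r.subgroup]
        row.n += 1
        sex_row = sex_breakdown[r.proband_sex]
        sex_row.n += 1
        if r.solved:
            n_solved += 1
            row.n_solved += 1
            sex_row.n_solved += 1
    return CohortSummary(
        n_total=len(reports),
        n_solved=n_solved,
        per_subgroup=per_subgroup,
        mode_counts=mode_distribution(reports, mosaic_as),
        consang=consanguinity_stats(reports, mosaic_as),
        sex_breakdown=sex_breakdown,
        dual_diagnosis_count=sum(1 for r in reports if r.dual_diagnosis),
    )


@dataclass
class ReanalysisUplift:
    n_families: int
    n_unsolved_before: int
    n_newly_solved: int

    def uplift_percent(self, decimals: int = 0):
        return percent(self.n_newly_solved, self.n_families, decimals)


def reanalysis_uplift(
    before: Sequence[FamilyReport], after: Sequence[FamilyReport]
) -> ReanalysisUplift:
    """Families unsolved before and solved after (e.g., a panel update)."""
    before_by_id = {r.family_id: r for r in before}
    after_by_id = {r.family_id: r for r in after}
    if set(before_by_id) != set(after_by_id):
        raise ValueError("before/after cohorts contain different family ids")
    unsolved = [fid for fid, r in before_by_id.items() if not r.solved]
    newly = sum(1 for fid in unsolved if after_by_id[fid].solved)
    return ReanalysisUplift(
        n_families=len(before_by_id),
        n_unsolved_before=len(unsolved),
        n_newly_solved=newly,
    )


def male_xl_maternal_share(
    reports: Sequence[FamilyReport],
    mosaic_as: MosaicConvention = MosaicConvention.AD_INHERITED,
) -> tuple[int, int]:
    """(maternal-inherited, total) X-linked diagnoses among solved males."""
    maternal = total = 0
    xl_modes = {InheritanceMode.XL_MATERNAL, InheritanceMode.XL_DENOVO}
    for r in reports:
        if not r.solved or r.proband_sex is not Sex.MALE:
            continue
        modes = _family_modes(r, mosaic_as) & xl_modes
        if not modes:
            continue
        total += 1
        if InheritanceMode.XL_MATERNAL in modes:
            maternal += 1
    return maternal, total


def summary_tables(summary: CohortSummary) -> dict[str, str]:
    """Render the summary as a bundle of TSV tables (deterministic)."""
    overall = [
        "metric\tvalue",
        f"n_total\t{summary.n_total}",
        f"n_solved\t{summary.n_solved}",
        f"yield_overall_percent\t{summary.yield_overall(0)}",
        f"dual_diagnosis_count\t{summary.dual_diagnosis_count}",
    ]
    sub = ["subgroup\tn\tn_solved\tyield_percent"]
    for g in PhenotypeSubgroup:
        row = summary.per_subgroup[g]
        y = row.yield_percent(1) if row.n else ""
        sub.append(f"{g.value}\t{row.n}\t{row.n_solved}\t{y}")
    modes = ["mode\tcount\tpercent_of_solved"]
    for m in InheritanceMode:
        if m is InheritanceMode.NONE:
            continue
        c = summary.mode_counts.get(m, 0)
        p = summary.mode_percent(m, 0) if summary.n_solved else ""
        modes.append(f"{m.value}\t{c}\t{p}")
    consang_lines = ["metric\tvalue"]
    if summary.consang is not None:
        cs = summary.consang
        consang_lines += [
            f"n_consanguineous\t{cs.n_consang}",
            f"n_consanguineous_solved\t{cs.n_consang_solved}",
            f"yield_percent\t{cs.yield_percent(0)}",
            f"n_hom_total\t{cs.n_hom_total}",
            f"n_hom_in_consanguineous\t{cs.n_hom_in_consang}",
            f"hom_share_percent\t{cs.hom_share_percent(0) if cs.n_hom_total else ''}",
        ]
    return {
        "summary_overall.tsv": "\n".join(overall) + "\n",
        "summary_subgroups.tsv": "\n".join(sub) + "\n",
        "summary_modes.tsv": "\n".join(modes) + "\n",
        "summary_consanguinity.tsv": "\n".join(consang_lines) + "\n",
    }


def summary_json(summary: CohortSummary) -> dict:
    return {
        "n_total": summary.n_total,
        "n_solved": summary.n_solved,
        "yield_overall_percent": summary.yield_overall(0),
        "per_subgroup": {
            g.value: {
                "n": row.n,
                "n_solved": row.n_solved,
                "yield_percent": row.yield_percent(1) if row.n else None,
            }
            for g, row in summary.per_subgroup.items()
        },
        "mode_counts": {m.value: c for m, c in sorted(summary.mode_counts.items(), key=lambda kv: kv[0].value)},
        "sex_breakdown": {
            s.value: {"n": row.n, "n_solved": row.n_solved}
            for s, row in summary.sex_breakdown.items()
        },
        "consanguinity": None
        if summary.consang is None
        else {
            "n_consanguineous": summary.consang.n_consang,
            "n_solved": summary.consang.n_consang_solved,
            "yield_percent": summary.consang.yield_percent(0),
            "n_hom_total": summary.consang.n_hom_total,
            "n_hom_in_consanguineous": summary.consang.n_hom_in_consang,
        },
        "dual_diagnosis_count": summary.dual_diagnosis_count,
    }
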
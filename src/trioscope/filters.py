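"""Variant-level filters with an auditable trail.

Three filters gate a variant into inheritance classification: population
allele frequency strictly below a threshold (default 1%), a consequence
class affecting exons or exon-intron boundaries, and membership of the
gene in the analysis panel.  All three are always evaluated so the trail
records every outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .variants import AnnotatedVariant, REPORTABLE_CONSEQUENCES

DEFAULT_AF_THRESHOLD = 0.01


@dataclass
class FilterTrail:
    frequency_pass: bool
    region_pass: bool
    panel_pass: bool
    reasons: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.frequency_pass and self.region_pass and self.panel_pass


def frequency_filter(v: AnnotatedVariant, threshold: float = DEFAULT_AF_THRESHOLD) -> bool:
    """True iff population AF is strictly below ``threshold``."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0,1], got {threshold}")
    return v.pop_af < threshold


def region_filter(v: AnnotatedVariant) -> bool:
    """True iff the consequence class affects exons or exon-intron boundaries."""
    return v.consequence in REPORTABLE_CONSEQUENCES


def panel_filter(v: AnnotatedVariant, panel: frozenset[str] | set[str]) -> bool:
    """True iff the gene symbol is in the panel (case-insensitive exact match)."""
    if not panel:
        raise ValueError("gene panel must be non-empty")
    return v.gene.upper() in {g.upper() for g in panel}


def apply_filters(
    v: AnnotatedVariant,
    panel: frozenset[str] | set[str],
    threshold: float = DEFAULT_AF_THRESHOLD,
) -> FilterTrail:
    """Evaluate all three filters (no short-circuit) and record reasons."""
    freq_ok = frequency_filter(v, threshold)
    region_ok = region_filter(v)
    panel_ok = panel_filter(v, panel)
    reasons: list[str] = []
    if not freq_ok:
        reasons.append(f"pop_af {v.pop_af:.4g} >= {threshold:g}")
    if not region_ok:
        reasons.append(f"consequence {v.consequence.value} outside exon/boundary classes")
    if not panel_ok:
        reasons.append(f"gene {v.gene} not in panel")
    return FilterTrail(frequency_pass=freq_ok, region_pass=region_ok, panel_pass=panel_ok, reasons=reasons)


def filter_trail_tsv_row(family_id: str, v: AnnotatedVariant, trail: FilterTrail) -> str:
    return "\t".join(
        [
            family_id,
            v.chrom,
            str(v.pos),
            v.ref,
            v.alt,
            v.gene,
            str(int(trail.frequency_pass)),
            str(int(trail.region_pass)),
            str(int(trail.panel_pass)),
        ]
    )


FILTER_TSV_HEADER = "family_id\tchrom\tpos\tref\talt\tgene\tfrequency_pass\tregion_pass\tpanel_pass"
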
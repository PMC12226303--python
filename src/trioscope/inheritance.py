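"""Trio inheritance-pattern classification.

Classifies each filtered variant (or variant pair) into an inheritance
mode: autosomal dominant de novo, X-linked de novo, autosomal recessive
homozygous or compound heterozygous, X-linked from a carrier mother,
inherited autosomal dominant (ClinVar pathogenic-only highlighting), and
parental-mosaic refinements of de novo candidates based on low-fraction
alternate reads in a parent.

Sites on chrX inside the pseudoautosomal regions are classified with the
autosomal rules.  Sites with a missing parental genotype are ineligible
for de novo and compound-het calls (conservative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from itertools import product
from typing import Iterable, Sequence

from .ped import Sex, TrioFamily
from .variants import AnnotatedVariant, GenotypeCall, chrom_sort_key, compute_vaf

log = logging.getLogger(__name__)


class InheritanceMode(str, Enum):
    AD_DENOVO = "AD_DENOVO"
    XL_DENOVO = "XL_DENOVO"
    AR_HOM = "AR_HOM"
    AR_COMPHET = "AR_COMPHET"
    XL_MATERNAL = "XL_MATERNAL"
    AD_INHERITED = "AD_INHERITED"
    PARENTAL_MOSAIC_MATERNAL = "PARENTAL_MOSAIC_MATERNAL"
    PARENTAL_MOSAIC_PATERNAL = "PARENTAL_MOSAIC_PATERNAL"
    NONE = "NONE"


class TransmittingParent(str, Enum):
    MOTHER = "mother"
    FATHER = "father"
    BOTH = "both"
    NONE = "none"


@dataclass(frozen=True)
class InheritanceCall:
    mode: InheritanceMode
    variant_ids: tuple[str, ...]
    transmitting_parent: TransmittingParent = TransmittingParent.NONE
    parental_alt_fraction: float | None = None
    notes: str = ""


@dataclass(frozen=True)
class DeNovoParams:
    """Read-support thresholds for de novo and parental-mosaic calling.

    Parent alternate-read ranges must abut: reads up to
    ``parent_max_alt_reads_for_denovo`` are compatible with a clean de novo,
    and the mosaic window starts at ``mosaic_min_alt_reads`` which may not
    leave a gap above that bound.
    """

    min_proband_alt_reads: int = 4
    min_depth: int = 10
    min_gq: int = 20
    parent_max_alt_reads_for_denovo: int = 1
    mosaic_min_alt_reads: int = 2
    mosaic_max_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.mosaic_min_alt_reads > self.parent_max_alt_reads_for_denovo + 1:
            raise ValueError(
                "mosaic_min_alt_reads leaves a gap above parent_max_alt_reads_for_denovo"
            )
        if not 0.0 < self.mosaic_max_fraction < 0.5:
            raise ValueError("mosaic_max_fraction must lie in (0, 0.5)")


def _child_support_ok(call: GenotypeCall, params: DeNovoParams) -> bool:
    return (
        call.total_depth >= params.min_depth
        and call.alt_depth >= params.min_proband_alt_reads
        and call.genotype_quality >= params.min_gq
    )


def _mosaic_evidence(call: GenotypeCall, params: DeNovoParams) -> str | None:
    """For a hom-ref parent call with alt reads above the de novo bound:
    'mosaic', 'likely_het', or None (clean)."""
    if call.alt_depth <= params.parent_max_alt_reads_for_denovo:
        return None
    vaf = compute_vaf(call)
    if vaf is not None and call.alt_depth >= params.mosaic_min_alt_reads and vaf <= params.mosaic_max_fraction:
        return "mosaic"
    return "likely_het"


def detect_parental_mosaic(
    v: AnnotatedVariant, fam: TrioFamily, params: DeNovoParams
) -> InheritanceCall:
    """Refine a de novo candidate (both parents called hom-ref) by parental reads.

    A parent whose hom-ref call carries >= ``mosaic_min_alt_reads`` alternate
    reads at a fraction <= ``mosaic_max_fraction`` is flagged mosaic; a
    fraction above the bound implies a missed heterozygote and voids the
    de novo call.  If both parents qualify, the higher-fraction parent is
    reported with a note on the other.
    """
    mom = v.call(fam.mother.sample_id)
    dad = v.call(fam.father.sample_id)
    evidence = {
        TransmittingParent.MOTHER: _mosaic_evidence(mom, params),
        TransmittingParent.FATHER: _mosaic_evidence(dad, params),
    }
    vid = (v.variant_id,)
    if "likely_het" in evidence.values():
        who = [p.value for p, e in evidence.items() if e == "likely_het"]
        return InheritanceCall(
            mode=InheritanceMode.NONE,
            variant_ids=vid,
            notes=f"parent_likely_het:{','.join(who)}",
        )
    mosaics = [p for p, e in evidence.items() if e == "mosaic"]
    if not mosaics:
        return InheritanceCall(
            mode=InheritanceMode.AD_DENOVO,
            variant_ids=vid,
            notes="possible_germline_mosaicism_not_excluded",
        )
    fractions = {
        TransmittingParent.MOTHER: compute_vaf(mom) or 0.0,
        TransmittingParent.FATHER: compute_vaf(dad) or 0.0,
    }
    best = max(mosaics, key=lambda p: fractions[p])
    mode = (
        InheritanceMode.PARENTAL_MOSAIC_MATERNAL
        if best is TransmittingParent.MOTHER
        else InheritanceMode.PARENTAL_MOSAIC_PATERNAL
    )
    notes = ""
    if len(mosaics) == 2:
        other = (set(mosaics) - {best}).pop()
        notes = f"both_parents_mosaic_evidence:{other.value}={fractions[other]:.3f}"
    return InheritanceCall(
        mode=mode,
        variant_ids=vid,
        transmitting_parent=best,
        parental_alt_fraction=fractions[best],
        notes=notes,
    )


def _none(v: AnnotatedVariant, note: str, parent: TransmittingParent = TransmittingParent.NONE) -> InheritanceCall:
    return InheritanceCall(
        mode=InheritanceMode.NONE,
        variant_ids=(v.variant_id,),
        transmitting_parent=parent,
        notes=note,
    )


def _classify_autosomal(
    v: AnnotatedVariant,
    fam: TrioFamily,
    child: GenotypeCall,
    mom: GenotypeCall,
    dad: GenotypeCall,
    params: DeNovoParams,
) -> InheritanceCall:
    c, m, f = child.alt_count, mom.alt_count, dad.alt_count
    vid = (v.variant_id,)
    # Mendelian impossibilities given diploid transmission
    if (c == 2 and (m == 0 or f == 0)) or (c == 0 and (m == 2 or f == 2)) or (
        c == 1 and m == 2 and f == 2
    ):
        return _none(v, "mendelian_error")
    if c == 0:
        return _none(v, "no_alt_in_proband")
    if c == 1:
        if m == 0 and f == 0:
            if not _child_support_ok(child, params):
                return _none(v, "denovo_low_support")
            return detect_parental_mosaic(v, fam, params)
        # inherited het: determine the certain transmitting parent if any
        maternal = m is not None and m >= 1
        paternal = f is not None and f >= 1
        if m == 2:  # hom mother must transmit alt; father gave ref
            return _none(v, "inherited_single_parent", TransmittingParent.MOTHER)
        if f == 2:
            return _none(v, "inherited_single_parent", TransmittingParent.FATHER)
        if maternal and paternal:
            return _none(v, "inherited_ambiguous", TransmittingParent.BOTH)
        if maternal:
            return _none(v, "inherited_single_parent", TransmittingParent.MOTHER)
        return _none(v, "inherited_single_parent", TransmittingParent.FATHER)
    # c == 2
    if m == 1 and f == 1:
        return InheritanceCall(
            mode=InheritanceMode.AR_HOM,
            variant_ids=vid,
            transmitting_parent=TransmittingParent.BOTH,
        )
    return _none(v, "inherited_homozygous_carrier_parent")


def _classify_x_male(
    v: AnnotatedVariant,
    fam: TrioFamily,
    child: GenotypeCall,
    mom: GenotypeCall,
    dad: GenotypeCall,
    params: DeNovoParams,
) -> InheritanceCall:
    vid = (v.variant_id,)
    if child.ploidy == 2 and child.is_het:
        return _none(v, "possible_mosaic_or_artifact")
    c = 1 if child.has_alt else 0
    m = mom.alt_count
    note_father = ";father_carries_alt" if dad.has_alt else ""
    if c == 0:
        if m == 2:
            return _none(v, "mendelian_error")
        return _none(v, "no_alt_in_proband")
    # hemizygous alt son: the X came from the mother
    if m == 0:
        if not _child_support_ok(child, params):
            return _none(v, "denovo_low_support")
        ev = _mosaic_evidence(mom, params)
        if ev == "likely_het":
            return _none(v, "parent_likely_het:mother")
        if ev == "mosaic":
            return InheritanceCall(
                mode=InheritanceMode.PARENTAL_MOSAIC_MATERNAL,
                variant_ids=vid,
                transmitting_parent=TransmittingParent.MOTHER,
                parental_alt_fraction=compute_vaf(mom),
                notes="x_linked" + note_father,
            )
        return InheritanceCall(
            mode=InheritanceMode.XL_DENOVO,
            variant_ids=vid,
            notes=note_father.lstrip(";"),
        )
    if m == 1:
        return InheritanceCall(
            mode=InheritanceMode.XL_MATERNAL,
            variant_ids=vid,
            transmitting_parent=TransmittingParent.MOTHER,
            notes=note_father.lstrip(";"),
        )
    return _none(v, "maternal_hom_transmission", TransmittingParent.MOTHER)


def _classify_x_female(
    v: AnnotatedVariant,
    fam: TrioFamily,
    child: GenotypeCall,
    mom: GenotypeCall,
    dad: GenotypeCall,
    params: DeNovoParams,
    allow_female_xl_carrier: bool,
) -> InheritanceCall:
    vid = (v.variant_id,)
    c = child.alt_count
    m = mom.alt_count
    f = 1 if dad.has_alt else 0  # father hemizygous on X
    if (c == 2 and (m == 0 or f == 0)) or (c == 0 and (m == 2 or f == 1)) or (
        c == 1 and m == 2 and f == 1
    ):
        return _none(v, "mendelian_error")
    if c == 0:
        return _none(v, "no_alt_in_proband")
    if c == 1:
        if m == 0 and f == 0:
            if not _child_support_ok(child, params):
                return _none(v, "denovo_low_support")
            ev = _mosaic_evidence(mom, params)
            if ev == "likely_het":
                return _none(v, "parent_likely_het:mother")
            if ev == "mosaic":
                return InheritanceCall(
                    mode=InheritanceMode.PARENTAL_MOSAIC_MATERNAL,
                    variant_ids=vid,
                    transmitting_parent=TransmittingParent.MOTHER,
                    parental_alt_fraction=compute_vaf(mom),
                    notes="x_linked",
                )
            return InheritanceCall(mode=InheritanceMode.XL_DENOVO, variant_ids=vid)
        if f == 1 and m == 0:
            return _none(v, "inherited_paternal_x", TransmittingParent.FATHER)
        if f == 1 and m == 1:
            return _none(v, "inherited_ambiguous", TransmittingParent.BOTH)
        # maternal transmission certain (m >= 1, f == 0)
        if allow_female_xl_carrier and m == 1:
            return InheritanceCall(
                mode=InheritanceMode.XL_MATERNAL,
                variant_ids=vid,
                transmitting_parent=TransmittingParent.MOTHER,
                notes="female_carrier_exception",
            )
        return _none(v, "xl_female_carrier", TransmittingParent.MOTHER)
    # c == 2: father is a hemizygous (affected) carrier
    return _none(v, "xl_hom_father_hemizygous_alt")


def classify_site(
    v: AnnotatedVariant,
    fam: TrioFamily,
    params: DeNovoParams | None = None,
    allow_female_xl_carrier: bool = False,
) -> InheritanceCall:
    """Classify one filtered site in a trio.

    Returns an :class:`InheritanceCall`; sites classified ``NONE`` carry a
    note explaining why (Mendelian error, inherited single-parent het that
    remains a compound-het / highlighting candidate, low read support, ...).
    """
    params = params or DeNovoParams()
    if fam.mother is None or fam.father is None:
        return _none(v, "missing_parent_sample")
    child = v.call(fam.proband.sample_id)
    mom = v.call(fam.mother.sample_id)
    dad = v.call(fam.father.sample_id)
    if child.is_missing:
        return _none(v, "missing_proband_genotype")
    if mom.is_missing or dad.is_missing:
        return _none(v, "missing_parental_genotype")
    if v.is_x_nonpar:
        if fam.proband.sex is Sex.MALE:
            return _classify_x_male(v, fam, child, mom, dad, params)
        return _classify_x_female(v, fam, child, mom, dad, params, allow_female_xl_carrier)
    return _classify_autosomal(v, fam, child, mom, dad, params)


def _comphet_side(call: InheritanceCall) -> TransmittingParent | None:
    """Transmission side a NONE-classified site contributes to comp-het pairing."""
    if call.mode is not InheritanceMode.NONE or call.notes != "inherited_single_parent":
        return None
    if call.transmitting_parent in (TransmittingParent.MOTHER, TransmittingParent.FATHER):
        return call.transmitting_parent
    return None


def find_compound_hets(
    variants_in_gene: Sequence[AnnotatedVariant],
    fam: TrioFamily,
    params: DeNovoParams | None = None,
) -> list[InheritanceCall]:
    """Enumerate trans pairs of proband-het variants in one gene.

    A pair qualifies when one member is transmitted only by the mother and
    the other only by the father; cis pairs (same parent) and ambiguous
    sites (both parents carry the allele) are rejected.  With more than two
    candidates, every valid trans pair is reported.
    """
    params = params or DeNovoParams()
    genes = {v.gene for v in variants_in_gene}
    if len(genes) > 1:
        raise ValueError(f"find_compound_hets expects one gene, got {sorted(genes)}")
    maternal: list[AnnotatedVariant] = []
    paternal: list[AnnotatedVariant] = []
    for v in variants_in_gene:
        child = v.call(fam.proband.sample_id)
        if not child.is_het:
            continue
        call = classify_site(v, fam, params)
        if call.mode is InheritanceMode.NONE and "missing" in call.notes:
            log.info("comp-het pairing skips %s: %s", v.variant_id, call.notes)
            continue
        side = _comphet_side(call)
        if side is TransmittingParent.MOTHER:
            maternal.append(v)
        elif side is TransmittingParent.FATHER:
            paternal.append(v)
    out: list[InheritanceCall] = []
    for a, b in product(maternal, paternal):
        ids = tuple(sorted((a.variant_id, b.variant_id)))
        out.append(
            InheritanceCall(
                mode=InheritanceMode.AR_COMPHET,
                variant_ids=ids,
                transmitting_parent=TransmittingParent.BOTH,
            )
        )
    return out


def highlight_clinvar(v: AnnotatedVariant, fam: TrioFamily) -> InheritanceCall | None:
    """Promote an inherited het to AD_INHERITED when ClinVar-pathogenic-only.

    Applies to sites het in the proband and carried by exactly one parent;
    anything else (or a non-pathogenic-only ClinVar status) returns None and
    the inherited variant is dismissed.
    """
    from .variants import ClinvarStatus

    if fam.mother is None or fam.father is None:
        return None
    child = v.call(fam.proband.sample_id)
    mom = v.call(fam.mother.sample_id)
    dad = v.call(fam.father.sample_id)
    if not child.is_het or mom.is_missing or dad.is_missing:
        return None
    if mom.has_alt == dad.has_alt:
        return None
    if v.clinvar is not ClinvarStatus.PATHOGENIC_ONLY:
        return None
    parent = TransmittingParent.MOTHER if mom.has_alt else TransmittingParent.FATHER
    return InheritanceCall(
        mode=InheritanceMode.AD_INHERITED,
        variant_ids=(v.variant_id,),
        transmitting_parent=parent,
        notes="clinvar_pathogenic_only",
    )


_MODE_ORDER = {m: i for i, m in enumerate(InheritanceMode)}


def _call_sort_key(call: InheritanceCall):
    chrom, pos = call.variant_ids[0].split(":")[:2]
    return (chrom_sort_key(chrom), int(pos), _MODE_ORDER[call.mode], call.variant_ids)


def call_family(
    variants: Sequence[AnnotatedVariant],
    fam: TrioFamily,
    params: DeNovoParams | None = None,
    allow_female_xl_carrier: bool = False,
) -> list[InheritanceCall]:
    """Run site classification, compound-het pairing, and ClinVar highlighting
    over all filtered variants of one family.

    Returns deduplicated calls (modes other than NONE) in deterministic
    (chrom, pos, mode) order.  Compound-het members are not additionally
    reported through the ClinVar highlight.
    """
    params = params or DeNovoParams()
    calls: list[InheritanceCall] = []
    single_parent_hets: list[tuple[AnnotatedVariant, InheritanceCall]] = []
    for v in variants:
        call = classify_site(v, fam, params, allow_female_xl_carrier)
        if call.mode is not InheritanceMode.NONE:
            calls.append(call)
        elif call.notes == "mendelian_error":
            log.info("family %s: mendelian error at %s", fam.family_id, v.variant_id)
        elif _comphet_side(call) is not None:
            single_parent_hets.append((v, call))

    # compound hets: autosomal (and PAR) genes only
    by_gene: dict[str, list[AnnotatedVariant]] = {}
    for v, _ in single_parent_hets:
        if not v.is_x_nonpar:
            by_gene.setdefault(v.gene, []).append(v)
    comphet_members: set[str] = set()
    for gene in sorted(by_gene):
        group = by_gene[gene]
        if len(group) < 2:
            continue
        for ch in find_compound_hets(group, fam, params):
            calls.append(ch)
            comphet_members.update(ch.variant_ids)

    for v, _ in single_parent_hets:
        if v.variant_id in comphet_members:
            continue
        hl = highlight_clinvar(v, fam)
        if hl is not None:
            calls.append(hl)

    unique = {(c.mode, c.variant_ids): c for c in calls}
    return sorted(unique.values(), key=_call_sort_key)
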
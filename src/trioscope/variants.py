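"""Annotated-variant data model and annotated-VCF dialect I/O.

The pipeline consumes pre-annotated per-family VCFs (VCF 4.2) carrying four
INFO keys (``GENE``, ``POP_AF``, ``CSQ_CLASS``, ``CLNSIG``) and the standard
``GT``/``AD``/``DP``/``GQ`` FORMAT fields.  Multi-allelic records are split
on read into one :class:`AnnotatedVariant` per alternate allele, with allele
depths re-indexed per alternate.

Coordinates are VCF-native (1-based, fully closed).  GRCh37 chrX
pseudoautosomal boundaries are built in; sites inside PAR1/PAR2 are treated
as autosomal by the inheritance logic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from cyvcf2 import VCF

log = logging.getLogger(__name__)

# GRCh37 chrX pseudoautosomal regions, 1-based inclusive.
PAR1 = (60_001, 2_699_520)
PAR2 = (154_931_044, 155_260_560)

_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25}


class VcfDialectError(ValueError):
    """Raised when an input VCF violates the annotated dialect contract."""


class ConsequenceClass(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_REGION = "splice_region"
    SYNONYMOUS = "synonymous"
    START_OR_STOP_ALTERING = "start_or_stop_altering"
    INTRONIC_DEEP = "intronic_deep"
    OTHER = "other"


#: Classes affecting exons or exon-intron boundaries (pass the region filter).
REPORTABLE_CONSEQUENCES: frozenset[ConsequenceClass] = frozenset(
    {
        ConsequenceClass.MISSENSE,
        ConsequenceClass.NONSENSE,
        ConsequenceClass.FRAMESHIFT,
        ConsequenceClass.INFRAME_INDEL,
        ConsequenceClass.SPLICE_REGION,
        ConsequenceClass.START_OR_STOP_ALTERING,
    }
)


class ClinvarStatus(str, Enum):
    PATHOGENIC_ONLY = "pathogenic_only"
    OTHER_OR_CONFLICTING = "other_or_conflicting"
    ABSENT = "absent"


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call at one (split) site.

    ``alleles`` holds allele indices in {0,1} after normalization: a pair
    for diploid calls, a single index for hemizygous calls, ``None`` for a
    missing call.
    """

    alleles: tuple[int, ...] | None
    ref_depth: int = 0
    alt_depth: int = 0
    total_depth: int = 0
    genotype_quality: int = 0

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    @property
    def ploidy(self) -> int:
        return 0 if self.alleles is None else len(self.alleles)

    @property
    def alt_count(self) -> int | None:
        """Number of alternate alleles carried; None for a missing call."""
        if self.alleles is None:
            return None
        return sum(1 for a in self.alleles if a == 1)

    @property
    def is_het(self) -> bool:
        return self.alleles is not None and len(self.alleles) == 2 and self.alt_count == 1

    @property
    def is_hom_ref(self) -> bool:
        return self.alleles is not None and all(a == 0 for a in self.alleles)

    @property
    def is_hom_alt(self) -> bool:
        return self.alleles is not None and len(self.alleles) == 2 and all(a == 1 for a in self.alleles)

    @property
    def has_alt(self) -> bool:
        return self.alleles is not None and any(a == 1 for a in self.alleles)


MISSING_CALL = GenotypeCall(alleles=None)


def compute_vaf(call: GenotypeCall) -> float | None:
    """Variant allele fraction alt/(ref+alt); ``None`` at zero depth."""
    denom = call.ref_depth + call.alt_depth
    if denom == 0:
        return None
    return call.alt_depth / denom


@dataclass
class AnnotatedVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: ConsequenceClass
    pop_af: float
    clinvar: ClinvarStatus
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not 0.0 <= self.pop_af <= 1.0:
            raise ValueError(f"pop_af must be in [0,1], got {self.pop_af}")

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def is_x_nonpar(self) -> bool:
        """True on chrX outside the pseudoautosomal regions."""
        if self.chrom not in ("X", "chrX"):
            return False
        return not (PAR1[0] <= self.pos <= PAR1[1] or PAR2[0] <= self.pos <= PAR2[1])

    def call(self, sample_id: str) -> GenotypeCall:
        return self.genotypes.get(sample_id, MISSING_CALL)


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    c = chrom.removeprefix("chr")
    return (_CHROM_ORDER.get(c, 99), c)


def _parse_clnsig(value: str | None) -> ClinvarStatus:
    if value is None:
        return ClinvarStatus.ABSENT
    if value == "pathogenic_only":
        return ClinvarStatus.PATHOGENIC_ONLY
    return ClinvarStatus.OTHER_OR_CONFLICTING


def _int_or_zero(x) -> int:
    try:
        v = int(x)
    except (TypeError, ValueError):
        return 0
    # htslib missing-value sentinels come through as large negatives
    return v if v >= 0 else 0


def read_annotated_vcf(path: str | Path, family) -> list[AnnotatedVariant]:
    """Read a per-family annotated VCF into split, sorted variant records.

    ``family`` is a :class:`trioscope.ped.TrioFamily`; every family sample
    must be present in the VCF header (hard error otherwise).  Multi-allelic
    records are split per alternate allele with AD projected onto
    (ref, this-alt); genotype alleles pointing at other alternates are
    normalized to 0.  Missing ``POP_AF`` reads as 0.0 and missing ``CLNSIG``
    as absent.
    """
    vcf = VCF(str(path))
    header_samples = list(vcf.samples)
    for sid in family.sample_ids:
        if sid not in header_samples:
            raise VcfDialectError(f"{path}: pedigree sample {sid!r} absent from VCF header")

    out: list[AnnotatedVariant] = []
    for rec in vcf:
        gene = rec.INFO.get("GENE")
        if gene is None:
            log.warning("%s:%s missing GENE annotation; gene set to ''", rec.CHROM, rec.POS)
            gene = ""
        pop_af = rec.INFO.get("POP_AF")
        pop_af = float(pop_af) if pop_af is not None else 0.0
        csq_raw = rec.INFO.get("CSQ_CLASS")
        try:
            consequence = ConsequenceClass(csq_raw) if csq_raw is not None else ConsequenceClass.OTHER
        except ValueError:
            log.warning("%s:%s unknown CSQ_CLASS %r; treated as 'other'", rec.CHROM, rec.POS, csq_raw)
            consequence = ConsequenceClass.OTHER
        clinvar = _parse_clnsig(rec.INFO.get("CLNSIG"))

        genotypes_raw = rec.genotypes  # per sample: [a0, (a1,) phased]
        ad = rec.format("AD")
        dp = rec.format("DP")
        gq = rec.format("GQ")
        n_alt = len(rec.ALT)

        for alt_idx, alt in enumerate(rec.ALT):
            allele_of_interest = alt_idx + 1
            genos: dict[str, GenotypeCall] = {}
            for s_idx, sid in enumerate(header_samples):
                raw = genotypes_raw[s_idx]
                allele_fields = raw[:-1]  # last element is the phased flag
                if any(a < 0 for a in allele_fields):
                    genos[sid] = MISSING_CALL
                    continue
                alleles = tuple(1 if a == allele_of_interest else 0 for a in allele_fields)
                ref_d = _int_or_zero(ad[s_idx][0]) if ad is not None else 0
                alt_d = (
                    _int_or_zero(ad[s_idx][allele_of_interest])
                    if ad is not None and ad.shape[1] > allele_of_interest
                    else 0
                )
                total = _int_or_zero(dp[s_idx][0]) if dp is not None else ref_d + alt_d
                genos[sid] = GenotypeCall(
                    alleles=alleles,
                    ref_depth=ref_d,
                    alt_depth=alt_d,
                    total_depth=max(total, ref_d + alt_d),
                    genotype_quality=_int_or_zero(gq[s_idx][0]) if gq is not None else 0,
                )
            out.append(
                AnnotatedVariant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    gene=str(gene),
                    consequence=consequence,
                    pop_af=pop_af,
                    clinvar=clinvar,
                    genotypes=genos,
                )
            )
    vcf.close()
    out.sort(key=lambda v: (chrom_sort_key(v.chrom), v.pos, v.ref, v.alt))
    return out


_VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##INFO=<ID=POP_AF,Number=1,Type=Float,Description="Population allele frequency">',
    '##INFO=<ID=CSQ_CLASS,Number=1,Type=String,Description="Consequence class">',
    '##INFO=<ID=CLNSIG,Number=1,Type=String,Description="ClinVar status: pathogenic_only or other">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
]


def _format_call(call: GenotypeCall) -> str:
    if call.alleles is None:
        return "./.:.:.:."
    gt = "/".join(str(a) for a in call.alleles)
    return f"{gt}:{call.ref_depth},{call.alt_depth}:{call.total_depth}:{call.genotype_quality}"


def write_annotated_vcf(
    path: str | Path,
    variants: Sequence[AnnotatedVariant],
    sample_ids: Sequence[str],
    contigs: dict[str, int] | None = None,
) -> None:
    """Write biallelic records in the annotated dialect (uncompressed text)."""
    lines = list(_VCF_HEADER_LINES)
    if contigs:
        for name, length in contigs.items():
            lines.insert(1, f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids))
    ordered = sorted(variants, key=lambda v: (chrom_sort_key(v.chrom), v.pos, v.ref, v.alt))
    for v in ordered:
        info = (
            f"GENE={v.gene};POP_AF={v.pop_af:.6g};CSQ_CLASS={v.consequence.value}"
        )
        if v.clinvar is not ClinvarStatus.ABSENT:
            tag = "pathogenic_only" if v.clinvar is ClinvarStatus.PATHOGENIC_ONLY else "other"
            info += f";CLNSIG={tag}"
        calls = "\t".join(_format_call(v.call(s)) for s in sample_ids)
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\tGT:AD:DP:GQ\t{calls}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_gene_panel(path: str | Path) -> frozenset[str]:
    """Read a gene-panel file: one symbol per line, '#' comments allowed."""
    genes: set[str] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line:
                genes.add(line.upper())
    return frozenset(genes)
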
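from __future__ import annotations

import pytest

from trioscope.filters import FilterTrail
from trioscope.inheritance import InheritanceCall, InheritanceMode, TransmittingParent
from trioscope.ped import Affection, Individual, PhenotypeSubgroup, Sex, TrioFamily
from trioscope.reports import AcmgClass, CandidateVariant, FamilyReport
from trioscope.variants import (
    AnnotatedVariant,
    ClinvarStatus,
    ConsequenceClass,
    GenotypeCall,
    MISSING_CALL,
)


def make_trio(
    family_id: str = "FAM1",
    sex: Sex = Sex.MALE,
    consanguineous: bool = False,
    fetus: bool = False,
    hpo_terms=frozenset(),
) -> TrioFamily:
    child = Individual(
        f"{family_id}_child", family_id, f"{family_id}_father", f"{family_id}_mother",
        sex, Affection.AFFECTED,
    )
    father = Individual(f"{family_id}_father", family_id, None, None, Sex.MALE, Affection.UNAFFECTED)
    mother = Individual(f"{family_id}_mother", family_id, None, None, Sex.FEMALE, Affection.UNAFFECTED)
    return TrioFamily(
        family_id=family_id, proband=child, mother=mother, father=father,
        consanguineous=consanguineous, fetus=fetus, hpo_terms=frozenset(hpo_terms),
    )


def gt(genotype: str, ad: tuple[int, int] | None = None, dp: int | None = None, gq: int = 99) -> GenotypeCall:
    """Build a GenotypeCall from a GT string with sensible clean-read defaults."""
    if genotype in ("./.", "."):
        return MISSING_CALL
    alleles = tuple(int(a) for a in genotype.replace("|", "/").split("/"))
    if ad is None:
        frac = sum(alleles) / len(alleles)
        ad = (30 - round(30 * frac), round(30 * frac))
    total = dp if dp is not None else ad[0] + ad[1]
    return GenotypeCall(
        alleles=alleles, ref_depth=ad[0], alt_depth=ad[1], total_depth=total, genotype_quality=gq
    )


def make_variant(
    fam: TrioFamily,
    chrom: str = "1",
    pos: int = 1000,
    gene: str = "GENE1",
    child: str = "0/1",
    mother: str = "0/0",
    father: str = "0/0",
    child_ad=None,
    mother_ad=None,
    father_ad=None,
    pop_af: float = 0.001,
    consequence: ConsequenceClass = ConsequenceClass.MISSENSE,
    clinvar: ClinvarStatus = ClinvarStatus.ABSENT,
    ref: str = "A",
    alt: str = "T",
) -> AnnotatedVariant:
    return AnnotatedVariant(
        chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
        consequence=consequence, pop_af=pop_af, clinvar=clinvar,
        genotypes={
            fam.proband.sample_id: gt(child, child_ad),
            fam.mother.sample_id: gt(mother, mother_ad),
            fam.father.sample_id: gt(father, father_ad),
        },
    )


_GENE_COUNTER = [0]


def report_fixture(
    family_id: str,
    subgroup: PhenotypeSubgroup = PhenotypeSubgroup.NDD_SYNDROME,
    modes: tuple[InheritanceMode, ...] = (),
    consanguineous: bool = False,
    sex: Sex = Sex.MALE,
    solved: bool | None = None,
) -> FamilyReport:
    """Build a FamilyReport with one reportable candidate per given mode."""
    candidates = []
    genes = set()
    for i, mode in enumerate(modes):
        _GENE_COUNTER[0] += 1
        gene = f"G{_GENE_COUNTER[0]:05d}"
        genes.add(gene)
        pos = 1000 + i
        variant = AnnotatedVariant(
            chrom="1", pos=pos, ref="A", alt="T", gene=gene,
            consequence=ConsequenceClass.MISSENSE, pop_af=0.0, clinvar=ClinvarStatus.ABSENT,
        )
        call = InheritanceCall(
            mode=mode, variant_ids=(variant.variant_id,),
            transmitting_parent=TransmittingParent.NONE,
        )
        candidates.append(
            CandidateVariant(
                variant=variant, call=call, trail=None, highlight=False,
                acmg_class=AcmgClass.CLASS4, phenotype_concordant=False,
                reportable=True,
            )
        )
    is_solved = bool(modes) if solved is None else solved
    return FamilyReport(
        family_id=family_id, subgroup=subgroup, consanguineous=consanguineous,
        proband_sex=sex, candidates=candidates, solved=is_solved,
        reported_genes=frozenset(genes), dual_diagnosis=len(genes) >= 2,
    )


@pytest.fixture
def trio():
    return make_trio()


@pytest.fixture
def female_trio():
    return make_trio(sex=Sex.FEMALE)
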
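"""Pedigree and phenotype data model.

Readers for 6-column PED files and the tab-separated phenotype table, plus
assignment of each family to a phenotype subgroup and mapping of its HPO
terms onto high-level symptom categories.

The subgroup logic works on a fixed, flat list of HPO identifiers: a small
set of neurodevelopmental-disorder (NDD) terms and one high-level term per
symptom category.  No ontology expansion is performed; terms outside the
known list fall into ``OTHER``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

log = logging.getLogger(__name__)


class PedigreeError(ValueError):
    """Raised for malformed PED or phenotype-table input."""


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(str, Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class PhenotypeSubgroup(str, Enum):
    NDD_ONLY = "NDD_ONLY"
    NDD_SYNDROME = "NDD_SYNDROME"
    SYNDROME = "SYNDROME"
    FETUS = "FETUS"


class SymptomCategory(str, Enum):
    SEIZURES = "SEIZURES"
    BRAIN_MORPHOLOGY = "BRAIN_MORPHOLOGY"
    MICROCEPHALY = "MICROCEPHALY"
    MACROCEPHALY = "MACROCEPHALY"
    GROWTH = "GROWTH"
    FACE = "FACE"
    SKELETAL = "SKELETAL"
    HYPOTONIA = "HYPOTONIA"
    CONTRACTURE = "CONTRACTURE"
    VISUAL = "VISUAL"
    HEARING = "HEARING"
    CARDIOVASCULAR = "CARDIOVASCULAR"
    KIDNEY = "KIDNEY"
    CONGENITAL_MALFORMATION = "CONGENITAL_MALFORMATION"
    NEUROMUSCULAR = "NEUROMUSCULAR"
    OTHER = "OTHER"


#: HPO terms that place a patient in the NDD group.
NDD_TERMS: frozenset[str] = frozenset(
    {
        "HP:0012758",  # neurodevelopmental delay
        "HP:0001263",  # global developmental delay
        "HP:0001270",  # motor delay
        "HP:0000750",  # delayed speech and language development
        "HP:0001249",  # intellectual disability
        "HP:0000729",  # autistic behavior
        "HP:0000717",  # autism
    }
)

#: High-level term -> symptom category.  CAT:CM and CAT:NMD are pseudo-terms
#: for the two free-text categories that have no single HPO id.
SYMPTOM_CATEGORY_BY_TERM: dict[str, SymptomCategory] = {
    "HP:0001250": SymptomCategory.SEIZURES,
    "HP:0012443": SymptomCategory.BRAIN_MORPHOLOGY,
    "HP:0000252": SymptomCategory.MICROCEPHALY,
    "HP:0000256": SymptomCategory.MACROCEPHALY,
    "HP:0001507": SymptomCategory.GROWTH,
    "HP:0000271": SymptomCategory.FACE,
    "HP:0000924": SymptomCategory.SKELETAL,
    "HP:0001252": SymptomCategory.HYPOTONIA,
    "HP:0002803": SymptomCategory.CONTRACTURE,
    "HP:0000505": SymptomCategory.VISUAL,
    "HP:0000364": SymptomCategory.HEARING,
    "HP:0030680": SymptomCategory.CARDIOVASCULAR,
    "HP:0000077": SymptomCategory.KIDNEY,
    "CAT:CM": SymptomCategory.CONGENITAL_MALFORMATION,
    "CAT:NMD": SymptomCategory.NEUROMUSCULAR,
}


@dataclass(frozen=True)
class Individual:
    sample_id: str
    family_id: str
    father_id: str | None
    mother_id: str | None
    sex: Sex
    affected: Affection


@dataclass
class TrioFamily:
    """A proband plus (usually) both parents, with referral metadata."""

    family_id: str
    proband: Individual
    mother: Individual | None
    father: Individual | None
    consanguineous: bool = False
    fetus: bool = False
    hpo_terms: frozenset[str] = frozenset()
    siblings: tuple[Individual, ...] = ()

    @property
    def is_trio(self) -> bool:
        return self.mother is not None and self.father is not None

    @property
    def sample_ids(self) -> tuple[str, ...]:
        ids = [self.proband.sample_id]
        if self.father is not None:
            ids.append(self.father.sample_id)
        if self.mother is not None:
            ids.append(self.mother.sample_id)
        return tuple(ids)


_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
_PHENO_CODES = {"2": Affection.AFFECTED, "1": Affection.UNAFFECTED, "0": Affection.UNKNOWN}


def read_ped(path: str | Path) -> list[TrioFamily]:
    """Read a standard 6-column PED file into trio families.

    One :class:`TrioFamily` is produced per family id.  The proband is the
    first affected individual whose two parent ids both resolve within the
    family; additional children are retained as ``siblings``.  Families in
    which no individual has both parents present are excluded with a
    warning (non-trio).
    """
    individuals: dict[str, dict[str, Individual]] = {}
    order: list[str] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise PedigreeError(f"{path}: line {lineno}: expected 6 columns, got {len(fields)}")
            fam_id, sample_id, father_id, mother_id, sex_code, pheno_code = fields[:6]
            if sex_code not in _SEX_CODES:
                raise PedigreeError(f"{path}: line {lineno}: bad sex code {sex_code!r}")
            if pheno_code not in _PHENO_CODES:
                raise PedigreeError(f"{path}: line {lineno}: bad phenotype code {pheno_code!r}")
            ind = Individual(
                sample_id=sample_id,
                family_id=fam_id,
                father_id=None if father_id == "0" else father_id,
                mother_id=None if mother_id == "0" else mother_id,
                sex=_SEX_CODES[sex_code],
                affected=_PHENO_CODES[pheno_code],
            )
            fam = individuals.setdefault(fam_id, {})
            if sample_id in fam:
                raise PedigreeError(f"{path}: line {lineno}: duplicate sample id {sample_id!r} in family {fam_id!r}")
            fam[sample_id] = ind
            if fam_id not in order:
                order.append(fam_id)

    families: list[TrioFamily] = []
    for fam_id in order:
        members = individuals[fam_id]
        children = [
            ind
            for ind in members.values()
            if ind.father_id is not None or ind.mother_id is not None
        ]
        proband = None
        for ind in children:
            if ind.affected is not Affection.AFFECTED:
                continue
            father = members.get(ind.father_id) if ind.father_id else None
            mother = members.get(ind.mother_id) if ind.mother_id else None
            if (ind.father_id and father is None) or (ind.mother_id and mother is None):
                log.warning("family %s: child %s references absent parent id; skipping as proband", fam_id, ind.sample_id)
                continue
            if father is not None and father.sex is not Sex.MALE:
                log.warning("family %s: father %s not recorded male; excluding family", fam_id, father.sample_id)
                proband = None
                break
            if mother is not None and mother.sex is not Sex.FEMALE:
                log.warning("family %s: mother %s not recorded female; excluding family", fam_id, mother.sample_id)
                proband = None
                break
            if father is None and mother is None:
                continue
            proband = ind
            break
        if proband is None:
            log.warning("family %s: no usable affected child with linked parents; excluded (non-trio)", fam_id)
            continue
        father = members.get(proband.father_id) if proband.father_id else None
        mother = members.get(proband.mother_id) if proband.mother_id else None
        siblings = tuple(
            ind for ind in children if ind.sample_id != proband.sample_id
        )
        families.append(
            TrioFamily(
                family_id=fam_id,
                proband=proband,
                mother=mother,
                father=father,
                siblings=siblings,
            )
        )
    return families


def read_phenotype_table(path: str | Path) -> dict[str, dict]:
    """Read the phenotype table (family_id, hpo_terms, fetus, consanguineous).

    Returns a mapping family_id -> {"hpo_terms": frozenset, "fetus": bool,
    "consanguineous": bool}.
    """
    rows: dict[str, dict] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["family_id", "hpo_terms", "fetus", "consanguineous"]
        if header[: len(required)] != required:
            raise PedigreeError(f"{path}: expected header {required}, got {header}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise PedigreeError(f"{path}: line {lineno}: expected 4 columns")
            fam_id, terms_str, fetus_str, consang_str = fields[:4]
            terms = frozenset(t for t in terms_str.split(";") if t)
            rows[fam_id] = {
                "hpo_terms": terms,
                "fetus": fetus_str == "1",
                "consanguineous": consang_str == "1",
            }
    return rows


def load_cohort(ped_path: str | Path, phenotype_path: str | Path) -> list[TrioFamily]:
    """Read PED + phenotype table and merge referral metadata onto families."""
    families = read_ped(ped_path)
    pheno = read_phenotype_table(phenotype_path)
    for fam in families:
        row = pheno.get(fam.family_id)
        if row is None:
            log.warning("family %s: no phenotype-table row; assuming no terms", fam.family_id)
            continue
        fam.hpo_terms = row["hpo_terms"]
        fam.fetus = row["fetus"]
        fam.consanguineous = row["consanguineous"]
    return families


def assign_subgroup(hpo_terms: Iterable[str], fetus: bool) -> PhenotypeSubgroup:
    """Assign the referral phenotype subgroup.

    Fetal samples dominate.  Otherwise: only-NDD terms -> NDD_ONLY, NDD
    plus anything else -> NDD_SYNDROME, no NDD term -> SYNDROME.  An empty
    non-fetal term set falls into SYNDROME (logged).
    """
    terms = set(hpo_terms)
    if fetus:
        return PhenotypeSubgroup.FETUS
    ndd = terms & NDD_TERMS
    non_ndd = terms - NDD_TERMS
    if ndd and not non_ndd:
        return PhenotypeSubgroup.NDD_ONLY
    if ndd and non_ndd:
        return PhenotypeSubgroup.NDD_SYNDROME
    if not terms:
        log.info("empty term set for non-fetal family; assigning SYNDROME")
    return PhenotypeSubgroup.SYNDROME


def categorize_symptoms(hpo_terms: Iterable[str]) -> set[SymptomCategory]:
    """Map HPO terms to high-level symptom categories.

    NDD terms are excluded from the result; terms not in the known table
    map to ``OTHER``.
    """
    out: set[SymptomCategory] = set()
    for term in hpo_terms:
        if term in NDD_TERMS:
            continue
        out.add(SYMPTOM_CATEGORY_BY_TERM.get(term, SymptomCategory.OTHER))
    return out
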
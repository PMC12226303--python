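"""Independent brute-force rule tables for trio genotype classification.

These tables are derived directly from Mendelian transmission logic and
are deliberately written as literal enumerations, independent of the
implementation under test.  Genotypes are expressed as alternate-allele
counts; reads are assumed clean (high depth/GQ, zero alternate reads in
hom-ref parents).
"""

from __future__ import annotations

from trioscope.inheritance import InheritanceMode

M = InheritanceMode

# ---------------------------------------------------------------------------
# Autosomal: (child, mother, father) alt-allele counts, each in {0,1,2}.
# Value: expected mode under clean reads, plus the note class for NONE.
#   "err"  = Mendelian-impossible configuration
#   "ref"  = no alternate allele in the proband
#   "inh"  = inherited het with a certain single transmitting parent
#   "amb"  = inherited het, either parent could have transmitted
#   "hom"  = homozygous child with a hom-alt (carrier) parent
# ---------------------------------------------------------------------------
AUTOSOMAL_TABLE: dict[tuple[int, int, int], tuple[M, str | None]] = {
    (0, 0, 0): (M.NONE, "ref"),
    (0, 0, 1): (M.NONE, "ref"),
    (0, 0, 2): (M.NONE, "err"),
    (0, 1, 0): (M.NONE, "ref"),
    (0, 1, 1): (M.NONE, "ref"),
    (0, 1, 2): (M.NONE, "err"),
    (0, 2, 0): (M.NONE, "err"),
    (0, 2, 1): (M.NONE, "err"),
    (0, 2, 2): (M.NONE, "err"),
    (1, 0, 0): (M.AD_DENOVO, None),
    (1, 0, 1): (M.NONE, "inh:father"),
    (1, 0, 2): (M.NONE, "inh:father"),
    (1, 1, 0): (M.NONE, "inh:mother"),
    (1, 1, 1): (M.NONE, "amb"),
    (1, 1, 2): (M.NONE, "inh:father"),
    (1, 2, 0): (M.NONE, "inh:mother"),
    (1, 2, 1): (M.NONE, "inh:mother"),
    (1, 2, 2): (M.NONE, "err"),
    (2, 0, 0): (M.NONE, "err"),
    (2, 0, 1): (M.NONE, "err"),
    (2, 0, 2): (M.NONE, "err"),
    (2, 1, 0): (M.NONE, "err"),
    (2, 1, 1): (M.AR_HOM, None),
    (2, 1, 2): (M.NONE, "hom"),
    (2, 2, 0): (M.NONE, "err"),
    (2, 2, 1): (M.NONE, "hom"),
    (2, 2, 2): (M.NONE, "hom"),
}

# ---------------------------------------------------------------------------
# chrX outside PAR, male proband: (child hemizygous in {0,1}, mother in
# {0,1,2}, father hemizygous in {0,1}).  The son's X always comes from the
# mother, so the father's genotype never changes the call.
# ---------------------------------------------------------------------------
X_MALE_TABLE: dict[tuple[int, int, int], tuple[M, str | None]] = {}
for _f in (0, 1):
    X_MALE_TABLE[(0, 0, _f)] = (M.NONE, "ref")
    X_MALE_TABLE[(0, 1, _f)] = (M.NONE, "ref")
    X_MALE_TABLE[(0, 2, _f)] = (M.NONE, "err")  # hom mother must transmit alt
    X_MALE_TABLE[(1, 0, _f)] = (M.XL_DENOVO, None)
    X_MALE_TABLE[(1, 1, _f)] = (M.XL_MATERNAL, None)
    X_MALE_TABLE[(1, 2, _f)] = (M.NONE, "momhom")

# ---------------------------------------------------------------------------
# chrX outside PAR, female proband: (child in {0,1,2}, mother in {0,1,2},
# father hemizygous in {0,1}).  A hemizygous father transmits his X allele
# to every daughter.  The carrier-mother het configuration (1,1,0)/(1,2,0)
# is NONE unless the female-carrier exception is enabled.
# ---------------------------------------------------------------------------
X_FEMALE_TABLE: dict[tuple[int, int, int], tuple[M, str | None]] = {
    (0, 0, 0): (M.NONE, "ref"),
    (0, 0, 1): (M.NONE, "err"),
    (0, 1, 0): (M.NONE, "ref"),
    (0, 1, 1): (M.NONE, "err"),
    (0, 2, 0): (M.NONE, "err"),
    (0, 2, 1): (M.NONE, "err"),
    (1, 0, 0): (M.XL_DENOVO, None),
    (1, 0, 1): (M.NONE, "inh:father_x"),
    (1, 1, 0): (M.NONE, "carrier"),
    (1, 1, 1): (M.NONE, "amb"),
    (1, 2, 0): (M.NONE, "carrier"),
    (1, 2, 1): (M.NONE, "err"),
    (2, 0, 0): (M.NONE, "err"),
    (2, 0, 1): (M.NONE, "err"),
    (2, 1, 0): (M.NONE, "err"),
    (2, 1, 1): (M.NONE, "xlhom"),
    (2, 2, 0): (M.NONE, "err"),
    (2, 2, 1): (M.NONE, "xlhom"),
}

#: note-class -> substring expected in the implementation's note string
NOTE_SUBSTRING = {
    "err": "mendelian_error",
    "ref": "no_alt_in_proband",
    "amb": "inherited_ambiguous",
    "hom": "inherited_homozygous",
    "momhom": "maternal_hom",
    "carrier": "xl_female_carrier",
    "xlhom": "xl_hom",
    "inh:mother": "inherited_single_parent",
    "inh:father": "inherited_single_parent",
    "inh:father_x": "inherited_paternal_x",
}


def brute_force_comphet_pairs(variants, fam):
    """Independent comp-het oracle: all unordered pairs of proband-het
    variants where one is carried by the mother only and the other by the
    father only (checked directly on the genotype calls)."""
    def side(v):
        """Certain transmitting parent of the child's single alt allele."""
        child = v.genotypes[fam.proband.sample_id]
        mom = v.genotypes[fam.mother.sample_id]
        dad = v.genotypes[fam.father.sample_id]
        if child.alleles is None or sorted(child.alleles) != [0, 1]:
            return None
        if mom.alleles is None or dad.alleles is None:
            return None
        m = sum(mom.alleles)
        f = sum(dad.alleles)
        if m == 2 and f == 2:  # child could not be het
            return None
        if m == 2:  # hom mother must have transmitted the alt
            return "M"
        if f == 2:
            return "F"
        if m >= 1 and f >= 1:  # either parent could have transmitted
            return None
        if m >= 1:
            return "M"
        if f >= 1:
            return "F"
        return None  # de novo configuration

    pairs = set()
    for i, a in enumerate(variants):
        for b in variants[i + 1 :]:
            sides = {side(a), side(b)}
            if sides == {"M", "F"}:
                pairs.add(tuple(sorted((a.variant_id, b.variant_id))))
    return pairs
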
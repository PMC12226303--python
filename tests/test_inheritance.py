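from __future__ import annotations

import itertools

import pytest

from conftest import make_trio, make_variant
from oracles import (
    AUTOSOMAL_TABLE,
    NOTE_SUBSTRING,
    X_FEMALE_TABLE,
    X_MALE_TABLE,
    brute_force_comphet_pairs,
)
from trioscope.inheritance import (
    DeNovoParams,
    InheritanceMode,
    TransmittingParent,
    call_family,
    classify_site,
    detect_parental_mosaic,
    find_compound_hets,
    highlight_clinvar,
)
from trioscope.ped import Sex
from trioscope.variants import ClinvarStatus

M = InheritanceMode
TRIO = make_trio()
FEMALE_TRIO = make_trio(sex=Sex.FEMALE)

_DIPLOID = {0: "0/0", 1: "0/1", 2: "1/1"}
_HAPLOID = {0: "0", 1: "1"}


def autosomal_site(c, m, f):
    return make_variant(TRIO, child=_DIPLOID[c], mother=_DIPLOID[m], father=_DIPLOID[f])


class TestClassifySiteExamples:
    def test_ad_denovo(self):
        v = make_variant(
            TRIO, child="0/1", mother="0/0", father="0/0",
            child_ad=(14, 13), mother_ad=(30, 0), father_ad=(28, 0),
        )
        call = classify_site(v, TRIO)
        assert call.mode is M.AD_DENOVO

    def test_xl_maternal(self):
        v = make_variant(
            TRIO, chrom="X", pos=5_000_000, child="1", mother="0/1", father="0",
        )
        call = classify_site(v, TRIO)
        assert call.mode is M.XL_MATERNAL
        assert call.transmitting_parent is TransmittingParent.MOTHER

    def test_ar_hom(self):
        call = classify_site(autosomal_site(2, 1, 1), TRIO)
        assert call.mode is M.AR_HOM
        assert call.transmitting_parent is TransmittingParent.BOTH

    def test_low_support_denovo_rejected(self):
        v = make_variant(TRIO, child="0/1", mother="0/0", father="0/0", child_ad=(5, 2))
        assert classify_site(v, TRIO).mode is M.NONE

    def test_low_gq_denovo_rejected(self):
        from conftest import gt

        v = make_variant(TRIO, child="0/1", mother="0/0", father="0/0")
        v.genotypes[TRIO.proband.sample_id] = gt("0/1", (15, 15), gq=5)
        assert classify_site(v, TRIO).mode is M.NONE

    def test_missing_parent_genotype_blocks(self):
        v = make_variant(TRIO, child="0/1", mother="./.", father="0/0")
        call = classify_site(v, TRIO)
        assert call.mode is M.NONE
        assert "missing_parental_genotype" in call.notes

    def test_het_male_on_x_flagged_artifact(self):
        v = make_variant(TRIO, chrom="X", pos=5_000_000, child="0/1", mother="0/1", father="0")
        call = classify_site(v, TRIO)
        assert call.mode is M.NONE
        assert "possible_mosaic_or_artifact" in call.notes

    def test_par_site_uses_autosomal_rules(self):
        # inside PAR1 a male child is diploid; 1/1 with het parents -> AR_HOM
        v = make_variant(TRIO, chrom="X", pos=100_000, child="1/1", mother="0/1", father="0/1")
        assert classify_site(v, TRIO).mode is M.AR_HOM


class TestExhaustiveOracle:
    """classify_site must agree with the independent rule tables on every
    clean-read trio genotype configuration."""

    @pytest.mark.parametrize("cfg", sorted(AUTOSOMAL_TABLE))
    def test_autosomal(self, cfg):
        c, m, f = cfg
        expected_mode, note_class = AUTOSOMAL_TABLE[cfg]
        call = classify_site(autosomal_site(c, m, f), TRIO)
        assert call.mode is expected_mode, cfg
        if note_class is not None:
            assert NOTE_SUBSTRING[note_class] in call.notes, (cfg, call.notes)
            if note_class.startswith("inh:"):
                assert call.transmitting_parent.value == note_class.split(":")[1]

    @pytest.mark.parametrize("proband_sex", [Sex.MALE, Sex.FEMALE])
    def test_autosomal_sex_invariant(self, proband_sex):
        trio = make_trio(sex=proband_sex)
        for (c, m, f), (expected_mode, _) in AUTOSOMAL_TABLE.items():
            v = make_variant(trio, child=_DIPLOID[c], mother=_DIPLOID[m], father=_DIPLOID[f])
            assert classify_site(v, trio).mode is expected_mode

    @pytest.mark.parametrize("cfg", sorted(X_MALE_TABLE))
    def test_x_male(self, cfg):
        c, m, f = cfg
        expected_mode, note_class = X_MALE_TABLE[cfg]
        v = make_variant(
            TRIO, chrom="X", pos=5_000_000,
            child=_HAPLOID[c], mother=_DIPLOID[m], father=_HAPLOID[f],
        )
        call = classify_site(v, TRIO)
        assert call.mode is expected_mode, cfg
        if note_class is not None:
            assert NOTE_SUBSTRING[note_class] in call.notes, (cfg, call.notes)

    @pytest.mark.parametrize("cfg", sorted(X_FEMALE_TABLE))
    def test_x_female(self, cfg):
        c, m, f = cfg
        expected_mode, note_class = X_FEMALE_TABLE[cfg]
        v = make_variant(
            FEMALE_TRIO, chrom="X", pos=5_000_000,
            child=_DIPLOID[c], mother=_DIPLOID[m], father=_HAPLOID[f],
        )
        call = classify_site(v, FEMALE_TRIO)
        assert call.mode is expected_mode, cfg
        if note_class is not None:
            assert NOTE_SUBSTRING[note_class] in call.notes, (cfg, call.notes)

    def test_x_female_carrier_flag(self):
        v = make_variant(FEMALE_TRIO, chrom="X", pos=5_000_000, child="0/1", mother="0/1", father="0")
        assert classify_site(v, FEMALE_TRIO).mode is M.NONE
        call = classify_site(v, FEMALE_TRIO, allow_female_xl_carrier=True)
        assert call.mode is M.XL_MATERNAL
        assert "female_carrier_exception" in call.notes


class TestParentalMosaic:
    def test_paternal_mosaic(self):
        v = make_variant(
            TRIO, child="0/1", mother="0/0", father="0/0",
            mother_ad=(30, 0), father_ad=(27, 3),
        )
        call = classify_site(v, TRIO)
        assert call.mode is M.PARENTAL_MOSAIC_PATERNAL
        assert call.parental_alt_fraction == pytest.approx(0.10)

    def test_zero_alt_reads_stays_denovo(self):
        v = make_variant(TRIO, child="0/1", mother="0/0", father="0/0",
                         mother_ad=(28, 0), father_ad=(30, 0))
        assert classify_site(v, TRIO).mode is M.AD_DENOVO

    def test_high_fraction_reclassified_missed_het(self):
        v = make_variant(TRIO, child="0/1", mother="0/0", father="0/0",
                         mother_ad=(10, 9), father_ad=(30, 0))
        call = classify_site(v, TRIO)
        assert call.mode is M.NONE
        assert "parent_likely_het" in call.notes

    def test_both_parents_mosaic_higher_fraction_wins(self):
        v = make_variant(TRIO, child="0/1", mother="0/0", father="0/0",
                         mother_ad=(28, 2), father_ad=(27, 3))
        call = detect_parental_mosaic(v, TRIO, DeNovoParams())
        assert call.mode is M.PARENTAL_MOSAIC_PATERNAL
        assert "both_parents_mosaic_evidence" in call.notes

    def test_single_alt_read_tolerated(self):
        v = make_variant(TRIO, child="0/1", mother="0/0", father="0/0",
                         mother_ad=(29, 1), father_ad=(30, 0))
        assert classify_site(v, TRIO).mode is M.AD_DENOVO

    def test_conservative_thresholds_reproduce_plain_denovo(self):
        """Raising the mosaic window above every parental alt depth must give
        exactly the plain AD_DENOVO calls."""
        params = DeNovoParams(parent_max_alt_reads_for_denovo=10_000, mosaic_min_alt_reads=10_000)
        for father_ad in [(30, 0), (27, 3), (10, 9)]:
            v = make_variant(TRIO, child="0/1", mother="0/0", father="0/0",
                             father_ad=father_ad)
            assert classify_site(v, TRIO, params).mode is M.AD_DENOVO

    def test_params_gap_forbidden(self):
        with pytest.raises(ValueError):
            DeNovoParams(parent_max_alt_reads_for_denovo=1, mosaic_min_alt_reads=5)

    def test_params_fraction_bounds(self):
        with pytest.raises(ValueError):
            DeNovoParams(mosaic_max_fraction=0.5)


class TestCompoundHets:
    def gene_pair(self, sides):
        """sides: list of (mother_gt, father_gt); child het at each site."""
        return [
            make_variant(TRIO, pos=1000 + i, gene="GENEA", child="0/1", mother=m, father=f)
            for i, (m, f) in enumerate(sides)
        ]

    def test_trans_pair_called(self):
        vs = self.gene_pair([("0/1", "0/0"), ("0/0", "0/1")])
        calls = find_compound_hets(vs, TRIO)
        assert len(calls) == 1
        assert calls[0].mode is M.AR_COMPHET
        assert calls[0].transmitting_parent is TransmittingParent.BOTH
        assert set(calls[0].variant_ids) == {v.variant_id for v in vs}

    def test_cis_pair_rejected(self):
        vs = self.gene_pair([("0/1", "0/0"), ("0/1", "0/0")])
        assert find_compound_hets(vs, TRIO) == []

    def test_three_hets_two_pairs(self):
        vs = self.gene_pair([("0/1", "0/0"), ("0/1", "0/0"), ("0/0", "0/1")])
        calls = find_compound_hets(vs, TRIO)
        assert len(calls) == 2
        assert all(c.mode is M.AR_COMPHET for c in calls)

    def test_ambiguous_site_excluded(self):
        vs = self.gene_pair([("0/1", "0/1"), ("0/0", "0/1")])
        assert find_compound_hets(vs, TRIO) == []

    def test_missing_parent_skipped(self):
        vs = self.gene_pair([("0/1", "0/0"), ("./.", "0/1")])
        assert find_compound_hets(vs, TRIO) == []

    def test_mixed_gene_rejected(self):
        vs = self.gene_pair([("0/1", "0/0"), ("0/0", "0/1")])
        vs[1].gene = "GENEB"
        with pytest.raises(ValueError):
            find_compound_hets(vs, TRIO)

    def test_brute_force_oracle_random_fixtures(self):
        import random

        rnd = random.Random(7)
        gts = ["0/0", "0/1", "1/1"]
        for trial in range(50):
            n = rnd.randint(2, 6)
            vs = [
                make_variant(
                    TRIO, pos=1000 + i, gene="GENEA",
                    child=rnd.choice(gts), mother=rnd.choice(gts), father=rnd.choice(gts),
                )
                for i in range(n)
            ]
            got = {
                tuple(sorted(c.variant_ids))
                for c in find_compound_hets(vs, TRIO)
            }
            expected = brute_force_comphet_pairs(vs, TRIO)
            assert got == expected, f"trial {trial}"


class TestHighlightClinvar:
    def test_pathogenic_only_inherited_maternal(self):
        v = make_variant(TRIO, child="0/1", mother="0/1", father="0/0",
                         clinvar=ClinvarStatus.PATHOGENIC_ONLY)
        call = highlight_clinvar(v, TRIO)
        assert call is not None
        assert call.mode is M.AD_INHERITED
        assert call.transmitting_parent is TransmittingParent.MOTHER

    def test_absent_clinvar_dismissed(self):
        v = make_variant(TRIO, child="0/1", mother="0/1", father="0/0")
        assert highlight_clinvar(v, TRIO) is None

    def test_conflicting_clinvar_dismissed(self):
        v = make_variant(TRIO, child="0/1", mother="0/1", father="0/0",
                         clinvar=ClinvarStatus.OTHER_OR_CONFLICTING)
        assert highlight_clinvar(v, TRIO) is None

    def test_denovo_configuration_not_highlighted(self):
        v = make_variant(TRIO, child="0/1", mother="0/0", father="0/0",
                         clinvar=ClinvarStatus.PATHOGENIC_ONLY)
        assert highlight_clinvar(v, TRIO) is None

    def test_both_parents_carry_not_highlighted(self):
        v = make_variant(TRIO, child="0/1", mother="0/1", father="0/1",
                         clinvar=ClinvarStatus.PATHOGENIC_ONLY)
        assert highlight_clinvar(v, TRIO) is None


class TestCallFamily:
    def test_empty(self):
        assert call_family([], TRIO) == []

    def test_planted_ar_hom_among_background(self):
        """Exactly the planted AR call among AR-mode calls over a noiseless
        simulated background."""
        import numpy as np

        from trioscope.simulate import (
            GeneLocus,
            SimConfig,
            generate_background,
            plant_causal_variant,
        )

        cfg = SimConfig(n_families=1, seed=3, background_variants_per_family=200, base_error=0.0)
        rng = np.random.default_rng(3)
        used = set()
        gene = GeneLocus("CAUSAL1", "2", 1_000_000)
        records, truth = plant_causal_variant(
            M.AR_HOM, "FAM1", "male", gene, rng, cfg, used
        )
        bg_genes = [GeneLocus(f"BG{i:03d}", "1", 1_000_000 + i * 20_000) for i in range(50)]
        background = generate_background("FAM1", "male", bg_genes, rng, cfg, used)
        from trioscope.filters import apply_filters

        panel = frozenset(g.name for g in bg_genes) | {gene.name}
        passing = [v for v in records + background if apply_filters(v, panel).passed]
        calls = call_family(passing, TRIO, DeNovoParams())
        hom_calls = [c for c in calls if c.mode is M.AR_HOM]
        assert [c.variant_ids for c in hom_calls] == [truth.variant_ids]

    def test_planted_xl_denovo_female(self):
        v = make_variant(FEMALE_TRIO, chrom="X", pos=5_000_000, child="0/1",
                         mother="0/0", father="0")
        calls = call_family([v], FEMALE_TRIO)
        assert [c.mode for c in calls] == [M.XL_DENOVO]

    def test_no_contradictory_site_modes_and_comphet_disjoint_from_hom(self):
        vs = [
            make_variant(TRIO, pos=1000, gene="GENEA", child="0/1", mother="0/1", father="0/0"),
            make_variant(TRIO, pos=1001, gene="GENEA", child="0/1", mother="0/0", father="0/1"),
            make_variant(TRIO, pos=2000, gene="GENEB", child="1/1", mother="0/1", father="0/1"),
        ]
        calls = call_family(vs, TRIO)
        hom_ids = {vid for c in calls if c.mode is M.AR_HOM for vid in c.variant_ids}
        comphet_ids = {vid for c in calls if c.mode is M.AR_COMPHET for vid in c.variant_ids}
        assert hom_ids and comphet_ids
        assert hom_ids.isdisjoint(comphet_ids)
        by_variant_modes = {}
        for c in calls:
            for vid in c.variant_ids:
                by_variant_modes.setdefault(vid, set()).add(c.mode)
        for modes in by_variant_modes.values():
            assert len(modes) == 1

    def test_comphet_members_not_double_highlighted(self):
        vs = [
            make_variant(TRIO, pos=1000, gene="GENEA", child="0/1", mother="0/1", father="0/0",
                         clinvar=ClinvarStatus.PATHOGENIC_ONLY),
            make_variant(TRIO, pos=1001, gene="GENEA", child="0/1", mother="0/0", father="0/1"),
        ]
        calls = call_family(vs, TRIO)
        assert [c.mode for c in calls] == [M.AR_COMPHET]

    def test_deterministic_order(self):
        vs = [
            make_variant(TRIO, pos=3000, gene="GENEC", child="0/1", mother="0/0", father="0/0"),
            make_variant(TRIO, pos=1000, gene="GENEA", child="1/1", mother="0/1", father="0/1"),
        ]
        a = call_family(vs, TRIO)
        b = call_family(list(reversed(vs)), TRIO)
        assert a == b
        assert [c.mode for c in a] == [M.AR_HOM, M.AD_DENOVO]
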
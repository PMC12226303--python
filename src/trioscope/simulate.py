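"""Seeded synthetic trio-cohort simulator.

Generates a full analysis bundle — PED, phenotype table, per-family
annotated VCFs, gene panel, ACMG class table and a truth table of planted
diagnoses — with the statistical structure the trio analysis assumes:
per-mode trio genotype configurations, consanguinity-boosted homozygosity,
sex-consistent X genotypes (fathers and sons hemizygous outside PAR),
low-fraction mosaic parental reads, and background variant noise with a
common/rare population-AF mixture.

Everything is driven by one :class:`numpy.random.Generator`; a fixed
config (including seed) yields byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .inheritance import InheritanceMode
from .ped import NDD_TERMS, PhenotypeSubgroup, SYMPTOM_CATEGORY_BY_TERM
from .variants import (
    AnnotatedVariant,
    ClinvarStatus,
    ConsequenceClass,
    GenotypeCall,
    PAR1,
    PAR2,
    REPORTABLE_CONSEQUENCES,
    write_annotated_vcf,
)

# Synthetic contig set: five autosomes plus a GRCh37-sized X so the PAR
# constants apply unchanged.
CONTIGS: dict[str, int] = {
    "1": 50_000_000,
    "2": 50_000_000,
    "3": 50_000_000,
    "4": 50_000_000,
    "5": 50_000_000,
    "X": 155_270_560,
}
_X_NONPAR = (PAR1[1] + 1, PAR2[0] - 1)

_MODES_X = {InheritanceMode.XL_DENOVO, InheritanceMode.XL_MATERNAL}
_MODES_PLANTABLE = [
    InheritanceMode.AD_DENOVO,
    InheritanceMode.XL_DENOVO,
    InheritanceMode.AR_HOM,
    InheritanceMode.AR_COMPHET,
    InheritanceMode.XL_MATERNAL,
    InheritanceMode.AD_INHERITED,
    InheritanceMode.PARENTAL_MOSAIC_MATERNAL,
    InheritanceMode.PARENTAL_MOSAIC_PATERNAL,
]

_NDD_TERMS_ORDERED = sorted(NDD_TERMS)
_SYNDROME_TERMS_ORDERED = sorted(SYMPTOM_CATEGORY_BY_TERM)


@dataclass
class SimConfig:
    n_families: int = 100
    seed: int = 1
    subgroup_probs: dict[str, float] = field(
        default_factory=lambda: {
            "NDD_ONLY": 0.076,
            "NDD_SYNDROME": 0.489,
            "SYNDROME": 0.370,
            "FETUS": 0.065,
        }
    )
    solved_prob_per_subgroup: dict[str, float] = field(
        default_factory=lambda: {
            "NDD_ONLY": 0.329,
            "NDD_SYNDROME": 0.462,
            "SYNDROME": 0.335,
            "FETUS": 0.277,
        }
    )
    mode_probs: dict[str, float] = field(
        default_factory=lambda: {
            "AD_DENOVO": 177 / 392,
            "XL_DENOVO": 23 / 392,
            "AR_HOM": 83 / 392,
            "AR_COMPHET": 42 / 392,
            "XL_MATERNAL": 27 / 392,
            "AD_INHERITED": 38 / 392,
            "PARENTAL_MOSAIC_MATERNAL": 1 / 392,
            "PARENTAL_MOSAIC_PATERNAL": 1 / 392,
        }
    )
    consanguinity_prob: float = 0.103
    consang_ar_hom_boost: float = 4.0
    dual_diagnosis_prob: float = 0.048
    background_variants_per_family: int = 300
    background_af_distribution: dict[str, float] = field(
        default_factory=lambda: {
            "p_rare": 0.6,
            "rare_max": 0.009,
            "common_min": 0.02,
            "common_max": 0.5,
        }
    )
    background_offtarget_prob: float = 0.3  # synonymous / deep-intronic share
    mean_depth: int = 30
    base_error: float = 0.0
    mosaic_fraction_range: tuple[float, float] = (0.05, 0.14)
    male_prob: float = 0.59

    def __post_init__(self) -> None:
        for name, table in (
            ("subgroup_probs", self.subgroup_probs),
            ("solved_prob_per_subgroup", None),
            ("mode_probs", self.mode_probs),
        ):
            if table is not None and abs(sum(table.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        lo, hi = self.mosaic_fraction_range
        if not (0.0 < lo <= hi < 0.5):
            raise ValueError("mosaic_fraction_range must lie within (0, 0.5)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "mosaic_fraction_range" in data:
            data["mosaic_fraction_range"] = tuple(data["mosaic_fraction_range"])
        return cls(**data)

    @classmethod
    def published_cohort(cls, **overrides) -> "SimConfig":
        """The shipped preset encoding the published cohort fractions."""
        with resources.files("trioscope").joinpath("presets/published_cohort.yaml").open("r") as fh:
            data = yaml.safe_load(fh)
        data.update(overrides)
        if "mosaic_fraction_range" in data:
            data["mosaic_fraction_range"] = tuple(data["mosaic_fraction_range"])
        return cls(**data)

    def to_yaml(self) -> str:
        data = dataclasses.asdict(self)
        data["mosaic_fraction_range"] = list(self.mosaic_fraction_range)
        return yaml.safe_dump(data, sort_keys=True)


@dataclass(frozen=True)
class TruthRecord:
    family_id: str
    mode: InheritanceMode
    gene: str
    variant_ids: tuple[str, ...]


@dataclass
class SimulatedFamily:
    family_id: str
    proband_sex: str  # "male" | "female"
    subgroup: PhenotypeSubgroup
    consanguineous: bool
    fetus: bool
    hpo_terms: tuple[str, ...]
    variants: list[AnnotatedVariant]
    truth: list[TruthRecord]
    classes: dict[str, tuple[str, bool]]  # variant_id -> (acmg class, concordant)

    @property
    def sample_ids(self) -> tuple[str, str, str]:
        fid = self.family_id
        return (f"{fid}_child", f"{fid}_father", f"{fid}_mother")


@dataclass
class GeneLocus:
    name: str
    chrom: str
    start: int


def _build_gene_pools(rng: np.random.Generator) -> tuple[list[GeneLocus], list[GeneLocus], list[GeneLocus]]:
    """(autosomal causal, X causal, background) gene pools with loci."""
    causal_auto, causal_x, background = [], [], []
    autosomes = [c for c in CONTIGS if c != "X"]
    for i in range(400):
        chrom = autosomes[i % len(autosomes)]
        start = 1_000_000 + (i // len(autosomes)) * 200_000
        causal_auto.append(GeneLocus(f"CGA{i:04d}", chrom, start))
    for i in range(60):
        start = _X_NONPAR[0] + 1_000_000 + i * 500_000
        causal_x.append(GeneLocus(f"CGX{i:03d}", "X", start))
    for i in range(600):
        chrom = autosomes[i % len(autosomes)]
        start = 25_000_000 + (i // len(autosomes)) * 150_000
        background.append(GeneLocus(f"BGA{i:04d}", chrom, start))
    for i in range(60):
        start = _X_NONPAR[0] + 40_000_000 + i * 400_000
        background.append(GeneLocus(f"BGX{i:03d}", "X", start))
    return causal_auto, causal_x, background


def _rare_af(rng: np.random.Generator) -> float:
    return float(rng.uniform(0.0, 0.009))


def _reportable_consequence(rng: np.random.Generator) -> ConsequenceClass:
    choices = sorted(REPORTABLE_CONSEQUENCES, key=lambda c: c.value)
    weights = {"missense": 0.52, "nonsense": 0.15, "frameshift": 0.14,
               "splice_region": 0.10, "inframe_indel": 0.06, "start_or_stop_altering": 0.03}
    p = np.array([weights[c.value] for c in choices])
    return choices[int(rng.choice(len(choices), p=p / p.sum()))]


def _depth(rng: np.random.Generator, cfg: SimConfig, floor: int = 15) -> int:
    return max(int(rng.poisson(cfg.mean_depth)), floor)


def _call(alleles: tuple[int, ...], depth: int, alt_reads: int, gq: int = 99) -> GenotypeCall:
    alt = min(alt_reads, depth)
    return GenotypeCall(
        alleles=alleles, ref_depth=depth - alt, alt_depth=alt, total_depth=depth,
        genotype_quality=gq,
    )


def _het_call(rng: np.random.Generator, cfg: SimConfig, ploidy: int = 2) -> GenotypeCall:
    d = _depth(rng, cfg)
    alt = int(np.clip(rng.binomial(d, 0.5), 5, d - 2))
    return _call((0, 1) if ploidy == 2 else (1,), d, alt)


def _hom_ref_call(rng: np.random.Generator, cfg: SimConfig, ploidy: int = 2) -> GenotypeCall:
    d = _depth(rng, cfg)
    leak = int(rng.binomial(d, cfg.base_error)) if cfg.base_error > 0 else 0
    return _call((0, 0) if ploidy == 2 else (0,), d, leak)


def _hom_alt_call(rng: np.random.Generator, cfg: SimConfig, ploidy: int = 2) -> GenotypeCall:
    d = _depth(rng, cfg)
    leak = int(rng.binomial(d, cfg.base_error)) if cfg.base_error > 0 else 0
    return _call((1, 1) if ploidy == 2 else (1,), d, d - leak)


def _mosaic_parent_call(rng: np.random.Generator, cfg: SimConfig) -> GenotypeCall:
    """Hom-ref GT with low-fraction alt reads inside the detection window.

    The alternate-read count is a truncated Binomial(depth, f): draws are
    rejected until at least 2 alt reads at a fraction <= 0.15, guaranteeing
    the planted mosaic is detectable under the default thresholds.
    """
    f = float(rng.uniform(*cfg.mosaic_fraction_range))
    d = max(_depth(rng, cfg), 20)
    for _ in range(200):
        alt = int(rng.binomial(d, f))
        if alt >= 2 and alt / d <= 0.15:
            return _call((0, 0), d, alt)
    return _call((0, 0), d, max(2, int(0.1 * d)))


def plant_causal_variant(
    mode: InheritanceMode,
    family_id: str,
    proband_sex: str,
    gene: GeneLocus,
    rng: np.random.Generator,
    cfg: SimConfig,
    used_positions: set[tuple[str, int]],
) -> tuple[list[AnnotatedVariant], TruthRecord]:
    """Emit the variant record(s) whose trio genotypes define ``mode``."""
    child_id, father_id, mother_id = (
        f"{family_id}_child",
        f"{family_id}_father",
        f"{family_id}_mother",
    )
    male = proband_sex == "male"
    if mode in _MODES_X and gene.chrom != "X":
        raise ValueError(f"{mode} requires an X gene")

    def new_site(clinvar: ClinvarStatus = ClinvarStatus.ABSENT) -> AnnotatedVariant:
        while True:
            pos = gene.start + int(rng.integers(0, 10_000))
            if (gene.chrom, pos) not in used_positions:
                used_positions.add((gene.chrom, pos))
                break
        ref, alt = [["A", "T"], ["C", "G"], ["G", "A"], ["T", "C"]][int(rng.integers(0, 4))]
        return AnnotatedVariant(
            chrom=gene.chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            gene=gene.name,
            consequence=_reportable_consequence(rng),
            pop_af=_rare_af(rng),
            clinvar=clinvar,
            genotypes={},
        )

    records: list[AnnotatedVariant] = []
    on_x = gene.chrom == "X"
    child_ploidy = 1 if (on_x and male) else 2

    if mode is InheritanceMode.AD_DENOVO:
        v = new_site()
        v.genotypes = {
            child_id: _het_call(rng, cfg),
            father_id: _hom_ref_call(rng, cfg),
            mother_id: _hom_ref_call(rng, cfg),
        }
        records.append(v)
    elif mode is InheritanceMode.AR_HOM:
        v = new_site()
        v.genotypes = {
            child_id: _hom_alt_call(rng, cfg),
            father_id: _het_call(rng, cfg),
            mother_id: _het_call(rng, cfg),
        }
        records.append(v)
    elif mode is InheritanceMode.AR_COMPHET:
        v1, v2 = new_site(), new_site()
        v1.genotypes = {
            child_id: _het_call(rng, cfg),
            father_id: _hom_ref_call(rng, cfg),
            mother_id: _het_call(rng, cfg),
        }
        v2.genotypes = {
            child_id: _het_call(rng, cfg),
            father_id: _het_call(rng, cfg),
            mother_id: _hom_ref_call(rng, cfg),
        }
        records.extend([v1, v2])
    elif mode is InheritanceMode.XL_DENOVO:
        v = new_site()
        v.genotypes = {
            child_id: _het_call(rng, cfg, ploidy=child_ploidy)
            if child_ploidy == 2
            else _hom_alt_call(rng, cfg, ploidy=1),
            father_id: _hom_ref_call(rng, cfg, ploidy=1),
            mother_id: _hom_ref_call(rng, cfg),
        }
        records.append(v)
    elif mode is InheritanceMode.XL_MATERNAL:
        if not male:
            raise ValueError("XL_MATERNAL requires a male proband")
        v = new_site()
        v.genotypes = {
            child_id: _hom_alt_call(rng, cfg, ploidy=1),
            father_id: _hom_ref_call(rng, cfg, ploidy=1),
            mother_id: _het_call(rng, cfg),
        }
        records.append(v)
    elif mode is InheritanceMode.AD_INHERITED:
        v = new_site(clinvar=ClinvarStatus.PATHOGENIC_ONLY)
        maternal = bool(rng.integers(0, 2))
        v.genotypes = {
            child_id: _het_call(rng, cfg),
            father_id: _hom_ref_call(rng, cfg) if maternal else _het_call(rng, cfg),
            mother_id: _het_call(rng, cfg) if maternal else _hom_ref_call(rng, cfg),
        }
        records.append(v)
    elif mode in (
        InheritanceMode.PARENTAL_MOSAIC_MATERNAL,
        InheritanceMode.PARENTAL_MOSAIC_PATERNAL,
    ):
        v = new_site()
        maternal = mode is InheritanceMode.PARENTAL_MOSAIC_MATERNAL
        v.genotypes = {
            child_id: _het_call(rng, cfg),
            father_id: _hom_ref_call(rng, cfg) if maternal else _mosaic_parent_call(rng, cfg),
            mother_id: _mosaic_parent_call(rng, cfg) if maternal else _hom_ref_call(rng, cfg),
        }
        records.append(v)
    else:
        raise ValueError(f"cannot plant mode {mode}")

    truth = TruthRecord(
        family_id=family_id,
        mode=mode,
        gene=gene.name,
        variant_ids=tuple(r.variant_id for r in records),
    )
    return records, truth


def generate_background(
    family_id: str,
    proband_sex: str,
    genes: list[GeneLocus],
    rng: np.random.Generator,
    cfg: SimConfig,
    used_positions: set[tuple[str, int]],
) -> list[AnnotatedVariant]:
    """Mendelian-consistent inherited background noise for one family."""
    child_id, father_id, mother_id = (
        f"{family_id}_child",
        f"{family_id}_father",
        f"{family_id}_mother",
    )
    male = proband_sex == "male"
    afd = cfg.background_af_distribution
    out: list[AnnotatedVariant] = []
    n = cfg.background_variants_per_family
    gene_idx = rng.integers(0, len(genes), size=n)
    for i in range(n):
        gene = genes[int(gene_idx[i])]
        on_x = gene.chrom == "X"
        while True:
            pos = gene.start + int(rng.integers(0, 10_000))
            if (gene.chrom, pos) not in used_positions:
                used_positions.add((gene.chrom, pos))
                break
        if rng.random() < afd["p_rare"]:
            af = float(rng.uniform(0.0, afd["rare_max"]))
        else:
            af = float(rng.uniform(afd["common_min"], afd["common_max"]))
        if rng.random() < cfg.background_offtarget_prob:
            csq = ConsequenceClass.SYNONYMOUS if rng.random() < 0.5 else ConsequenceClass.INTRONIC_DEEP
        else:
            csq = _reportable_consequence(rng)

        mother = tuple(int(rng.random() < af) for _ in range(2))
        father = tuple(int(rng.random() < af) for _ in range(2 if not on_x else 1))
        from_mother = mother[int(rng.integers(0, 2))]
        if on_x and male:
            child = (from_mother,)
        else:
            from_father = father[int(rng.integers(0, len(father)))]
            child = tuple(sorted((from_mother, from_father)))

        def emit(alleles: tuple[int, ...]) -> GenotypeCall:
            d = _depth(rng, cfg, floor=12)
            frac = sum(alleles) / len(alleles)
            if cfg.base_error > 0:
                frac = frac * (1 - cfg.base_error) + (1 - frac) * cfg.base_error
            if frac == 0.0:
                alt = 0
            elif frac == 1.0:
                alt = d
            else:
                alt = int(rng.binomial(d, frac))
            return _call(alleles, d, alt, gq=int(rng.integers(30, 100)))

        ref, alt_base = [["A", "G"], ["C", "T"], ["G", "C"], ["T", "A"]][int(rng.integers(0, 4))]
        out.append(
            AnnotatedVariant(
                chrom=gene.chrom,
                pos=pos,
                ref=ref,
                alt=alt_base,
                gene=gene.name,
                consequence=csq,
                pop_af=af,
                clinvar=ClinvarStatus.ABSENT,
                genotypes={
                    child_id: emit(child),
                    father_id: emit(father),
                    mother_id: emit(mother),
                },
            )
        )
    return out


def emit_phenotypes(
    subgroup: PhenotypeSubgroup, rng: np.random.Generator
) -> tuple[tuple[str, ...], bool]:
    """Draw HPO terms consistent with the subgroup; returns (terms, fetus)."""
    def pick(pool: list[str], k: int) -> list[str]:
        idx = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
        return [pool[int(i)] for i in sorted(idx)]

    if subgroup is PhenotypeSubgroup.FETUS:
        terms = pick(_SYNDROME_TERMS_ORDERED, int(rng.integers(1, 4)))
        return tuple(terms), True
    if subgroup is PhenotypeSubgroup.NDD_ONLY:
        return tuple(pick(_NDD_TERMS_ORDERED, int(rng.integers(1, 4)))), False
    if subgroup is PhenotypeSubgroup.NDD_SYNDROME:
        terms = pick(_NDD_TERMS_ORDERED, int(rng.integers(1, 4)))
        terms += pick(_SYNDROME_TERMS_ORDERED, int(rng.integers(1, 5)))
        return tuple(terms), False
    return tuple(pick(_SYNDROME_TERMS_ORDERED, int(rng.integers(1, 5)))), False


def adjusted_mode_probs(
    cfg: SimConfig, male: bool, consanguineous: bool
) -> dict[InheritanceMode, float]:
    """Per-family mode probabilities after the consanguinity boost and the
    removal of male-only modes for female probands (renormalized)."""
    probs = {InheritanceMode(k): v for k, v in cfg.mode_probs.items()}
    if consanguineous:
        probs[InheritanceMode.AR_HOM] = probs.get(InheritanceMode.AR_HOM, 0.0) * cfg.consang_ar_hom_boost
    if not male:
        probs[InheritanceMode.XL_MATERNAL] = 0.0
    total = sum(probs.values())
    return {m: p / total for m, p in probs.items()}


def effective_mode_probs(cfg: SimConfig) -> dict[InheritanceMode, float]:
    """Marginal planted-mode probabilities over sex and consanguinity strata."""
    out = {m: 0.0 for m in _MODES_PLANTABLE}
    for male, p_sex in ((True, cfg.male_prob), (False, 1 - cfg.male_prob)):
        for consang, p_c in ((True, cfg.consanguinity_prob), (False, 1 - cfg.consanguinity_prob)):
            adj = adjusted_mode_probs(cfg, male, consang)
            for m, p in adj.items():
                out[m] += p_sex * p_c * p
    return out


def _draw_mode(rng: np.random.Generator, probs: dict[InheritanceMode, float]) -> InheritanceMode:
    modes = sorted(probs, key=lambda m: m.value)
    p = np.array([probs[m] for m in modes])
    return modes[int(rng.choice(len(modes), p=p / p.sum()))]


def _draw_acmg(rng: np.random.Generator) -> tuple[str, bool]:
    """Reported-variant class mix: 24% class5, 46% class4, 30% class3+."""
    u = rng.random()
    if u < 0.24:
        return "class5", False
    if u < 0.70:
        return "class4", False
    return "class3", True


def simulate_family(
    family_id: str,
    cfg: SimConfig,
    rng: np.random.Generator,
    pools: tuple[list[GeneLocus], list[GeneLocus], list[GeneLocus]],
) -> SimulatedFamily:
    causal_auto, causal_x, background_genes = pools
    male = rng.random() < cfg.male_prob
    sex = "male" if male else "female"
    subgroups = sorted(cfg.subgroup_probs)
    p = np.array([cfg.subgroup_probs[g] for g in subgroups])
    subgroup = PhenotypeSubgroup(subgroups[int(rng.choice(len(subgroups), p=p / p.sum()))])
    consang = rng.random() < cfg.consanguinity_prob
    solved = rng.random() < cfg.solved_prob_per_subgroup[subgroup.value]
    terms, fetus = emit_phenotypes(subgroup, rng)

    used_positions: set[tuple[str, int]] = set()
    variants: list[AnnotatedVariant] = []
    truth: list[TruthRecord] = []
    classes: dict[str, tuple[str, bool]] = {}

    if solved:
        n_diagnoses = 2 if rng.random() < cfg.dual_diagnosis_prob else 1
        probs = adjusted_mode_probs(cfg, male, consang)
        used_genes: set[str] = set()
        for _ in range(n_diagnoses):
            mode = _draw_mode(rng, probs)
            pool = causal_x if mode in _MODES_X else causal_auto
            while True:
                gene = pool[int(rng.integers(0, len(pool)))]
                if gene.name not in used_genes:
                    used_genes.add(gene.name)
                    break
            records, rec = plant_causal_variant(
                mode, family_id, sex, gene, rng, cfg, used_positions
            )
            variants.extend(records)
            truth.append(rec)
            acmg = _draw_acmg(rng)
            for r in records:
                classes[r.variant_id] = acmg

    variants.extend(
        generate_background(family_id, sex, background_genes, rng, cfg, used_positions)
    )
    return SimulatedFamily(
        family_id=family_id,
        proband_sex=sex,
        subgroup=subgroup,
        consanguineous=consang,
        fetus=fetus,
        hpo_terms=terms,
        variants=variants,
        truth=truth,
        classes=classes,
    )


def simulate_cohort(cfg: SimConfig, out_dir: str | Path | None = None) -> list[SimulatedFamily]:
    """Simulate the cohort; optionally write the full bundle to ``out_dir``.

    The bundle contains ``cohort.ped``, ``phenotypes.tsv``, ``panel.txt``,
    ``classes.tsv``, ``truth.tsv``, ``sim_config.yaml`` and one annotated
    VCF per family under ``families/``.
    """
    rng = np.random.default_rng(cfg.seed)
    pools = _build_gene_pools(rng)
    families = [
        simulate_family(f"FAM{i:05d}", cfg, rng, pools) for i in range(cfg.n_families)
    ]
    if out_dir is not None:
        write_bundle(families, cfg, pools, Path(out_dir))
    return families


def write_bundle(
    families: list[SimulatedFamily],
    cfg: SimConfig,
    pools: tuple[list[GeneLocus], list[GeneLocus], list[GeneLocus]],
    out_dir: Path,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    fam_dir = out_dir / "families"
    fam_dir.mkdir(exist_ok=True)

    ped_lines = []
    pheno_lines = ["family_id\thpo_terms\tfetus\tconsanguineous"]
    truth_lines = ["family_id\tmode\tgene\tvariant_ids"]
    class_lines = ["family_id\tvariant_id\tacmg_class\tphenotype_concordant"]
    for fam in families:
        child, father, mother = fam.sample_ids
        sex_code = "1" if fam.proband_sex == "male" else "2"
        ped_lines += [
            f"{fam.family_id}\t{father}\t0\t0\t1\t1",
            f"{fam.family_id}\t{mother}\t0\t0\t2\t1",
            f"{fam.family_id}\t{child}\t{father}\t{mother}\t{sex_code}\t2",
        ]
        pheno_lines.append(
            f"{fam.family_id}\t{';'.join(fam.hpo_terms)}\t{int(fam.fetus)}\t{int(fam.consanguineous)}"
        )
        for rec in fam.truth:
            truth_lines.append(
                f"{fam.family_id}\t{rec.mode.value}\t{rec.gene}\t{','.join(rec.variant_ids)}"
            )
        for vid in sorted(fam.classes):
            acmg, conc = fam.classes[vid]
            class_lines.append(f"{fam.family_id}\t{vid}\t{acmg}\t{int(conc)}")
        write_annotated_vcf(
            fam_dir / f"{fam.family_id}.vcf", fam.variants, list(fam.sample_ids), CONTIGS
        )

    (out_dir / "cohort.ped").write_text("\n".join(ped_lines) + "\n", encoding="utf-8")
    (out_dir / "phenotypes.tsv").write_text("\n".join(pheno_lines) + "\n", encoding="utf-8")
    (out_dir / "truth.tsv").write_text("\n".join(truth_lines) + "\n", encoding="utf-8")
    (out_dir / "classes.tsv").write_text("\n".join(class_lines) + "\n", encoding="utf-8")
    causal_auto, causal_x, background_genes = pools
    panel = [g.name for g in causal_auto + causal_x]
    panel += [g.name for i, g in enumerate(background_genes) if i % 2 == 0]
    (out_dir / "panel.txt").write_text(
        "# simulated analysis panel\n" + "\n".join(sorted(panel)) + "\n", encoding="utf-8"
    )
    (out_dir / "sim_config.yaml").write_text(cfg.to_yaml(), encoding="utf-8")


def read_truth_table(path: str | Path) -> list[TruthRecord]:
    records = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for line in lines[1:]:
        if not line:
            continue
        fam_id, mode, gene, vids = line.split("\t")
        records.append(
            TruthRecord(
                family_id=fam_id,
                mode=InheritanceMode(mode),
                gene=gene,
                variant_ids=tuple(vids.split(",")),
            )
        )
    return records


def read_class_table(path: str | Path) -> dict[str, dict[str, tuple[str, bool]]]:
    """classes.tsv -> {family_id: {variant_id: (acmg_class, concordant)}}."""
    out: dict[str, dict[str, tuple[str, bool]]] = {}
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for line in lines[1:]:
        if not line:
            continue
        fam_id, vid, acmg, conc = line.split("\t")
        out.setdefault(fam_id, {})[vid] = (acmg, conc == "1")
    return out
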
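"""Synthetic multi-incident family studies: pedigrees, gene dropping,
penetrance/phenocopy phenotypes, and study assembly.

The generator emulates the ascertainment design of a multiplex-family
sequencing study: families are simulated until they contain at least two
affected members (rejection sampling over the phenotype model), a rare
causal variant is introduced through one founder and transmitted by
Mendelian gene dropping, background variants are dropped independently
at their population frequencies, and sequencing tiers are assigned so
that every family has at least two exome-sequenced cases and one
exome-sequenced unaffected member, with everyone genotyped at the
targeted tier.

The phenotype model is deliberately simple — one uniform draw per
individual compared against the penetrance (carriers) or phenocopy rate
(non-carriers) — which makes recovery of the causal variant monotone in
penetrance under common random numbers. No linkage disequilibrium,
haplotype structure, sequencing error, or age-of-onset liability is
modelled.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FamsegError, ValidationError
from .pedigree import (Affection, Cohort, Individual, SequencingTier, Sex,
                       Subtype, write_cohort)
from .variants import (AnnotatedVariant, AnnotationRecord, Consequence,
                       GenotypeMatrix, VariantRecord, canonical_key,
                       write_annotations, write_vcf)

logger = logging.getLogger(__name__)

_ROMAN = ["I", "II", "III", "IV", "V", "VI"]


@dataclass(frozen=True)
class SimConfig:
    """Study-level simulation parameters.

    Frequencies are on the percent scale; ``penetrance`` and
    ``phenocopy_rate`` are probabilities. Defaults describe a multiplex
    cohort of nine small two-to-three-generation families segregating a
    rare (MAF 0.05%), deleterious (CADD 25) missense variant with high
    but incomplete penetrance against a low phenocopy background.
    """

    n_families: int = 9
    generations: int = 3
    sibship_size_range: tuple[int, int] = (2, 4)
    causal_maf_percent: float = 0.05
    causal_cadd: float = 25.0
    background_variant_count: int = 30
    background_maf_range_percent: tuple[float, float] = (0.001, 5.0)  # log-uniform
    background_cadd_range: tuple[float, float] = (1.0, 40.0)  # uniform
    background_x_fraction: float = 0.05
    penetrance: float = 0.8
    phenocopy_rate: float = 0.02
    fraction_exome_sequenced: float = 0.6
    seed: int = 0

    def __post_init__(self):
        for name in ("penetrance", "phenocopy_rate", "fraction_exome_sequenced",
                     "background_x_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.n_families < 1 or self.background_variant_count < 0:
            raise ValidationError("n_families ≥ 1 and background_variant_count ≥ 0 required")
        lo, hi = self.sibship_size_range
        if not (1 <= lo <= hi):
            raise ValidationError(f"bad sibship_size_range {self.sibship_size_range}")
        if self.penetrance <= self.phenocopy_rate:
            logger.warning(
                "penetrance (%.3g) ≤ phenocopy rate (%.3g): affection carries "
                "no information about carrier status", self.penetrance, self.phenocopy_rate,
            )


@dataclass
class SimulatedStudy:
    cohort: Cohort
    variants: list[AnnotatedVariant]
    genotypes: GenotypeMatrix
    truth: dict[str, str] = field(default_factory=dict)  # family_id -> causal key


# --- pedigree structure -------------------------------------------------


def simulate_pedigree(cfg: SimConfig, family_id: str,
                      rng: np.random.Generator) -> list[Individual]:
    """Founder couple plus descendants; parents always precede children.

    Within each non-final generation the first two children marry
    founder spouses and reproduce. One generation yields founders only
    (flagged degenerate, useful only as an edge case).
    """
    if cfg.generations < 1:
        raise ValidationError("generations must be ≥ 1")
    if cfg.generations == 1:
        logger.warning("generations=1: degenerate pedigree of founders only")
    inds = [
        Individual("I.1", family_id, sex=Sex.MALE),
        Individual("I.2", family_id, sex=Sex.FEMALE),
    ]
    couples = [("I.1", "I.2")]
    lo, hi = cfg.sibship_size_range
    for g in range(2, cfg.generations + 1):
        label = _ROMAN[g - 1]
        idx = 1
        children: list[Individual] = []
        for father_id, mother_id in couples:
            for _ in range(int(rng.integers(lo, hi + 1))):
                sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
                children.append(Individual(
                    f"{label}.{idx}", family_id,
                    father_id=father_id, mother_id=mother_id, sex=sex,
                ))
                idx += 1
        spouses: list[Individual] = []
        couples = []
        if g < cfg.generations:
            for child in children[: min(2, len(children))]:
                spouse_sex = Sex.FEMALE if child.sex is Sex.MALE else Sex.MALE
                spouse = Individual(f"{label}.{idx}", family_id, sex=spouse_sex)
                idx += 1
                spouses.append(spouse)
                father, mother = (
                    (child, spouse) if child.sex is Sex.MALE else (spouse, child)
                )
                couples.append((father.individual_id, mother.individual_id))
        inds += children + spouses
    return inds


# --- Mendelian transmission --------------------------------------------


def draw_founder_genotypes(
    ped: list[Individual], maf_percent: float, chrom: str,
    rng: np.random.Generator,
) -> dict[str, tuple[int, ...]]:
    """Independent allele draws at the population frequency for founders."""
    p = maf_percent / 100.0
    out: dict[str, tuple[int, ...]] = {}
    for ind in ped:
        if ind.father_id is not None or ind.mother_id is not None:
            continue
        n_alleles = 1 if (chrom == "X" and ind.sex is Sex.MALE) else 2
        out[ind.individual_id] = tuple(int(rng.random() < p) for _ in range(n_alleles))
    return out


def gene_drop(ped: list[Individual],
              founder_allele_assignments: dict[str, tuple[int, ...]],
              rng: np.random.Generator, chrom: str = "1") -> dict[str, int]:
    """Drop one variant through a pedigree; returns allele counts per member.

    Autosomes: each child draws one allele uniformly from each parent.
    X chromosome: daughters inherit the father's single X allele plus one
    of the mother's; sons inherit one of the mother's only (counts in
    {0, 1}).
    """
    alleles: dict[str, tuple[int, ...]] = {}
    x_linked = chrom == "X"
    for ind in ped:  # construction order guarantees parents first
        if ind.father_id is None and ind.mother_id is None:
            try:
                alleles[ind.individual_id] = founder_allele_assignments[ind.individual_id]
            except KeyError:
                raise ValidationError(
                    f"missing founder assignment for {ind.individual_id!r}"
                ) from None
            continue
        fa = alleles[ind.father_id]
        mo = alleles[ind.mother_id]
        a_m = mo[int(rng.integers(len(mo)))]
        if x_linked and ind.sex is Sex.MALE:
            alleles[ind.individual_id] = (a_m,)
        elif x_linked:
            alleles[ind.individual_id] = (fa[0], a_m)
        else:
            a_f = fa[int(rng.integers(len(fa)))]
            alleles[ind.individual_id] = (a_f, a_m)
    return {iid: sum(a) for iid, a in alleles.items()}


def assign_phenotypes(ped: list[Individual], gm: GenotypeMatrix, causal_key: str,
                      cfg: SimConfig, rng: np.random.Generator) -> dict[str, bool]:
    """Affection statuses given carrier status at the causal variant.

    One uniform per individual, compared against the penetrance for
    carriers and the phenocopy rate for non-carriers; independent across
    individuals given genotype.
    """
    out = {}
    for ind in ped:
        count = gm.get(causal_key, ind.family_id, ind.individual_id)
        if count is None:
            raise ValidationError(f"causal variant {causal_key!r} not called for "
                                  f"{ind.individual_id!r}")
        threshold = cfg.penetrance if count >= 1 else cfg.phenocopy_rate
        out[ind.individual_id] = bool(rng.random() < threshold)
    return out


# --- study assembly -----------------------------------------------------

_SUBTYPES = [Subtype.RRMS, Subtype.SPMS, Subtype.PPMS, Subtype.NA]
_SUBTYPE_WEIGHTS = [0.50, 0.23, 0.08, 0.19]

_MAX_ATTEMPTS = 500


def _family_rng(cfg: SimConfig, family_index: int, attempt: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([cfg.seed, family_index, attempt])
    )


def _background_panel(cfg: SimConfig) -> list[AnnotatedVariant]:
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 10_007]))
    lo, hi = cfg.background_maf_range_percent
    panel = []
    for j in range(cfg.background_variant_count):
        if rng.random() < cfg.background_x_fraction:
            chrom = "X"
        else:
            chrom = str(int(rng.integers(1, 23)))
        rec = VariantRecord(chrom=chrom, pos=1_000_000 + j * 1_000, ref="G", alt="A")
        consequence = [Consequence.MISSENSE, Consequence.SYNONYMOUS,
                       Consequence.LOF, Consequence.OTHER][
            int(rng.choice(4, p=[0.5, 0.3, 0.1, 0.1]))]
        maf = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        anno = AnnotationRecord(
            variant_key=canonical_key(rec),
            gene=f"BG{j + 1}",
            consequence=Consequence(consequence),
            maf_percent=maf,
            cadd_phred=float(rng.uniform(*cfg.background_cadd_range)),
            gene_assoc_p=float(rng.uniform(1e-3, 1.0)),
            literature_ms_link=False,
        )
        panel.append(AnnotatedVariant(record=rec, annotation=anno))
    return panel


def _causal_variant(cfg: SimConfig, family_index: int) -> AnnotatedVariant:
    rec = VariantRecord(chrom="7", pos=50_000_000 + family_index * 10_000,
                        ref="C", alt="T")
    anno = AnnotationRecord(
        variant_key=canonical_key(rec),
        gene=f"CAUSAL{family_index}",
        consequence=Consequence.MISSENSE,
        maf_percent=cfg.causal_maf_percent,
        cadd_phred=cfg.causal_cadd,
        literature_ms_link=True,
    )
    return AnnotatedVariant(record=rec, annotation=anno)


def simulate_study(cfg: SimConfig) -> SimulatedStudy:
    """Simulate a full multiplex-family study under ``cfg``.

    Per family, pedigree + causal gene drop + phenotypes are rejection
    sampled until ≥ 2 affected and ≥ 1 unaffected member exist; the
    causal variant enters through one heterozygous first-generation
    founder (rare-variant ascertainment: one copy segregating in the
    family regardless of its population frequency).
    """
    background = _background_panel(cfg)
    cohort = Cohort()
    gm = GenotypeMatrix()
    truth: dict[str, str] = {}
    causals: list[AnnotatedVariant] = []
    for i in range(1, cfg.n_families + 1):
        family_id = f"F{i}"
        causal = _causal_variant(cfg, i)
        causal_key = causal.key
        accepted = None
        for attempt in range(_MAX_ATTEMPTS):
            rng = _family_rng(cfg, i, attempt)
            ped = simulate_pedigree(cfg, family_id, rng)
            assignments = draw_founder_genotypes(ped, 0.0, causal.record.chrom, rng)
            carrier_founder = "I.1" if rng.random() < 0.5 else "I.2"
            assignments[carrier_founder] = (1, 0)
            counts = gene_drop(ped, assignments, rng, causal.record.chrom)
            fam_gm = GenotypeMatrix()
            for iid, c in counts.items():
                fam_gm.set_call(causal_key, family_id, iid, c)
            affection = assign_phenotypes(ped, fam_gm, causal_key, cfg, rng)
            n_affected = sum(affection.values())
            if n_affected >= 2 and n_affected < len(ped):
                accepted = (rng, ped, counts, affection)
                break
        if accepted is None:
            raise FamsegError(
                f"family {family_id}: no pedigree with ≥ 2 affected members in "
                f"{_MAX_ATTEMPTS} attempts (penetrance={cfg.penetrance}, "
                f"phenocopy_rate={cfg.phenocopy_rate})"
            )
        rng, ped, causal_counts, affection = accepted
        ped = _finalize_family(ped, affection, cfg, rng, cohort)
        for ind in ped:
            gm.set_call(causal_key, family_id, ind.individual_id,
                        causal_counts[ind.individual_id])
        for bg in background:
            assignments = draw_founder_genotypes(
                ped, bg.annotation.maf_percent, bg.record.chrom, rng)
            counts = gene_drop(ped, assignments, rng, bg.record.chrom)
            for iid, c in counts.items():
                gm.set_call(bg.key, family_id, iid, c)
        truth[family_id] = causal_key
        causals.append(causal)
    variants = causals + background
    return SimulatedStudy(cohort=cohort, variants=variants, genotypes=gm, truth=truth)


def _finalize_family(ped: list[Individual], affection: dict[str, bool],
                     cfg: SimConfig, rng: np.random.Generator,
                     cohort: Cohort) -> list[Individual]:
    """Attach affection, subtype, ages, and sequencing tiers; add to cohort."""
    case_ids = [iid for iid, a in affection.items() if a]
    unaff_ids = [iid for iid, a in affection.items() if not a]
    # exome tier: ≥ 2 cases and ≥ 1 unaffected, filled to the target fraction
    exome = set(rng.choice(case_ids, size=min(2, len(case_ids)), replace=False))
    exome |= set(rng.choice(unaff_ids, size=1, replace=False))
    target = max(len(exome), int(np.ceil(cfg.fraction_exome_sequenced * len(ped))))
    remaining = [i.individual_id for i in ped if i.individual_id not in exome]
    extra = target - len(exome)
    if extra > 0 and remaining:
        exome |= set(rng.choice(remaining, size=min(extra, len(remaining)),
                                replace=False))
    out = []
    for ind in ped:
        if affection[ind.individual_id]:
            onset = float(int(np.clip(rng.normal(31.6, 8.5), 18, 60)))
            ind = dataclasses.replace(
                ind,
                affected=Affection.AFFECTED,
                subtype=_SUBTYPES[int(rng.choice(4, p=_SUBTYPE_WEIGHTS))],
                age_at_diagnosis_years=onset,
                age_at_dna_collection_years=onset + float(int(rng.uniform(0, 25))),
            )
        else:
            ind = dataclasses.replace(
                ind,
                affected=Affection.UNAFFECTED,
                age_at_dna_collection_years=float(int(np.clip(rng.normal(50, 15), 20, 85))),
            )
        tier = (SequencingTier.EXOME if ind.individual_id in exome
                else SequencingTier.TARGETED_ONLY)
        ind = dataclasses.replace(ind, sequencing_tier=tier)
        cohort.add(ind)
        out.append(ind)
    return out


# --- Mendelian consistency ----------------------------------------------

_SINGLE_ALLELE_OPTIONS = {0: (0,), 1: (0, 1), 2: (1,)}


def check_mendelian(study: SimulatedStudy) -> list[str]:
    """Verify every child call is traceable to its parents' calls.

    Returns a list of human-readable violations (empty = consistent).
    Children with a missing own or parental call are skipped.
    """
    chrom_of = {v.key: v.record.chrom for v in study.variants}
    violations = []
    for family_id, members in study.cohort.families.items():
        by_id = {m.individual_id: m for m in members}
        for vk in chrom_of:
            x_linked = chrom_of[vk] == "X"
            for child in members:
                if child.father_id is None or child.mother_id is None:
                    continue
                if child.father_id not in by_id or child.mother_id not in by_id:
                    continue
                c = study.genotypes.get(vk, family_id, child.individual_id)
                f = study.genotypes.get(vk, family_id, child.father_id)
                m = study.genotypes.get(vk, family_id, child.mother_id)
                if c is None or f is None or m is None:
                    continue
                if x_linked:
                    if child.sex is Sex.MALE:
                        ok = c in _SINGLE_ALLELE_OPTIONS[min(m, 2)]
                    elif child.sex is Sex.FEMALE:
                        ok = (c - f) in _SINGLE_ALLELE_OPTIONS[min(m, 2)]
                    else:
                        continue
                else:
                    ok = any(
                        (c - af) in _SINGLE_ALLELE_OPTIONS[m]
                        for af in _SINGLE_ALLELE_OPTIONS[f]
                    )
                if not ok:
                    violations.append(
                        f"{family_id}/{child.individual_id} at {vk}: child {c} "
                        f"incompatible with father {f}, mother {m}"
                    )
    return violations


# --- output -------------------------------------------------------------


def write_study(study: SimulatedStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write cohort (ped_extended), genotypes (VCF), annotations (TSV),
    and the truth map (TSV) into ``out_dir``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": out_dir / "cohort.ped",
        "vcf": out_dir / "genotypes.vcf",
        "annotations": out_dir / "annotations.tsv",
        "truth": out_dir / "truth.tsv",
    }
    write_cohort(study.cohort, paths["cohort"])
    write_vcf(paths["vcf"], [v.record for v in study.variants], study.genotypes,
              study.cohort)
    write_annotations([v.annotation for v in study.variants], paths["annotations"])
    truth_lines = ["family_id\tcausal_variant_key"]
    truth_lines += [f"{fam}\t{vk}" for fam, vk in study.truth.items()]
    paths["truth"].write_text("\n".join(truth_lines) + "\n", encoding="utf-8")
    return paths
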
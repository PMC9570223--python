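"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import famseg as fs
from famseg.pedigree import SequencingTier
from famseg.variants import Consequence

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def paper_study() -> fs.SimulatedStudy:
    return fs.build_paper_fixture()


@pytest.fixture(scope="session")
def paper_selection(paper_study):
    return fs.run_cascade(paper_study.cohort, paper_study.variants,
                          paper_study.genotypes)


@pytest.fixture(scope="session")
def paper_coseg(paper_study, paper_selection):
    return fs.cosegregation_table(paper_selection, paper_study.cohort,
                                  paper_study.genotypes)


@pytest.fixture(scope="session")
def fixture_files(tmp_path_factory, paper_study):
    out = tmp_path_factory.mktemp("fixture")
    return fs.write_study(paper_study, out)


def gene_of(study: fs.SimulatedStudy, variant_key: str) -> str:
    for v in study.variants:
        if v.key == variant_key:
            return v.annotation.gene
    raise KeyError(variant_key)


# --- independent selection oracle --------------------------------------


def oracle_select(cohort, variants, gm, cfg=None) -> dict[str, list[str]]:
    """Exhaustive re-check of every cascade criterion, written directly
    from the selection rules and sharing no code with the cascade module.

    Returns {selected variant key: candidate families}.
    """
    cfg = cfg or fs.CascadeConfig()
    selected: dict[str, list[str]] = {}
    for v in variants:
        fams = []
        for fam, members in cohort.families.items():
            exome = [m for m in members if m.sequencing_tier is SequencingTier.EXOME]
            cases = [m for m in exome if m.is_case]
            unaff = [m for m in exome if m.is_unaffected]
            if len(cases) == 0 or len(unaff) == 0:
                continue
            case_calls = [gm.get(v.key, fam, m.individual_id) for m in cases]
            unaff_calls = [gm.get(v.key, fam, m.individual_id) for m in unaff]
            present = all(c is not None and c >= 1 for c in case_calls)
            absent = all(c is None or c == 0 for c in unaff_calls)
            if present and absent:
                fams.append(fam)
        a = v.annotation
        maf = 0.0 if a.maf_percent is None else a.maf_percent
        cons_ok = a.consequence in cfg.consequences_admitted
        cadd_ok = a.cadd_phred is not None and a.cadd_phred >= cfg.cadd_min
        if len(fams) >= cfg.min_recurrent_families:
            ok = maf <= cfg.maf_multi_family_max_percent and cons_ok and cadd_ok
        elif len(fams) == 1:
            ok = maf <= cfg.maf_single_family_max_percent and cons_ok and cadd_ok
        else:
            ok = False
        if ok and a.consequence is not Consequence.LOF:
            ok = bool(
                a.literature_ms_link
                or (a.variant_assoc_p is not None
                    and a.variant_assoc_p < cfg.prior_evidence_alpha)
                or (a.gene_assoc_p is not None
                    and a.gene_assoc_p < cfg.prior_evidence_alpha)
            )
        if ok:
            selected[v.key] = fams
    return selected


# --- random small instances for oracle / property checks ----------------


def random_instance(seed: int, n_families=3, n_members=6, n_variants=50):
    """A random cohort + genotypes + annotations, ≤ 3 families × 6 members
    × 50 variants, with mixed tiers, affections and missingness."""
    rng = np.random.default_rng(seed)
    cohort = fs.Cohort()
    for f in range(1, int(rng.integers(1, n_families + 1)) + 1):
        fam = f"F{f}"
        for m in range(1, int(rng.integers(2, n_members + 1)) + 1):
            cohort.add(fs.Individual(
                individual_id=f"M{m}",
                family_id=fam,
                sex=fs.Sex.MALE if rng.random() < 0.5 else fs.Sex.FEMALE,
                affected=(fs.Affection.AFFECTED if rng.random() < 0.5
                          else fs.Affection.UNAFFECTED),
                sequencing_tier=(SequencingTier.EXOME if rng.random() < 0.7
                                 else SequencingTier.TARGETED_ONLY),
            ))
    gm = fs.GenotypeMatrix()
    variants = []
    consequences = [Consequence.MISSENSE, Consequence.LOF,
                    Consequence.SYNONYMOUS, Consequence.OTHER]
    for j in range(int(rng.integers(1, n_variants + 1))):
        rec = fs.VariantRecord(chrom=str(int(rng.integers(1, 23))),
                               pos=1000 + j, ref="A", alt="T")
        anno = fs.AnnotationRecord(
            variant_key=fs.canonical_key(rec),
            gene=f"G{j}",
            consequence=consequences[int(rng.integers(4))],
            maf_percent=(None if rng.random() < 0.2
                         else float(rng.choice([0.0, 0.01, 0.05, 0.5, 1.0, 2.0]))),
            cadd_phred=(None if rng.random() < 0.1
                        else float(rng.choice([5.0, 19.9, 20.0, 25.0, 40.0]))),
            variant_assoc_p=None if rng.random() < 0.5 else float(rng.uniform(1e-4, 1)),
            gene_assoc_p=None if rng.random() < 0.5 else float(rng.uniform(1e-4, 1)),
            literature_ms_link=bool(rng.random() < 0.3),
        )
        variants.append(fs.AnnotatedVariant(record=rec, annotation=anno))
        for ind in cohort.individuals():
            u = rng.random()
            call = None if u < 0.1 else (0 if u < 0.55 else (1 if u < 0.95 else 2))
            if call == 2 and rec.chrom == "X" and ind.sex is fs.Sex.MALE:
                call = 1
            gm.set_call(fs.canonical_key(rec), ind.family_id,
                        ind.individual_id, call)
    return cohort, variants, gm
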
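"""Two-strategy candidate-variant selection cascade for multiplex families.

Stage 1 is per-family: on the exome-sequenced members only, a variant is
a candidate in a family when it is present (allele count ≥ 1) in every
sequenced case and absent in every sequenced unaffected member. Stage 2
applies two complementary strategies over candidate families:

* multi-family — variants recurring in ≥ 2 candidate families, with
  population MAF ≤ 1%;
* single-family — variants with exactly one candidate family, held to a
  stricter MAF ≤ 0.05%.

Both strategies admit only missense and putative loss-of-function
consequences and require a CADD deleteriousness score ≥ 20. Finally a
prior-evidence gate retains a missense variant only when it has a
literature link to the disease, or a variant-level (exome-chip) or
gene-level (gene-wide GWAS) association p-value below alpha; LoF
variants pass the gate unconditionally.

Missing-genotype conventions are conservative for cases: a missing call
in a sequenced case voids the presence flag, while absence among
unaffected members is judged over non-missing calls only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from .errors import ValidationError
from .pedigree import Cohort, SequencingTier
from .variants import AnnotatedVariant, Consequence, GenotypeMatrix

PASS, FAIL, NOT_APPLICABLE = "pass", "fail", "not_applicable"


class Strategy(str, Enum):
    MULTI_FAMILY = "multi_family"
    SINGLE_FAMILY = "single_family"


@dataclass(frozen=True)
class PresencePattern:
    """Per-(variant, family) case-present / control-absent flags.

    Computed over exome-sequenced members only. Both flags are forced
    false when the family has no sequenced case or no sequenced
    unaffected member; the counts record why.
    """

    variant_key: str
    family_id: str
    present_in_all_sequenced_cases: bool
    absent_in_all_sequenced_unaffected: bool
    n_sequenced_cases: int
    n_sequenced_unaffected: int

    @property
    def qualifies(self) -> bool:
        return (self.present_in_all_sequenced_cases
                and self.absent_in_all_sequenced_unaffected)


@dataclass(frozen=True)
class CascadeConfig:
    maf_multi_family_max_percent: float = 1.0
    maf_single_family_max_percent: float = 0.05
    cadd_min: float = 20.0
    min_recurrent_families: int = 2
    prior_evidence_alpha: float = 0.05
    consequences_admitted: frozenset[Consequence] = frozenset(
        {Consequence.MISSENSE, Consequence.LOF}
    )

    def __post_init__(self):
        for name in ("maf_multi_family_max_percent", "maf_single_family_max_percent",
                     "cadd_min"):
            if getattr(self, name) <= 0 and not math.isinf(getattr(self, name)):
                raise ValidationError(f"{name} must be strictly positive")
        if self.min_recurrent_families < 1:
            raise ValidationError("min_recurrent_families must be ≥ 1")
        if not (0.0 < self.prior_evidence_alpha < 1.0):
            raise ValidationError("prior_evidence_alpha must lie in (0, 1)")


@dataclass
class SelectionResult:
    variant: AnnotatedVariant
    strategy: Strategy
    contributing_families: list[str]
    criteria_trace: dict[str, str] = field(default_factory=dict)

    @property
    def key(self) -> str:
        return self.variant.key


# --- stage 1: per-family presence patterns ------------------------------


def presence_pattern(variant_key: str, family_id: str, cohort: Cohort,
                     gm: GenotypeMatrix) -> PresencePattern:
    """Compute the case-present / control-absent pattern on the WES subset."""
    if family_id not in cohort.families:
        raise ValidationError(f"unknown family {family_id!r}")
    exome = [m for m in cohort.members(family_id)
             if m.sequencing_tier is SequencingTier.EXOME]
    cases = [m for m in exome if m.is_case]
    unaffected = [m for m in exome if m.is_unaffected]
    if not cases or not unaffected:
        return PresencePattern(variant_key, family_id, False, False,
                               len(cases), len(unaffected))
    present = True
    for m in cases:
        count = gm.get(variant_key, family_id, m.individual_id)
        if count is None or count < 1:  # missing in a sequenced case voids presence
            present = False
            break
    absent = True
    for m in unaffected:
        count = gm.get(variant_key, family_id, m.individual_id)
        if count is not None and count >= 1:
            absent = False
            break
    return PresencePattern(variant_key, family_id, present, absent,
                           len(cases), len(unaffected))


def candidate_families(variant_key: str, cohort: Cohort,
                       gm: GenotypeMatrix) -> list[str]:
    """Families whose presence pattern qualifies, in stable cohort order."""
    return [
        fam for fam in cohort.families
        if presence_pattern(variant_key, fam, cohort, gm).qualifies
    ]


def compute_patterns(
    variants: Iterable[AnnotatedVariant], cohort: Cohort, gm: GenotypeMatrix
) -> dict[str, list[PresencePattern]]:
    """Presence patterns for every variant × family, keyed by variant."""
    return {
        v.key: [presence_pattern(v.key, fam, cohort, gm) for fam in cohort.families]
        for v in variants
    }


# --- stage 2: strategies ------------------------------------------------


def _effective_maf(v: AnnotatedVariant) -> float:
    # novel variants (absent MAF) trivially satisfy any MAF ceiling
    maf = v.annotation.maf_percent
    return 0.0 if maf is None else maf


def _consequence_cadd_trace(v: AnnotatedVariant, cfg: CascadeConfig,
                            trace: dict[str, str]) -> None:
    cons = v.annotation.consequence
    trace["consequence"] = PASS if cons in cfg.consequences_admitted else FAIL
    cadd = v.annotation.cadd_phred
    trace["cadd"] = PASS if (cadd is not None and cadd >= cfg.cadd_min) else FAIL


def examine_variant(
    v: AnnotatedVariant,
    candidate_fams: Sequence[str],
    cfg: CascadeConfig,
    strategy: Strategy,
) -> SelectionResult:
    """Evaluate every criterion of one strategy for one variant.

    All criteria are evaluated (no short-circuit) so the trace of a
    rejected variant records every failure; the prior-evidence entry
    stays ``not_applicable`` until the gate runs.
    """
    trace: dict[str, str] = {}
    if strategy is Strategy.MULTI_FAMILY:
        trace["recurrent_families"] = (
            PASS if len(candidate_fams) >= cfg.min_recurrent_families else FAIL
        )
        maf_max = cfg.maf_multi_family_max_percent
    else:
        # complement of the recurrence rule: exactly one candidate family
        trace["single_candidate_family"] = PASS if len(candidate_fams) == 1 else FAIL
        maf_max = cfg.maf_single_family_max_percent
    trace["maf"] = PASS if _effective_maf(v) <= maf_max else FAIL
    _consequence_cadd_trace(v, cfg, trace)
    trace["prior_evidence"] = NOT_APPLICABLE  # applied by the gate
    return SelectionResult(
        variant=v, strategy=strategy,
        contributing_families=list(candidate_fams), criteria_trace=trace,
    )


def passes_trace(result: SelectionResult) -> bool:
    return all(status != FAIL for status in result.criteria_trace.values())


def _run_strategy(
    variants: Iterable[AnnotatedVariant],
    patterns: Mapping[str, Sequence[PresencePattern]],
    cfg: CascadeConfig,
    strategy: Strategy,
) -> list[SelectionResult]:
    results = []
    for v in variants:
        fams = [p.family_id for p in patterns.get(v.key, ()) if p.qualifies]
        result = examine_variant(v, fams, cfg, strategy)
        if passes_trace(result):
            results.append(result)
    return results


def strategy_multi_family(
    variants: Iterable[AnnotatedVariant],
    patterns: Mapping[str, Sequence[PresencePattern]],
    cfg: CascadeConfig,
) -> list[SelectionResult]:
    """Variants recurring in ≥ 2 candidate families at the 1% MAF ceiling."""
    return _run_strategy(variants, patterns, cfg, Strategy.MULTI_FAMILY)


def strategy_single_family(
    variants: Iterable[AnnotatedVariant],
    patterns: Mapping[str, Sequence[PresencePattern]],
    cfg: CascadeConfig,
) -> list[SelectionResult]:
    """Variants private to one candidate family at the 0.05% MAF ceiling."""
    return _run_strategy(variants, patterns, cfg, Strategy.SINGLE_FAMILY)


# --- stage 3: prior-evidence gate ---------------------------------------


def prior_evidence_gate(selected: Iterable[SelectionResult],
                        cfg: CascadeConfig) -> list[SelectionResult]:
    """Retain missense variants with prior disease evidence; LoF pass freely.

    Evidence sources, any of which suffices: a curated literature link,
    a variant-level association p-value < alpha, or a gene-level
    association p-value < alpha. The trace records which source fired.
    """
    out = []
    for res in selected:
        anno = res.variant.annotation
        if anno.consequence is Consequence.LOF:
            res.criteria_trace["prior_evidence"] = NOT_APPLICABLE
            out.append(res)
            continue
        sources = []
        if anno.literature_ms_link:
            sources.append("literature")
        if anno.variant_assoc_p is not None and anno.variant_assoc_p < cfg.prior_evidence_alpha:
            sources.append("variant_assoc")
        if anno.gene_assoc_p is not None and anno.gene_assoc_p < cfg.prior_evidence_alpha:
            sources.append("gene_assoc")
        if sources:
            res.criteria_trace["prior_evidence"] = PASS
            res.criteria_trace["prior_evidence_source"] = "+".join(sources)
            out.append(res)
        else:
            res.criteria_trace["prior_evidence"] = FAIL
    return out


# --- full cascade -------------------------------------------------------

_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25, "M": 25}


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Natural genomic chromosome order: 1..22, X, Y, MT, then others."""
    return (_CHROM_ORDER.get(chrom, 99), chrom)


def run_cascade(cohort: Cohort, variants: Sequence[AnnotatedVariant],
                gm: GenotypeMatrix,
                cfg: Optional[CascadeConfig] = None) -> list[SelectionResult]:
    """Run both strategies and the prior-evidence gate; return the union.

    Deduplicated by canonical variant key with merged contributing
    families, ordered by (chromosome, position).
    """
    cfg = cfg or CascadeConfig()
    patterns = compute_patterns(variants, cohort, gm)
    pooled = (strategy_multi_family(variants, patterns, cfg)
              + strategy_single_family(variants, patterns, cfg))
    gated = prior_evidence_gate(pooled, cfg)
    by_key: dict[str, SelectionResult] = {}
    for res in gated:
        prev = by_key.get(res.key)
        if prev is None:
            by_key[res.key] = res
        else:
            merged = list(dict.fromkeys(prev.contributing_families
                                        + res.contributing_families))
            prev.contributing_families = merged
    return sorted(
        by_key.values(),
        key=lambda r: (chrom_sort_key(r.variant.record.chrom), r.variant.record.pos,
                       r.variant.record.ref, r.variant.record.alt),
    )
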
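"""Co-segregation of selected variants with disease across whole families.

Unlike the selection cascade, which sees only exome-sequenced members,
this stage counts carriers among *all* genotyped family members (exome
plus targeted follow-up genotyping), pooled over the families in which a
variant was selected. Carrier fractions are kept as exact rationals;
display percentages are cosmetic (round-half-up) and never used for
classification.

Classification rule:

* ``complete``   — carried by every genotyped case and no genotyped
  unaffected member (case fraction 1, unaffected fraction 0);
* ``acceptable`` — carried by every genotyped case and by at most one
  third of genotyped unaffected members (0 < unaffected fraction ≤ 1/3,
  compared exactly);
* ``failed``     — anything else.

The 1/3 boundary is inclusive: a variant carried by exactly one of three
unaffected members still classifies as acceptable.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from typing import Optional, Sequence

from .cascade import SelectionResult
from .errors import ValidationError
from .pedigree import Cohort, Sex
from .variants import GenotypeMatrix

ACCEPTABLE_MAX_UNAFFECTED_FRACTION = Fraction(1, 3)


class Classification(str, Enum):
    COMPLETE = "complete"
    ACCEPTABLE = "acceptable"
    FAILED = "failed"


@dataclass(frozen=True)
class SegregationCounts:
    variant_key: str
    contributing_families: tuple[str, ...]
    per_family: dict[str, tuple[int, int, int, int]]
    # per family: (case_carriers, case_genotyped, unaffected_carriers, unaffected_genotyped)
    pooled_case_carriers: int
    pooled_case_genotyped: int
    pooled_unaffected_carriers: int
    pooled_unaffected_genotyped: int


@dataclass(frozen=True)
class SegregationResult:
    counts: SegregationCounts
    case_fraction: Fraction
    unaffected_fraction: Fraction
    case_percent_display: int
    unaffected_percent_display: int
    classification: Classification


def carrier(allele_count: Optional[int], sex: Sex, chrom: str) -> Optional[bool]:
    """True iff at least one alternate allele; missing propagates."""
    if allele_count is None:
        return None
    return allele_count >= 1


def segregation_counts(variant_key: str, families: Sequence[str],
                       cohort: Cohort, gm: GenotypeMatrix) -> SegregationCounts:
    """Carrier counts over all genotyped members of the given families.

    Members with a missing call at the site are excluded from both the
    numerator and the denominator.
    """
    if not families:
        raise ValidationError("families must be nonempty")
    per_family: dict[str, tuple[int, int, int, int]] = {}
    for fam in families:
        if fam not in cohort.families:
            raise ValidationError(f"unknown family {fam!r}")
        cc = cg = uc = ug = 0
        n_genotyped = 0
        for m in cohort.members(fam):
            is_carrier = carrier(gm.get(variant_key, fam, m.individual_id), m.sex,
                                 variant_key.split(":", 1)[0])
            if is_carrier is None:
                continue
            n_genotyped += 1
            if m.is_case:
                cg += 1
                cc += int(is_carrier)
            elif m.is_unaffected:
                ug += 1
                uc += int(is_carrier)
        if n_genotyped == 0:
            raise ValidationError(
                f"family {fam!r} has no genotyped member at {variant_key}"
            )
        per_family[fam] = (cc, cg, uc, ug)
    return SegregationCounts(
        variant_key=variant_key,
        contributing_families=tuple(families),
        per_family=per_family,
        pooled_case_carriers=sum(v[0] for v in per_family.values()),
        pooled_case_genotyped=sum(v[1] for v in per_family.values()),
        pooled_unaffected_carriers=sum(v[2] for v in per_family.values()),
        pooled_unaffected_genotyped=sum(v[3] for v in per_family.values()),
    )


def percent_display(fraction: Fraction) -> int:
    """Round-half-up of 100 × fraction to the nearest integer."""
    if not (0 <= fraction <= 1):
        raise ValidationError(f"fraction {fraction} outside [0, 1]")
    return int(100 * fraction + Fraction(1, 2))


def classify(case_fraction: Fraction,
             unaffected_fraction: Fraction) -> Classification:
    """Apply the complete/acceptable/failed rule on exact fractions."""
    if case_fraction == 1 and unaffected_fraction == 0:
        return Classification.COMPLETE
    if case_fraction == 1 and 0 < unaffected_fraction <= ACCEPTABLE_MAX_UNAFFECTED_FRACTION:
        return Classification.ACCEPTABLE
    return Classification.FAILED


def segregation_result(counts: SegregationCounts) -> SegregationResult:
    if counts.pooled_case_genotyped == 0:
        raise ValidationError(
            f"no genotyped cases for {counts.variant_key} in families "
            f"{counts.contributing_families}"
        )
    case_fraction = Fraction(counts.pooled_case_carriers, counts.pooled_case_genotyped)
    if counts.pooled_unaffected_genotyped == 0:
        unaffected_fraction = Fraction(0)
    else:
        unaffected_fraction = Fraction(counts.pooled_unaffected_carriers,
                                       counts.pooled_unaffected_genotyped)
    return SegregationResult(
        counts=counts,
        case_fraction=case_fraction,
        unaffected_fraction=unaffected_fraction,
        case_percent_display=percent_display(case_fraction),
        unaffected_percent_display=percent_display(unaffected_fraction),
        classification=classify(case_fraction, unaffected_fraction),
    )


def cosegregation_table(selected: Sequence[SelectionResult], cohort: Cohort,
                        gm: GenotypeMatrix) -> list[SegregationResult]:
    """One pooled segregation row per selected variant, in selection order."""
    return [
        segregation_result(
            segregation_counts(res.key, res.contributing_families, cohort, gm)
        )
        for res in selected
    ]
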
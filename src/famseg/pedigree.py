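"""Pedigree cohorts: reading, validation, and clinical roll-up summaries.

A cohort is a set of multi-incident disease families. Each family member
carries affection status, disease subtype, ages at diagnosis and at DNA
collection, and a sequencing tier: ``exome`` for members with whole-exome
data (used by the variant selection stage), ``targeted_only`` for members
genotyped only at candidate sites (used by the co-segregation stage), and
``none`` for members with no DNA.

The on-disk format is a tab-separated extension of the classic 6-column
PED file (``ped_extended``): family, individual, father, mother, sex,
affection, subtype, age at diagnosis, age at DNA collection, sequencing
tier. ``.``/empty/``0`` encode missing values; standard 6-column PED is
accepted for interchange with the simulator.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional

from .errors import ParseError, ValidationError


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(str, Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class Subtype(str, Enum):
    """Disease subtype of an affected member.

    ``NA`` is an explicit category (diagnosed, course undetermined) and is
    counted as such in summaries; ``NONE`` marks unaffected members.
    """

    RRMS = "RRMS"
    SPMS = "SPMS"
    PPMS = "PPMS"
    NA = "NA"
    NONE = "none"


class SequencingTier(str, Enum):
    EXOME = "exome"
    TARGETED_ONLY = "targeted_only"
    NONE = "none"


@dataclass(frozen=True)
class Individual:
    individual_id: str
    family_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: Sex = Sex.UNKNOWN
    affected: Affection = Affection.UNKNOWN
    subtype: Subtype = Subtype.NONE
    age_at_diagnosis_years: Optional[float] = None
    age_at_dna_collection_years: Optional[float] = None
    sequencing_tier: SequencingTier = SequencingTier.NONE

    @property
    def is_case(self) -> bool:
        return self.affected is Affection.AFFECTED

    @property
    def is_unaffected(self) -> bool:
        return self.affected is Affection.UNAFFECTED


@dataclass
class Cohort:
    """Families keyed by family id; member order is roster order."""

    families: dict[str, list[Individual]] = field(default_factory=dict)

    def individuals(self) -> Iterator[Individual]:
        for members in self.families.values():
            yield from members

    def get(self, family_id: str, individual_id: str) -> Individual:
        for ind in self.families[family_id]:
            if ind.individual_id == individual_id:
                return ind
        raise KeyError((family_id, individual_id))

    def members(self, family_id: str) -> list[Individual]:
        return self.families[family_id]

    @property
    def n_individuals(self) -> int:
        return sum(len(m) for m in self.families.values())

    def add(self, individual: Individual) -> None:
        members = self.families.setdefault(individual.family_id, [])
        if any(m.individual_id == individual.individual_id for m in members):
            raise ValidationError(
                f"duplicate individual {individual.individual_id!r} "
                f"in family {individual.family_id!r}"
            )
        members.append(individual)


@dataclass
class CohortSummary:
    n_total: int
    n_affected: int
    n_unaffected: int
    n_exome: int
    n_targeted_only: int
    subtype_counts: dict[Subtype, int]
    mean_age_dna_cases: Optional[float]
    sd_age_dna_cases: Optional[float]
    mean_age_dna_unaffected: Optional[float]
    sd_age_dna_unaffected: Optional[float]
    mean_age_onset: Optional[float]
    sd_age_onset: Optional[float]
    sex_ratio_cases: tuple[int, int]
    sex_ratio_unaffected: tuple[int, int]


@dataclass(frozen=True)
class Violation:
    """A single data-contract violation; violations are data, not exceptions."""

    family_id: str
    individual_id: str
    rule: str
    message: str


# --- parsing -----------------------------------------------------------

_MISSING = {"", ".", "0", "-", "NA"}

_SEX_CODES = {
    "male": Sex.MALE, "m": Sex.MALE, "1": Sex.MALE,
    "female": Sex.FEMALE, "f": Sex.FEMALE, "2": Sex.FEMALE,
    "unknown": Sex.UNKNOWN, "0": Sex.UNKNOWN, "u": Sex.UNKNOWN,
}

_AFFECTION_CODES = {
    "affected": Affection.AFFECTED, "2": Affection.AFFECTED, "yes": Affection.AFFECTED,
    "unaffected": Affection.UNAFFECTED, "1": Affection.UNAFFECTED, "no": Affection.UNAFFECTED,
    "unknown": Affection.UNKNOWN, "0": Affection.UNKNOWN, "-9": Affection.UNKNOWN,
}

_TIER_CODES = {
    "exome": SequencingTier.EXOME,
    "targeted_only": SequencingTier.TARGETED_ONLY,
    "targeted": SequencingTier.TARGETED_ONLY,
    "none": SequencingTier.NONE,
}


def _opt(token: str) -> Optional[str]:
    return None if token.strip() in _MISSING else token.strip()


def _opt_float(token: str, path: str, lineno: int, what: str) -> Optional[float]:
    tok = _opt(token)
    if tok is None:
        return None
    try:
        return float(tok)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: bad {what} value {token!r}") from None


def _code(token: str, table: dict, path: str, lineno: int, what: str):
    try:
        return table[token.strip().lower()]
    except KeyError:
        raise ParseError(f"{path}:{lineno}: bad {what} code {token!r}") from None


def read_cohort(path: str | Path, dialect: str = "ped_extended") -> Cohort:
    """Read a cohort from a PED-like file.

    ``ped_extended`` expects ≥ 10 tab-separated columns per row; ``ped6``
    the classic six. Returns a validated :class:`Cohort`; any violation of
    the data contracts raises :class:`ValidationError`.
    """
    if dialect not in ("ped6", "ped_extended"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    min_cols = 10 if dialect == "ped_extended" else 6
    cohort = Cohort()
    n_rows = 0
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise ParseError(
                    f"{path}:{lineno}: expected ≥ {min_cols} tab-separated "
                    f"columns, got {len(fields)}"
                )
            fam, iid = fields[0].strip(), fields[1].strip()
            if not fam or not iid:
                raise ParseError(f"{path}:{lineno}: empty family or individual id")
            affected = _code(fields[5], _AFFECTION_CODES, str(path), lineno, "affection")
            if dialect == "ped_extended":
                # "NA" is a real subtype category (diagnosed, course unknown),
                # never missing data
                subtype_tok = fields[6].strip()
                if subtype_tok in ("", ".", "-") or subtype_tok.lower() == "none":
                    subtype = Subtype.NONE
                else:
                    try:
                        subtype = Subtype(subtype_tok.upper())
                    except ValueError:
                        raise ParseError(
                            f"{path}:{lineno}: bad subtype {fields[6]!r}"
                        ) from None
                age_dx = _opt_float(fields[7], str(path), lineno, "age at diagnosis")
                age_dna = _opt_float(fields[8], str(path), lineno, "age at DNA collection")
                tier = _code(fields[9], _TIER_CODES, str(path), lineno, "sequencing tier")
            else:
                subtype, age_dx, age_dna, tier = Subtype.NONE, None, None, SequencingTier.NONE
            ind = Individual(
                individual_id=iid,
                family_id=fam,
                father_id=_opt(fields[2]),
                mother_id=_opt(fields[3]),
                sex=_code(fields[4], _SEX_CODES, str(path), lineno, "sex"),
                affected=affected,
                subtype=subtype,
                age_at_diagnosis_years=age_dx,
                age_at_dna_collection_years=age_dna,
                sequencing_tier=tier,
            )
            try:
                cohort.add(ind)
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
            n_rows += 1
    if n_rows == 0:
        raise ParseError(f"{path}: no individuals found")
    violations = validate_cohort(cohort)
    if violations:
        first = violations[0]
        raise ValidationError(
            f"{path}: {len(violations)} violation(s); first: "
            f"family {first.family_id} individual {first.individual_id}: {first.message}"
        )
    return cohort


_SEX_OUT = {Sex.MALE: "male", Sex.FEMALE: "female", Sex.UNKNOWN: "unknown"}
_AFF_OUT = {Affection.AFFECTED: "affected", Affection.UNAFFECTED: "unaffected",
            Affection.UNKNOWN: "unknown"}


def _fmt_age(age: Optional[float]) -> str:
    if age is None:
        return "."
    return str(int(age)) if float(age).is_integer() else repr(age)


def write_cohort(cohort: Cohort, path: str | Path, dialect: str = "ped_extended") -> None:
    """Write a cohort in ``ped_extended`` (default) or classic ``ped6`` form."""
    if dialect not in ("ped6", "ped_extended"):
        raise ValueError(f"unknown dialect {dialect!r}")
    lines = []
    for ind in cohort.individuals():
        row = [
            ind.family_id,
            ind.individual_id,
            ind.father_id or ".",
            ind.mother_id or ".",
            _SEX_OUT[ind.sex],
            _AFF_OUT[ind.affected],
        ]
        if dialect == "ped_extended":
            row += [
                ind.subtype.value,
                _fmt_age(ind.age_at_diagnosis_years),
                _fmt_age(ind.age_at_dna_collection_years),
                ind.sequencing_tier.value,
            ]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# --- validation --------------------------------------------------------


def validate_cohort(cohort: Cohort) -> list[Violation]:
    """Check every data contract; return one descriptor per violation."""
    out: list[Violation] = []
    for family_id, members in cohort.families.items():
        by_id = {m.individual_id: m for m in members}
        for ind in members:
            if ind.is_unaffected and ind.subtype is not Subtype.NONE:
                out.append(Violation(
                    family_id, ind.individual_id, "affection_subtype",
                    f"unaffected individual has subtype {ind.subtype.value}",
                ))
            if (
                ind.age_at_diagnosis_years is not None
                and ind.age_at_dna_collection_years is not None
                and ind.age_at_diagnosis_years > ind.age_at_dna_collection_years
            ):
                out.append(Violation(
                    family_id, ind.individual_id, "age_order",
                    "age at diagnosis exceeds age at DNA collection",
                ))
            for label, pid in (("father", ind.father_id), ("mother", ind.mother_id)):
                if pid is not None and pid not in by_id:
                    out.append(Violation(
                        family_id, ind.individual_id, "unknown_parent",
                        f"{label} id {pid!r} not in family {family_id}",
                    ))
        # ancestor cycles, over the parent links that resolve
        for ind in members:
            seen: set[str] = set()
            frontier = [p for p in (ind.father_id, ind.mother_id) if p in by_id]
            cyclic = False
            while frontier and not cyclic:
                pid = frontier.pop()
                if pid == ind.individual_id:
                    cyclic = True
                    break
                if pid in seen:
                    continue
                seen.add(pid)
                parent = by_id[pid]
                frontier += [p for p in (parent.father_id, parent.mother_id) if p in by_id]
            if cyclic:
                out.append(Violation(
                    family_id, ind.individual_id, "ancestor_cycle",
                    "individual is its own ancestor",
                ))
    return out


# --- summaries ---------------------------------------------------------


def _mean_sd(values: list[float]) -> tuple[Optional[float], Optional[float]]:
    # sample SD (n-1); absent, not zero, when too few observations
    if not values:
        return None, None
    mean = statistics.fmean(values)
    sd = statistics.stdev(values) if len(values) >= 2 else None
    return mean, sd


def _sex_ratio(inds: Iterable[Individual]) -> tuple[int, int]:
    males = sum(1 for i in inds if i.sex is Sex.MALE)
    females = sum(1 for i in inds if i.sex is Sex.FEMALE)
    return males, females


def summarize_cohort(cohort: Cohort) -> CohortSummary:
    """Roll up the clinical characteristics of a cohort.

    Means and SDs are computed over individuals with the relevant field
    present; the SD uses the n−1 denominator. Sex ratios are reported as
    raw (male, female) count pairs rather than normalized ratios.
    """
    inds = list(cohort.individuals())
    cases = [i for i in inds if i.is_case]
    unaffected = [i for i in inds if i.is_unaffected]
    subtype_counts = {s: 0 for s in (Subtype.RRMS, Subtype.SPMS, Subtype.PPMS, Subtype.NA)}
    for i in cases:
        if i.subtype in subtype_counts:
            subtype_counts[i.subtype] += 1
    mean_dna_c, sd_dna_c = _mean_sd(
        [i.age_at_dna_collection_years for i in cases if i.age_at_dna_collection_years is not None]
    )
    mean_dna_u, sd_dna_u = _mean_sd(
        [i.age_at_dna_collection_years for i in unaffected
         if i.age_at_dna_collection_years is not None]
    )
    mean_onset, sd_onset = _mean_sd(
        [i.age_at_diagnosis_years for i in cases if i.age_at_diagnosis_years is not None]
    )
    return CohortSummary(
        n_total=len(inds),
        n_affected=len(cases),
        n_unaffected=len(unaffected),
        n_exome=sum(1 for i in inds if i.sequencing_tier is SequencingTier.EXOME),
        n_targeted_only=sum(
            1 for i in inds if i.sequencing_tier is SequencingTier.TARGETED_ONLY
        ),
        subtype_counts=subtype_counts,
        mean_age_dna_cases=mean_dna_c,
        sd_age_dna_cases=sd_dna_c,
        mean_age_dna_unaffected=mean_dna_u,
        sd_age_dna_unaffected=sd_dna_u,
        mean_age_onset=mean_onset,
        sd_age_onset=sd_onset,
        sex_ratio_cases=_sex_ratio(cases),
        sex_ratio_unaffected=_sex_ratio(unaffected),
    )
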
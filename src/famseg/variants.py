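"""Variant genotypes (VCF) and annotations (TSV), joined on a canonical key.

Genotypes arrive as VCF v4.2 with GT calls; samples are named
``FAMILY_INDIVIDUAL`` and must resolve to cohort members. Annotations —
gene symbol, consequence class, population minor-allele frequency on the
percent scale, phred-scaled CADD deleteriousness score, variant- and
gene-level association p-values, and a literature-link flag — arrive as a
TSV keyed by the canonical ``chrom:pos:ref>alt`` string. MAF and CADD are
consumed as annotation, never recomputed here.

X-chromosome calls for males are normalized to {0, 1}: a diploid-coded
male X call of 2 is coerced to 1 (a warning summarizes how many calls
were coerced per file).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

from cyvcf2 import VCF

from .errors import ParseError, ValidationError
from .pedigree import Cohort, Individual, Sex

logger = logging.getLogger(__name__)


class VariantClass(str, Enum):
    SNV = "snv"
    DELETION = "deletion"
    INSERTION = "insertion"
    OTHER = "other"


class Consequence(str, Enum):
    MISSENSE = "missense"
    LOF = "lof"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


def _normalize_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def _infer_class(ref: str, alt: str) -> VariantClass:
    if len(ref) == 1 and len(alt) == 1:
        return VariantClass.SNV
    if len(ref) > len(alt):
        return VariantClass.DELETION
    if len(ref) < len(alt):
        return VariantClass.INSERTION
    return VariantClass.OTHER


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based, VCF-style; deletions carry anchored ref/alt alleles
    ref: str
    alt: str
    variant_id: Optional[str] = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"position must be ≥ 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"ref equals alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        object.__setattr__(self, "chrom", _normalize_chrom(self.chrom))

    @property
    def variant_class(self) -> VariantClass:
        return _infer_class(self.ref, self.alt)


def canonical_key(v: VariantRecord) -> str:
    """Deterministic ``chrom:pos:ref>alt`` key; chrom without ``chr`` prefix."""
    return f"{v.chrom}:{v.pos}:{v.ref}>{v.alt}"


@dataclass(frozen=True)
class AnnotationRecord:
    variant_key: str
    gene: Optional[str] = None
    consequence: Optional[Consequence] = None
    maf_percent: Optional[float] = None  # percent scale: "≤1%" means ≤ 1.0
    cadd_phred: Optional[float] = None
    variant_assoc_p: Optional[float] = None
    gene_assoc_p: Optional[float] = None
    literature_ms_link: bool = False
    protein_change: Optional[str] = None

    def __post_init__(self):
        if self.maf_percent is not None and not (0.0 <= self.maf_percent <= 100.0):
            raise ValidationError(
                f"maf_percent {self.maf_percent} outside [0, 100] for {self.variant_key}"
            )
        for name in ("variant_assoc_p", "gene_assoc_p"):
            p = getattr(self, name)
            if p is not None and not (0.0 < p <= 1.0):
                raise ValidationError(f"{name} {p} outside (0, 1] for {self.variant_key}")


@dataclass(frozen=True)
class AnnotatedVariant:
    record: VariantRecord
    annotation: AnnotationRecord

    def __post_init__(self):
        if self.annotation.variant_key != canonical_key(self.record):
            raise ValidationError(
                f"annotation key {self.annotation.variant_key!r} does not match "
                f"variant {canonical_key(self.record)!r}"
            )

    @property
    def key(self) -> str:
        return canonical_key(self.record)


MISSING = None  # genotype sentinel


class GenotypeMatrix:
    """Allele counts keyed by (variant_key, family_id, individual_id).

    A stored ``None`` is an attempted-but-missing call ("./."); an absent
    key means the individual was never genotyped at that site. Both read
    back as ``None`` via :meth:`get`.
    """

    def __init__(self) -> None:
        self._calls: dict[tuple[str, str, str], Optional[int]] = {}

    def set_call(self, variant_key: str, family_id: str, individual_id: str,
                 allele_count: Optional[int]) -> None:
        if allele_count is not None and allele_count not in (0, 1, 2):
            raise ValidationError(f"allele count {allele_count} not in {{0, 1, 2}}")
        self._calls[(variant_key, family_id, individual_id)] = allele_count

    def get(self, variant_key: str, family_id: str, individual_id: str) -> Optional[int]:
        return self._calls.get((variant_key, family_id, individual_id))

    def has_call(self, variant_key: str, family_id: str, individual_id: str) -> bool:
        return self._calls.get((variant_key, family_id, individual_id)) is not None

    def variant_keys(self) -> list[str]:
        seen: dict[str, None] = {}
        for (vk, _, _) in self._calls:
            seen.setdefault(vk)
        return list(seen)

    def items(self):
        return self._calls.items()

    def __len__(self) -> int:
        return len(self._calls)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenotypeMatrix) and self._calls == other._calls


# --- VCF ----------------------------------------------------------------


def _sample_map(cohort: Cohort) -> dict[str, Individual]:
    return {
        f"{ind.family_id}_{ind.individual_id}": ind
        for ind in cohort.individuals()
    }


def read_vcf(path: str | Path, cohort: Cohort) -> tuple[list[VariantRecord], GenotypeMatrix]:
    """Read GT genotypes for a cohort from a VCF.

    Multi-allelic sites are split into one biallelic record per ALT
    allele; an individual's allele count for a split record is the number
    of that ALT among their called alleles. ``./.`` maps to missing.
    """
    path = str(path)
    vcf = VCF(path, gts012=False)
    smap = _sample_map(cohort)
    unmatched = [s for s in vcf.samples if s not in smap]
    if unmatched:
        raise ValidationError(
            f"{path}: VCF samples not present in cohort: {', '.join(sorted(unmatched))}"
        )
    samples = [smap[s] for s in vcf.samples]
    records: list[VariantRecord] = []
    gm = GenotypeMatrix()
    n_coerced = 0
    for rec in vcf:
        chrom = _normalize_chrom(rec.CHROM)
        genotypes = rec.genotypes  # [a1, a2, ..., phased]
        for alt_index, alt in enumerate(rec.ALT, start=1):
            vr = VariantRecord(
                chrom=chrom, pos=rec.POS, ref=rec.REF, alt=alt,
                variant_id=rec.ID if rec.ID not in (None, ".") else None,
            )
            vk = canonical_key(vr)
            records.append(vr)
            for ind, gt in zip(samples, genotypes):
                alleles = [a for a in gt[:-1] if a != -1]
                if not alleles:
                    count: Optional[int] = None
                elif len(alleles) < len(gt) - 1:
                    # partially missing call treated as missing
                    count = None
                else:
                    count = sum(1 for a in alleles if a == alt_index)
                if (
                    count == 2 and chrom == "X" and ind.sex is Sex.MALE
                ):
                    count = 1
                    n_coerced += 1
                gm.set_call(vk, ind.family_id, ind.individual_id, count)
    if n_coerced:
        logger.warning(
            "%s: coerced %d diploid-coded male X calls from 2 to 1", path, n_coerced
        )
    return records, gm


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=famseg
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(path: str | Path, variants: Iterable[VariantRecord],
              gm: GenotypeMatrix, cohort: Cohort) -> None:
    """Write biallelic GT-only VCF for all cohort members, in input order.

    Male X carriers are written as ``1/1`` (diploid-coded hemizygous);
    :func:`read_vcf` re-normalizes them to allele count 1.
    """
    inds = list(cohort.individuals())
    sample_names = [f"{i.family_id}_{i.individual_id}" for i in inds]
    variants = list(variants)
    lines = [_VCF_HEADER.rstrip("\n")]
    for chrom in dict.fromkeys(v.chrom for v in variants):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_names)
    )
    gt_repr = {0: "0/0", 1: "0/1", None: "./."}
    for v in variants:
        vk = canonical_key(v)
        calls = []
        for ind in inds:
            count = gm.get(vk, ind.family_id, ind.individual_id)
            calls.append("1/1" if count == 2 or (
                count == 1 and v.chrom == "X" and ind.sex is Sex.MALE
            ) else gt_repr[count])
        lines.append("\t".join([
            v.chrom, str(v.pos), v.variant_id or ".", v.ref, v.alt,
            ".", "PASS", ".", "GT", *calls,
        ]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# --- annotations --------------------------------------------------------

_ANNOTATION_COLUMNS = [
    "variant_key", "gene", "consequence", "maf_percent", "cadd_phred",
    "variant_assoc_p", "gene_assoc_p", "literature_ms_link", "protein_change",
]

_BOOL_CODES = {"1": True, "true": True, "yes": True,
               "0": False, "false": False, "no": False, "": False, ".": False}


def _tsv_opt_float(token: str) -> Optional[float]:
    token = token.strip()
    if token in ("", "."):
        return None
    return float(token)


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read an annotation TSV; ``.``/empty cells become absent values."""
    path = Path(path)
    out: list[AnnotationRecord] = []
    with open(path, "rt", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "variant_key" not in reader.fieldnames:
            raise ParseError(f"{path}: missing header with 'variant_key' column")
        for lineno, row in enumerate(reader, start=2):
            def _opt_str(col: str):
                tok = (row.get(col) or "").strip()
                return None if tok in ("", ".") else tok

            try:
                cons_tok = (row.get("consequence") or "").strip()
                out.append(AnnotationRecord(
                    variant_key=row["variant_key"].strip(),
                    gene=_opt_str("gene"),
                    consequence=Consequence(cons_tok) if cons_tok not in ("", ".") else None,
                    maf_percent=_tsv_opt_float(row.get("maf_percent") or ""),
                    cadd_phred=_tsv_opt_float(row.get("cadd_phred") or ""),
                    variant_assoc_p=_tsv_opt_float(row.get("variant_assoc_p") or ""),
                    gene_assoc_p=_tsv_opt_float(row.get("gene_assoc_p") or ""),
                    literature_ms_link=_BOOL_CODES[
                        (row.get("literature_ms_link") or "").strip().lower()
                    ],
                    protein_change=_opt_str("protein_change"),
                ))
            except (ValueError, KeyError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc!r}") from None
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return out


def write_annotations(annos: Iterable[AnnotationRecord], path: str | Path) -> None:
    rows = ["\t".join(_ANNOTATION_COLUMNS)]
    for a in annos:
        rows.append("\t".join([
            a.variant_key,
            a.gene or ".",
            a.consequence.value if a.consequence else ".",
            "." if a.maf_percent is None else repr(float(a.maf_percent)),
            "." if a.cadd_phred is None else repr(float(a.cadd_phred)),
            "." if a.variant_assoc_p is None else repr(float(a.variant_assoc_p)),
            "." if a.gene_assoc_p is None else repr(float(a.gene_assoc_p)),
            "1" if a.literature_ms_link else "0",
            a.protein_change or ".",
        ]))
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


def join_annotations(
    variants: Iterable[VariantRecord], annos: Iterable[AnnotationRecord]
) -> tuple[list[AnnotatedVariant], list[str]]:
    """Left-join variants with annotations on the canonical key.

    Returns (annotated variants, keys that had no annotation row);
    unannotated variants carry an all-absent annotation.
    """
    by_key: dict[str, AnnotationRecord] = {}
    for a in annos:
        if a.variant_key in by_key:
            raise ValidationError(f"duplicate annotation key {a.variant_key!r}")
        by_key[a.variant_key] = a
    joined: list[AnnotatedVariant] = []
    unannotated: list[str] = []
    for v in variants:
        vk = canonical_key(v)
        anno = by_key.get(vk)
        if anno is None:
            unannotated.append(vk)
            anno = AnnotationRecord(variant_key=vk)
        joined.append(AnnotatedVariant(record=v, annotation=anno))
    if unannotated:
        logger.warning("%d variant(s) had no annotation row: %s",
                       len(unannotated), ", ".join(unannotated[:5]))
    return joined, unannotated
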
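"""Pipeline orchestration and report rendering.

``run_pipeline`` ties the stages together — cohort summary, selection
cascade, co-segregation — and writes machine-readable reports plus a run
manifest (input checksums recorded before computation, tool version,
seed). Tables carry both exact carrier fractions and cosmetic display
percentages so the classification is auditable independent of rounding;
reruns on identical inputs produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .cascade import (CascadeConfig, SelectionResult, Strategy, run_cascade)
from .errors import FamsegError, ParseError
from .pedigree import Cohort, CohortSummary, read_cohort, summarize_cohort
from .segregation import SegregationResult, cosegregation_table
from .variants import (AnnotatedVariant, AnnotationRecord, Consequence,
                       VariantRecord, canonical_key, join_annotations,
                       read_annotations, read_vcf)

logger = logging.getLogger(__name__)

FORMATS = ("tsv", "json")


@dataclass
class RunManifest:
    tool_version: str
    config_digest: str
    input_digests: dict[str, str]
    seed: Optional[int] = None
    started_at: str = ""
    finished_at: str = ""
    outputs: dict[str, str] = field(default_factory=dict)


def _sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()


def load_cascade_config(path: Optional[str | Path]) -> CascadeConfig:
    """Load a flat key→value config file (YAML mapping) into CascadeConfig."""
    if path is None:
        return CascadeConfig()
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: config must be a flat key: value mapping")
    if "consequences_admitted" in raw:
        raw["consequences_admitted"] = frozenset(
            Consequence(c) for c in raw["consequences_admitted"]
        )
    known = {f.name for f in dataclasses.fields(CascadeConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ParseError(f"{path}: unknown config keys: {', '.join(sorted(unknown))}")
    return CascadeConfig(**raw)


def config_digest(cfg: CascadeConfig) -> str:
    payload = {f.name: sorted(v) if isinstance(v := getattr(cfg, f.name), frozenset)
               else v for f in dataclasses.fields(cfg)}
    return _sha256_text(json.dumps(payload, sort_keys=True, default=str))


# --- frames -------------------------------------------------------------


def summary_frame(summary: CohortSummary) -> pd.DataFrame:
    def _fmt(x: Optional[float]) -> Optional[float]:
        return None if x is None else round(x, 1)

    row = {
        "n_total": summary.n_total,
        "n_affected": summary.n_affected,
        "n_unaffected": summary.n_unaffected,
        "n_exome": summary.n_exome,
        "n_targeted_only": summary.n_targeted_only,
        **{f"n_{s.value}": n for s, n in summary.subtype_counts.items()},
        "mean_age_dna_cases": _fmt(summary.mean_age_dna_cases),
        "sd_age_dna_cases": _fmt(summary.sd_age_dna_cases),
        "mean_age_dna_unaffected": _fmt(summary.mean_age_dna_unaffected),
        "sd_age_dna_unaffected": _fmt(summary.sd_age_dna_unaffected),
        "mean_age_onset": _fmt(summary.mean_age_onset),
        "sd_age_onset": _fmt(summary.sd_age_onset),
        "sex_cases_male": summary.sex_ratio_cases[0],
        "sex_cases_female": summary.sex_ratio_cases[1],
        "sex_unaffected_male": summary.sex_ratio_unaffected[0],
        "sex_unaffected_female": summary.sex_ratio_unaffected[1],
    }
    return pd.DataFrame([row])


_SELECTION_COLUMNS = [
    "variant_key", "chrom", "pos", "ref", "alt", "variant_id", "gene",
    "consequence", "maf_percent", "cadd_phred", "protein_change", "strategy",
    "contributing_families", "criteria_trace",
]


def selection_frame(results: Sequence[SelectionResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        v, a = r.variant.record, r.variant.annotation
        rows.append({
            "variant_key": r.key,
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "variant_id": v.variant_id,
            "gene": a.gene,
            "consequence": a.consequence.value if a.consequence else None,
            "maf_percent": a.maf_percent,
            "cadd_phred": a.cadd_phred,
            "protein_change": a.protein_change,
            "strategy": r.strategy.value,
            "contributing_families": ",".join(r.contributing_families),
            "criteria_trace": json.dumps(r.criteria_trace, sort_keys=True),
        })
    return pd.DataFrame(rows, columns=_SELECTION_COLUMNS)


def read_selection(path: str | Path) -> list[SelectionResult]:
    """Reload a selection table written by :func:`selection_frame`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "contributing_families": str})
    out = []
    for _, row in df.iterrows():
        rec = VariantRecord(
            chrom=str(row["chrom"]), pos=int(row["pos"]),
            ref=row["ref"], alt=row["alt"],
            variant_id=None if pd.isna(row["variant_id"]) else str(row["variant_id"]),
        )
        anno = AnnotationRecord(
            variant_key=canonical_key(rec),
            gene=None if pd.isna(row["gene"]) else str(row["gene"]),
            consequence=(None if pd.isna(row["consequence"])
                         else Consequence(row["consequence"])),
            maf_percent=None if pd.isna(row["maf_percent"]) else float(row["maf_percent"]),
            cadd_phred=None if pd.isna(row["cadd_phred"]) else float(row["cadd_phred"]),
            protein_change=(None if pd.isna(row["protein_change"])
                            else str(row["protein_change"])),
        )
        out.append(SelectionResult(
            variant=AnnotatedVariant(record=rec, annotation=anno),
            strategy=Strategy(row["strategy"]),
            contributing_families=str(row["contributing_families"]).split(","),
            criteria_trace=json.loads(row["criteria_trace"]),
        ))
    return out


_COSEG_COLUMNS = [
    "variant_key", "gene", "variant_id", "protein_change",
    "case_percent", "control_percent", "classification",
    "case_fraction", "unaffected_fraction",
    "case_carriers", "case_genotyped", "unaffected_carriers",
    "unaffected_genotyped", "contributing_families",
]


def coseg_frame(results: Sequence[SegregationResult],
                selected: Sequence[SelectionResult]) -> pd.DataFrame:
    anno_by_key = {r.key: r.variant for r in selected}
    rows = []
    for r in results:
        c = r.counts
        v = anno_by_key.get(c.variant_key)
        rows.append({
            "variant_key": c.variant_key,
            "gene": v.annotation.gene if v else None,
            "variant_id": v.record.variant_id if v else None,
            "protein_change": v.annotation.protein_change if v else None,
            "case_percent": r.case_percent_display,
            "control_percent": r.unaffected_percent_display,
            "classification": r.classification.value,
            "case_fraction": str(r.case_fraction),
            "unaffected_fraction": str(r.unaffected_fraction),
            "case_carriers": c.pooled_case_carriers,
            "case_genotyped": c.pooled_case_genotyped,
            "unaffected_carriers": c.pooled_unaffected_carriers,
            "unaffected_genotyped": c.pooled_unaffected_genotyped,
            "contributing_families": ",".join(c.contributing_families),
        })
    return pd.DataFrame(rows, columns=_COSEG_COLUMNS)


def write_table(df: pd.DataFrame, path: str | Path, fmt: str) -> None:
    """Write a report table as TSV or JSON records (stable column order)."""
    if fmt not in FORMATS:
        raise FamsegError(f"unknown report format {fmt!r}; expected one of {FORMATS}")
    path = Path(path)
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False)
    else:
        records = json.loads(df.to_json(orient="records"))
        path.write_text(json.dumps(records, indent=1) + "\n", encoding="utf-8")


def render_report(results: dict[str, pd.DataFrame], out_dir: str | Path,
                  fmt: str = "tsv") -> dict[str, Path]:
    """Write every named table under ``out_dir`` in the requested format."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in results.items():
        p = out_dir / f"{name}.{fmt}"
        write_table(df, p, fmt)
        paths[name] = p
    return paths


# --- end-to-end ---------------------------------------------------------


def run_pipeline(cohort_path: str | Path, vcf_path: str | Path,
                 annotations_path: str | Path,
                 config_path: Optional[str | Path] = None,
                 out_dir: str | Path = ".",
                 formats: Sequence[str] = ("tsv", "json"),
                 seed: Optional[int] = None) -> RunManifest:
    """Run summary + selection + co-segregation; write reports and manifest."""
    started = datetime.now(timezone.utc).isoformat()
    for p in (cohort_path, vcf_path, annotations_path):
        if not Path(p).is_file():
            raise FamsegError(f"input file not found: {p}")
    cfg = load_cascade_config(config_path)
    manifest = RunManifest(
        tool_version=__version__,
        config_digest=config_digest(cfg),
        input_digests={str(p): _sha256_file(p)
                       for p in (cohort_path, vcf_path, annotations_path)},
        seed=seed,
        started_at=started,
    )
    cohort = read_cohort(cohort_path)
    records, gm = read_vcf(vcf_path, cohort)
    annos = read_annotations(annotations_path)
    variants, unannotated = join_annotations(records, annos)
    if unannotated:
        logger.info("%d variants without annotation enter the cascade with "
                    "all-absent annotation", len(unannotated))
    summary = summarize_cohort(cohort)
    selected = run_cascade(cohort, variants, gm, cfg)
    coseg = cosegregation_table(selected, cohort, gm)
    tables = {
        "cohort_summary": summary_frame(summary),
        "selection": selection_frame(selected),
        "cosegregation": coseg_frame(coseg, selected),
    }
    out_dir = Path(out_dir)
    for fmt in formats:
        paths = render_report(tables, out_dir, fmt)
        manifest.outputs.update({f"{k}.{fmt}": _sha256_file(v)
                                 for k, v in paths.items()})
    manifest.finished_at = datetime.now(timezone.utc).isoformat()
    (out_dir / "manifest.json").write_text(
        json.dumps(dataclasses.asdict(manifest), indent=1) + "\n", encoding="utf-8")
    return manifest
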
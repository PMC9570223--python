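"""Deterministic bundled fixture: a nine-family multiple sclerosis cohort.

This module encodes, as plain Python data, the published characteristics
of a real nine-family multi-incident MS study: the 55-member roster
(family, id, sex, affection, subtype, ages, exome-sequencing flag), the
18 rare variants that survived the selection cascade (gene, locus, MAF
tier, CADD score, consequence), and carrier assignments that reproduce
every published pooled co-segregation fraction exactly. It also adds 24
decoy variants, each engineered to fail exactly one cascade criterion,
so the cascade's specificity is exercisable without external data.

Transcription conventions
-------------------------
* The published table gives no parent links, so fixture members carry
  none; genotypes are assigned directly rather than gene-dropped (only
  presence/absence matters downstream).
* MAF tiers are stored as representative in-tier values: 0.5 for "≤1",
  0.02 for "≤0.05", and 0.0 for novel variants with no population
  frequency (novel variants trivially satisfy any MAF ceiling).
* Genomic positions for variants published only under an rsID are
  synthetic placeholders inside the right chromosome; positionally
  identified variants keep their printed hg19 coordinates. The ITPR3
  deletion, printed as a coordinate range, is encoded as a single
  anchored record at the range start.
* Prior-evidence columns follow the study's attributions: literature
  links for MBP, MECP2 and CPT1A (previously reported MS rare-variant
  genes) and for PLK1, CACNA1F and TRIM66 (mechanistic/severity links
  discussed in the same study); exome-chip variant-level p < 0.05 for
  PRAM1 and USH2A; gene-wide association p < 0.05 for ZNF641, EXOC2,
  CCNI, ITPR3, SORCS1, PRAM1, MTMR7, TTC28 and TOX3.
* Named unaffected carriers are honored (family 1 I.2 for EXOC2;
  family 3 III.3 and family 7 II.9 for CACNA1F); all other unaffected
  carriers are placed on the lowest-ordered *targeted-only* unaffected
  member of the contributing family, so that every true variant passes
  the exome-only presence/absence step while reproducing the published
  carrier fractions among all genotyped members.
"""

from __future__ import annotations

from .pedigree import (Affection, Cohort, Individual, SequencingTier, Sex,
                       Subtype)
from .simulate import SimulatedStudy
from .variants import (AnnotatedVariant, AnnotationRecord, Consequence,
                       GenotypeMatrix, VariantRecord, canonical_key)

# --- roster: 55 members of 9 families ----------------------------------
# (family, individual, sex, affected, subtype, age_dx, age_dna, wes)
_ROSTER: list[tuple[str, str, str, bool, str | None, int | None, int, bool]] = [
    ("1", "I.2",   "F", False, None,   None, 62, False),
    ("1", "II.4",  "F", False, None,   None, 40, True),
    ("1", "II.5",  "M", True,  "RRMS", 29,   38, True),
    ("1", "II.11", "F", True,  "RRMS", 27,   34, False),
    ("1", "II.13", "F", True,  "RRMS", 26,   29, True),
    ("2", "II.1",  "M", False, None,   None, 81, True),
    ("2", "III.1", "M", False, None,   None, 60, False),
    ("2", "III.2", "F", True,  "SPMS", 46,   57, True),
    ("2", "III.10", "F", False, None,  None, 51, False),
    ("2", "III.12", "F", True, "SPMS", 16,   44, True),
    ("2", "IV.1",  "F", False, None,   None, 27, False),
    ("2", "IV.2",  "M", True,  "RRMS", 24,   25, False),
    ("3", "II.1",  "M", False, None,   None, 60, True),
    ("3", "II.2",  "F", True,  "RRMS", 32,   57, True),
    ("3", "II.3",  "M", False, None,   None, 51, False),
    ("3", "III.1", "M", True,  "RRMS", 24,   34, True),
    ("3", "III.3", "F", False, None,   None, 31, False),
    ("4", "III.2", "M", True,  "SPMS", 51,   71, True),
    ("4", "III.3", "F", False, None,   None, 68, True),
    ("4", "III.6", "F", False, None,   None, 61, False),
    ("4", "III.8", "F", True,  "NA",   22,   56, False),
    ("4", "IV.1",  "F", False, None,   None, 35, False),
    ("4", "IV.2",  "F", True,  "RRMS", 29,   34, True),
    ("4", "IV.4",  "F", True,  "RRMS", 31,   32, True),
    ("4", "IV.5",  "M", False, None,   None, 48, False),
    ("4", "IV.6",  "M", False, None,   None, 27, False),
    ("4", "IV.8",  "F", False, None,   None, 22, False),
    ("5", "I.1",   "M", True,  "SPMS", 29,   68, True),
    ("5", "I.2",   "F", False, None,   None, 64, False),
    ("5", "II.1",  "F", False, None,   None, 37, False),
    ("5", "II.2",  "M", True,  "RRMS", 36,   40, True),
    ("5", "II.3",  "F", True,  "RRMS", 26,   38, True),
    ("5", "II.4",  "M", False, None,   None, 39, True),
    ("6", "I.2",   "F", False, None,   None, 65, True),
    ("6", "II.1",  "F", True,  "RRMS", 27,   31, True),
    ("6", "II.2",  "F", False, None,   None, 28, False),
    ("6", "II.3",  "F", True,  "RRMS", 23,   26, True),
    ("7", "II.2",  "F", True,  "SPMS", 39,   66, True),
    ("7", "II.5",  "M", False, None,   None, 63, False),
    ("7", "II.7",  "F", True,  "SPMS", 35,   62, False),
    ("7", "II.9",  "F", False, None,   None, 61, False),
    ("7", "II.10", "M", False, None,   None, 56, False),
    ("7", "III.1", "F", True,  "PPMS", 38,   40, True),
    ("7", "III.2", "F", True,  "NA",   24,   38, True),
    ("7", "III.3", "F", False, None,   None, 36, True),
    ("8", "I.1",   "M", False, None,   None, 70, False),
    ("8", "I.2",   "F", False, None,   None, 68, False),
    ("8", "II.1",  "M", True,  "NA",   31,   42, True),
    ("8", "II.2",  "F", True,  "NA",   25,   40, True),
    ("8", "II.3",  "M", False, None,   None, 38, True),
    ("8", "II.4",  "F", True,  "RRMS", 34,   36, True),
    ("9", "II.7",  "F", True,  "NA",   42,   76, True),
    ("9", "II.8",  "F", True,  "PPMS", 52,   71, True),
    ("9", "III.1", "M", False, None,   None, 56, False),
    ("9", "III.2", "M", False, None,   None, 54, True),
]

# --- the 18 selected variants -------------------------------------------
# (gene, chrom, pos, ref, alt, variant_id, maf_percent, cadd, consequence,
#  protein_change, families, unaffected_carriers, non_carrier_cases)
# MAF tier encoding: 0.5 ≙ "≤1", 0.02 ≙ "≤0.05", 0.0 ≙ novel ("NA").
_TRUE_VARIANTS = [
    ("EXOC2",   "6",  543210,    "G", "A", "rs760365995", 0.02, 25.0, "missense",
     "p.Pro134Leu", ["1"], [("1", "I.2")], []),
    ("PLK1",    "16", 23691000,  "C", "T", "rs35056440",  0.5,  22.9, "missense",
     "p.Leu261Phe", ["1", "3"], [], []),
    ("MBP",     "18", 74696828,  "C", "A", "18:74696828", 0.0,  25.4, "missense",
     "p.Gly151Val", ["1"], [], []),
    ("ZNF641",  "12", 48733000,  "G", "A", "rs200502528", 0.02, 27.7, "missense",
     "p.His342Tyr", ["2"], [("2", "III.1")], [("2", "IV.2")]),
    ("CCNI",    "4",  77979000,  "T", "C", "rs139547927", 0.02, 29.1, "missense",
     "p.Tyr334Cys", ["3"], [("3", "II.3"), ("3", "III.3")], []),
    ("ITPR3",   "6",  33648382,  "AGTGCTGAGCGTT", "A", "6:33648383-33648394",
     0.0, 26.6, "lof", None, ["3"], [("3", "II.3")], []),
    ("SORCS1",  "10", 108439392, "G", "A", "10:108439392", 0.0, 34.0, "missense",
     "p.Ser554Leu", ["3"], [], []),
    ("PRAM1",   "19", 8564000,   "A", "G", "rs138042924", 0.5,  22.0, "missense",
     "p.Ser387Pro", ["3", "9"], [("3", "II.3")], []),
    ("CACNA1F", "X",  49067910,  "T", "A", "X:49067910",  0.0,  23.4, "missense",
     "p.Met1324Leu", ["3", "7"], [("3", "III.3"), ("7", "II.9")], []),
    ("MECP2",   "X",  153296777, "G", "A", "rs61751445",  0.02, 26.1, "missense",
     "p.Thr311Met", ["3"], [("3", "II.3")], []),
    ("USH2A",   "1",  216420000, "G", "A", "rs200802261", 0.02, 31.0, "missense",
     "p.Pro2870Leu", ["4"], [("4", "III.6")], [("4", "III.8")]),
    ("CPT1A",   "11", 68528000,  "C", "T", "rs140958507", 0.5,  23.7, "missense",
     "p.Arg288Gln", ["5", "9"], [("5", "I.2")], []),
    ("MTMR7",   "8",  17171000,  "G", "A", "rs760803217", 0.02, 22.5, "missense",
     "p.Thr6Met", ["6"], [], []),
    ("TRIM66",  "11", 8640000,   "G", "A", "rs138444298", 0.5,  21.5, "missense",
     "p.Arg1037Trp", ["6", "9"], [("6", "II.2")], []),
    ("CNGB1",   "16", 57929000,  "CAAGTAGT", "C", "rs776392588", 0.02, 51.0, "lof",
     None, ["6"], [("6", "II.2")], []),
    ("TTC28",   "22", 28501278,  "T", "C", "22:28501278", 0.0,  32.0, "missense",
     "p.Tyr1099Cys", ["8"], [("8", "I.1")], []),
    ("MANBA",   "4",  103560000, "TGAGCAAAGAAATTCT", "T", "rs1283991082",
     0.02, 30.0, "lof", None, ["9"], [("9", "III.1")], []),
    ("TOX3",    "16", 52580565,  "T", "C", "16:52580565", 0.0,  23.8, "missense",
     "p.Tyr24Cys", ["9"], [], []),
]

_LITERATURE_GENES = {"MBP", "MECP2", "CPT1A", "PLK1", "CACNA1F", "TRIM66"}
_VARIANT_ASSOC_P = {"PRAM1": 0.02, "USH2A": 0.03}
_GENE_ASSOC_P = {"ZNF641": 0.012, "EXOC2": 0.008, "CCNI": 0.021, "ITPR3": 0.004,
                 "SORCS1": 0.017, "PRAM1": 0.009, "MTMR7": 0.031, "TTC28": 0.026,
                 "TOX3": 0.002}

# --- decoys: each fails exactly one cascade criterion -------------------
# (gene, maf, cadd, consequence, lit, var_p, gene_p, mode, families, detail)
# modes: "clean"           — presence pattern passes in the listed families,
#                            the failure is an annotation criterion;
#        "unaff_carrier"   — a WES unaffected member carries (detail: ids);
#        "case_missing"    — a WES case has a missing call (detail: ids);
#        "case_noncarrier" — a WES case does not carry (detail: ids);
#        "nobody"          — carried by no one.
_DECOYS = [
    ("DCY_MAF_MULTI_A",   2.0,  25.0, "missense",   True,  None, None, "clean", ["1", "2"], []),
    ("DCY_MAF_MULTI_B",   1.5,  22.0, "missense",   False, None, 0.01, "clean", ["3", "4"], []),
    ("DCY_CADD_MULTI_A",  0.5,  19.9, "missense",   True,  None, None, "clean", ["2", "4"], []),
    ("DCY_CADD_MULTI_B",  0.8,  12.0, "missense",   False, None, 0.02, "clean", ["5", "8"], []),
    ("DCY_CONS_MULTI_A",  0.5,  30.0, "synonymous", True,  None, None, "clean", ["4", "5"], []),
    ("DCY_CONS_MULTI_B",  0.9,  24.0, "other",      False, None, 0.01, "clean", ["6", "7"], []),
    ("DCY_EVID_MULTI_A",  0.5,  24.0, "missense",   False, None, None, "clean", ["5", "6"], []),
    ("DCY_EVID_MULTI_B",  0.3,  21.0, "missense",   False, 0.5,  0.9,  "clean", ["7", "8"], []),
    ("DCY_MAF_SINGLE_A",  0.5,  25.0, "missense",   True,  None, None, "clean", ["7"], []),
    ("DCY_MAF_SINGLE_B",  0.2,  28.0, "missense",   False, None, 0.001, "clean", ["2"], []),
    ("DCY_CADD_SINGLE_A", 0.02, 19.5, "missense",   True,  None, None, "clean", ["9"], []),
    ("DCY_CADD_SINGLE_B", 0.01, 5.0,  "missense",   False, 0.01, None, "clean", ["1"], []),
    ("DCY_CONS_SINGLE_A", 0.01, 25.0, "synonymous", True,  None, None, "clean", ["8"], []),
    ("DCY_CONS_SINGLE_B", 0.04, 33.0, "other",      False, None, 0.04, "clean", ["3"], []),
    ("DCY_EVID_SINGLE_A", 0.02, 28.0, "missense",   False, None, None, "clean", ["1"], []),
    ("DCY_EVID_SINGLE_B", 0.0,  26.0, "missense",   False, 0.06, 0.07, "clean", ["6"], []),
    ("DCY_UNAFF_WES_A",   0.02, 30.0, "missense",   True,  None, None, "unaff_carrier",
     ["5"], [("5", "II.4")]),
    ("DCY_UNAFF_WES_B",   0.01, 27.0, "missense",   True,  None, None, "unaff_carrier",
     ["4"], [("4", "III.3")]),
    ("DCY_CASE_MISSING_A", 0.02, 26.0, "missense",  True,  None, None, "case_missing",
     ["3"], [("3", "III.1")]),
    ("DCY_CASE_MISSING_B", 0.01, 24.0, "missense",  True,  None, None, "case_missing",
     ["8"], [("8", "II.2")]),
    ("DCY_CASE_NONCARR_A", 0.02, 29.0, "missense",  True,  None, None, "case_noncarrier",
     ["1"], [("1", "II.13")]),
    ("DCY_CASE_NONCARR_B", 0.01, 23.0, "missense",  True,  None, None, "case_noncarrier",
     ["7"], [("7", "III.1")]),
    ("DCY_NOBODY_A",      0.02, 31.0, "missense",   True,  None, None, "nobody", [], []),
    ("DCY_NOBODY_B",      0.0,  22.0, "missense",   False, 0.01, None, "nobody", [], []),
]


def build_fixture_cohort() -> Cohort:
    """The 55-member roster as a validated cohort (no parent links)."""
    cohort = Cohort()
    for fam, iid, sex, affected, subtype, age_dx, age_dna, wes in _ROSTER:
        cohort.add(Individual(
            individual_id=iid,
            family_id=fam,
            sex=Sex.MALE if sex == "M" else Sex.FEMALE,
            affected=Affection.AFFECTED if affected else Affection.UNAFFECTED,
            subtype=Subtype(subtype) if subtype else Subtype.NONE,
            age_at_diagnosis_years=float(age_dx) if age_dx is not None else None,
            age_at_dna_collection_years=float(age_dna),
            sequencing_tier=SequencingTier.EXOME if wes else SequencingTier.TARGETED_ONLY,
        ))
    return cohort


def build_paper_fixture() -> SimulatedStudy:
    """Assemble the full deterministic fixture study.

    Returns a study whose cohort is the 55-member roster, whose variant
    list holds the 18 true variants followed by 24 decoys, and whose
    genotype matrix covers every member at every variant. The truth map
    is empty: causal status is unknown for real families.
    """
    cohort = build_fixture_cohort()
    gm = GenotypeMatrix()
    variants: list[AnnotatedVariant] = []

    def add_variant(rec: VariantRecord, anno: AnnotationRecord) -> str:
        variants.append(AnnotatedVariant(record=rec, annotation=anno))
        vk = canonical_key(rec)
        for ind in cohort.individuals():
            gm.set_call(vk, ind.family_id, ind.individual_id, 0)
        return vk

    for (gene, chrom, pos, ref, alt, vid, maf, cadd, cons, prot, fams,
         unaff_carriers, non_carrier_cases) in _TRUE_VARIANTS:
        rec = VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, variant_id=vid)
        anno = AnnotationRecord(
            variant_key=canonical_key(rec),
            gene=gene,
            consequence=Consequence(cons),
            maf_percent=maf,
            cadd_phred=cadd,
            variant_assoc_p=_VARIANT_ASSOC_P.get(gene),
            gene_assoc_p=_GENE_ASSOC_P.get(gene),
            literature_ms_link=gene in _LITERATURE_GENES,
            protein_change=prot,
        )
        vk = add_variant(rec, anno)
        skip = set(non_carrier_cases)
        for fam in fams:
            for ind in cohort.members(fam):
                if ind.is_case and (fam, ind.individual_id) not in skip:
                    gm.set_call(vk, fam, ind.individual_id, 1)
        for fam, iid in unaff_carriers:
            gm.set_call(vk, fam, iid, 1)

    for i, (gene, maf, cadd, cons, lit, var_p, gene_p, mode, fams,
            detail) in enumerate(_DECOYS):
        rec = VariantRecord(chrom="2", pos=10_000_000 + i * 1_000, ref="G", alt="A")
        anno = AnnotationRecord(
            variant_key=canonical_key(rec),
            gene=gene,
            consequence=Consequence(cons),
            maf_percent=maf,
            cadd_phred=cadd,
            variant_assoc_p=var_p,
            gene_assoc_p=gene_p,
            literature_ms_link=lit,
        )
        vk = add_variant(rec, anno)
        if mode in ("clean", "unaff_carrier", "case_missing", "case_noncarrier"):
            for fam in fams:
                for ind in cohort.members(fam):
                    if ind.is_case:
                        gm.set_call(vk, fam, ind.individual_id, 1)
        if mode == "unaff_carrier":
            for fam, iid in detail:
                gm.set_call(vk, fam, iid, 1)
        elif mode == "case_missing":
            for fam, iid in detail:
                gm.set_call(vk, fam, iid, None)
        elif mode == "case_noncarrier":
            for fam, iid in detail:
                gm.set_call(vk, fam, iid, 0)

    return SimulatedStudy(cohort=cohort, variants=variants, genotypes=gm, truth={})


def fixture_variant_key(study: SimulatedStudy, gene: str) -> str:
    """Canonical key of the fixture variant annotated with ``gene``."""
    for v in study.variants:
        if v.annotation.gene == gene:
            return v.key
    raise KeyError(gene)
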
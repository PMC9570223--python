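# Methods

## Analysis model

The pipeline operationalizes the family-based rare-variant design used
in multiplex-family sequencing studies. Its unit of evidence is the
family, not the population: a rare variant is interesting when it
tracks with disease through a family in which several members are
affected.

**Presence/absence step (exome tier).** For each variant and family,
computed only over exome-sequenced members: *present* means every
sequenced case has allele count ≥ 1; *absent* means no sequenced
unaffected member has a non-missing call ≥ 1. Missing-call conventions
are conservative for cases — a missing call in a sequenced case voids
the presence flag (a variant cannot be claimed fully segregating on
incomplete case data), while absence among unaffected members is judged
over non-missing calls only; if every sequenced unaffected call is
missing, absence holds vacuously. A family with no sequenced case or no
sequenced unaffected member can never qualify, and the pattern records
the counts that explain why.

**Selection cascade.** Two complementary strategies, then a gate:

| parameter | default | meaning |
|---|---|---|
| `maf_multi_family_max_percent` | 1.0 | MAF ceiling (%) for variants recurring in ≥ 2 candidate families |
| `maf_single_family_max_percent` | 0.05 | stricter ceiling (%) for variants private to one family |
| `min_recurrent_families` | 2 | recurrence threshold of the multi-family strategy |
| `cadd_min` | 20 | phred-scaled CADD deleteriousness floor (top 1% of substitutions) |
| `consequences_admitted` | missense, lof | consequence classes admitted |
| `prior_evidence_alpha` | 0.05 | uncorrected α for variant-/gene-level association evidence |

A variant with no population frequency (novel) trivially satisfies any
MAF ceiling and is treated as MAF 0. The prior-evidence gate applies
uniformly to *all* missense variants — whether recurrent or private —
and retains a variant if any one source fires: a curated literature
link, a variant-level (exome-chip) p < α, or a gene-level (gene-wide
association) p < α. Loss-of-function variants bypass the gate: their
predicted impact is their evidence. Every examined variant carries a
pass/fail/not-applicable trace for every criterion of its strategy; no
criterion short-circuits, so rejected variants record all of their
failures. Output order is genomic (chromosomes 1–22, X, Y, MT; then
position).

**Co-segregation.** Counts run over *all* genotyped members of a
variant's contributing families (exome + targeted tiers), pooled into a
single row per variant; members with missing calls leave both numerator
and denominator. Fractions are exact `fractions.Fraction` values.
Classification: `complete` iff the case fraction is 1 and the
unaffected fraction 0; `acceptable` iff the case fraction is 1 and the
unaffected fraction lies in (0, 1/3], compared exactly — the boundary
is inclusive, so 1 carrier among 3 unaffected members (printed 33%)
still classifies as acceptable; otherwise `failed`. Unaffected members
are counted regardless of age: a young unaffected carrier may simply
not have manifested yet, but no age-censoring is applied. Display
percentages use round-half-up of 100 × fraction and are never used for
classification; note that 2/3 displays as 67 under this rule.

## Synthetic data generator

`simulate_study` emulates the ascertainment and sequencing design the
analysis assumes:

* **Pedigrees** — a founder couple plus 2–3 generations; sibships drawn
  uniformly from `sibship_size_range` (default 2–4); within each
  non-final generation the first two children marry in founder spouses
  and reproduce; sexes equiprobable.
* **Causal variant** — one per family (rare: MAF 0.05%, CADD 25,
  missense, literature-linked by default), introduced as a single
  heterozygous copy in one random first-generation founder. This
  reflects ascertainment: a variant that is vanishingly rare in the
  population is present in the family *because* the family was
  ascertained, so drawing founder genotypes at the population frequency
  would almost never produce a segregating copy.
* **Gene dropping** — each child receives one allele drawn uniformly
  from each parent; X-linked variants transmit with sex-correct
  hemizygosity (sons draw from the mother only; daughters receive the
  father's single X allele). Background variants (default 30; MAF
  log-uniform on [0.001, 5]%, CADD uniform on [1, 40], mixed
  consequences, ~5% X-linked) drop independently from founder genotypes
  drawn at their own MAF.
* **Phenotypes** — one uniform draw per individual, compared against
  the penetrance (default 0.8) for carriers and the phenocopy rate
  (default 0.02) for non-carriers. The single-uniform form makes
  affection monotone in penetrance under common random numbers, which
  is what makes causal-variant recovery a monotone function of
  penetrance in the recovery tests.
* **Inclusion** — families are rejection-sampled (bounded attempts,
  per-attempt seed substreams) until they have ≥ 2 affected and ≥ 1
  unaffected member; sequencing tiers then always include ≥ 2 cases and
  ≥ 1 unaffected member in the exome tier, filled to
  `fraction_exome_sequenced` (default 0.6) of the family, with everyone
  else targeted-only.

All randomness flows from `numpy.random.SeedSequence([seed, family,
attempt])` substreams, so studies are bitwise reproducible and families
are independent.

What the generator does **not** model: linkage disequilibrium and
haplotype structure, sequencing/genotyping error, de novo mutation,
age-dependent penetrance, and shared causal variants across families.
Passing tests therefore demonstrate the correctness of the counting,
filtering and classification machinery under clean Mendelian
transmission — not the pipeline's behavior under real call-set noise,
relatedness confounding, or allelic heterogeneity.

## Bundled fixture

The fixture transcribes a published nine-family multiple sclerosis
study: 55 members (26 cases, 29 unaffected; 31 exome-sequenced), 18
selected rare variants, and carrier assignments reproducing every
published pooled co-segregation fraction. Conventions, and the places
where the printed tables are not internally reproducible, are
documented in `famseg/fixture.py`; the notable ones:

* Published MAF *tiers* are stored as representative in-tier values
  (0.5 for "≤1", 0.02 for "≤0.05", 0 for novel).
* Positions for rsID-only variants are synthetic placeholders on the
  correct chromosome; positionally published variants keep their
  printed coordinates, and the range-printed ITPR3 deletion is encoded
  as one anchored record at the range start.
* Unaffected carriers named in the source are honored; unnamed ones
  are placed deterministically on the lowest-ordered *targeted-only*
  unaffected member, which is also what lets every selected variant
  pass the exome-only presence step. In particular the X-linked
  CACNA1F variant's unaffected carriers are targeted-only members of
  families 3 and 7 (III.3 and II.9), since the published exome tier of
  family 7 contains an unaffected member that the source elsewhere
  names a carrier — a tension the fixture resolves in favor of the
  presence/absence step.
* Quantities the printed tables do not reproduce from their own roster
  are asserted at their computed values: unaffected mean age ≈ 50.3
  (printed 51.2), case sex ratio 7:19 (printed 1:2.9), case-age SD 15.5
  under the n−1 convention (printed 15.2, the n-denominator value), and
  the 2/3 unaffected fraction displaying as 67 (printed 66) — the
  latter checked at the fraction level.
* 24 decoy variants each fail exactly one criterion (MAF tier, CADD,
  consequence, evidence gate, or the presence pattern itself), so
  cascade specificity is testable: a correct run selects 18 variants
  and zero decoys.

## Numerical and design choices

* Carrier fractions and the 1/3 boundary use exact rational arithmetic;
  no floating-point comparison enters classification.
* Summary SDs use the sample (n−1) convention; statistics with no
  eligible individuals are absent, never zero.
* Diploid-coded male X calls of 2 are normalized to allele count 1 on
  VCF read (one summary warning per file); the VCF writer emits male
  hemizygous carriers as `1/1`, so a write/read round trip preserves
  normalized counts exactly.
* Multi-allelic VCF sites are split into biallelic records; a partially
  missing genotype is treated as missing. No further normalization
  (e.g., indel left-alignment) is performed.
* Deterministic ordering throughout (roster order for members, genomic
  order for variants) makes reports byte-identical across reruns; the
  run manifest records input digests before computation.

## Problem sizes in the checked examples

The test suite and acceptance script run entirely at desk scale: the
55-member fixture with 42 variants; simulator checks over 100
single-family studies (Mendelian consistency), 10,000+ transmission
draws (binomial checks against 3 SE), 100 simulated families per
penetrance level {1.0, 0.8, 0.6} for recovery monotonicity, a frozen
200-family regression at default parameters, and 25 random small
instances (≤ 3 families × 6 members × 50 variants) compared exhaustively
against a brute-force re-implementation of every selection criterion.

## Known limitations

* The co-segregation classification is descriptive; no formal
  co-segregation statistic (e.g., a Bayes-factor LOD) is computed, and
  with the small denominators typical of these studies the 1/3 boundary
  is sensitive to a single carrier.
* Population MAF, CADD, and association p-values are consumed as
  annotations and never recomputed; garbage in, garbage out.
* The sample-naming convention `FAMILY_INDIVIDUAL` requires family ids
  without underscores.
* Pedigree validation detects ancestor cycles and dangling parent ids
  but not implausible structures (e.g., inter-generational loops beyond
  cycles, sex-discordant parent roles).
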
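# Methods

`editscreen` decides whether any variant called in an edited cell
population is attributable to nuclease activity, using only per-sample
variant calls (VCF), a germline occurrence database, a guide table and
a reference sequence. This note documents the models and the design
choices behind each stage.

## Screening model

The core assumption is that a genuine nuclease-induced lesion must
satisfy, jointly:

1. **Reproducibility** — it is called in every technical replicate of a
   condition. The reproducible set is the intersection of the
   replicates' variant-key sets; concordance is reported as
   |intersection| / |union|. The union denominator is a design choice:
   the source data report "% of variants called in all replicates"
   without defining a denominator, and the Jaccard form is the
   conservative one.
2. **Non-germline origin** — it is neither synonymous (non-pathogenic
   by definition for this screen) nor reported more than 10 times in a
   germline occurrence database. The `>10` boundary is strict: a count
   of exactly 10 is retained.
3. **Absence from the Mock arm** — any variant in the same donor's
   Mock (electroporated, no nuclease) reproducible set at *any*
   timepoint removes the treated call, regardless of VAF. Subtraction
   is key-exact (chrom, pos, ref, alt after left-alignment), so a
   different ALT at the same site survives.
4. *(strict mode, off by default)* **Mechanistic plausibility** — the
   variant is an indel or MNV (not an SNV) and its flanks carry
   spacer+PAM homology (below). The permissive cascade (stages 1–3) is
   the primary view; the strict filter is a secondary lens for
   attributing survivors to the nuclease.

Every stage writes to a ledger that must conserve counts exactly
(`input = output + removed`) and never increase; both properties are
asserted at run time, not only in tests.

Variant identity is canonical: indels are left-aligned and minimally
represented on ingestion, and VAF is always recomputed as
`alt_reads / depth` even when the input carries an AF field.

## Detection model

The panel's validated operating point — LoD 0.205% VAF at median exon
coverage (MEC) 3550 with 95% sensitivity — is treated as a calibration
anchor, not a derivable quantity (its derivation involves the vendor's
empirical noise model, which is not available). The default model
assumes a constant expected number of supporting reads at the LoD:

    lambda* = depth_anchor x lod_anchor = 3550 x 0.00205 = 7.2775
    LoD(d)  = lambda* / d

This 1/d law reproduces the anchor exactly and gives the pooled
triplicate limit LoD(3 x 3550) = 0.0683% VAF, consistent with the
"<0.07%" pooled bound. Pooled depth is the sum of per-replicate MECs.
An explicit binomial mode (`k_min`) computes the smallest VAF whose
detection probability P(X >= k_min), X ~ Binomial(depth, VAF), reaches
the sensitivity target (bisection to 1e-9); it exists for sensitivity
analyses because no integer k reproduces the printed operating pair
exactly.

## Guide homology

Homology between a guide and a variant locus is scored by sliding the
23-mer (20-nt spacer + 3-nt PAM pattern) across a window spanning 20 bp
either side of the variant (extended by 22 bp so every overlapping
placement is scored), on both strands, counting positional matches; N
in the PAM pattern matches any base. A site is "homologous" when the
best placement matches at >= 10 of 23 positions. The threshold counts
*total* matches in the best ungapped placement, not a contiguous run —
the screening rule is worded as a count — but a contiguous-run mode is
available (`contiguous=True`). Ties break to the smallest offset, plus
strand first, for determinism. Gapped (bulged) alignments are out of
scope.

The cut site is placed between protospacer positions 17 and 18 (3 bp
5' of the PAM), standard SpCas9 geometry. On-target membership uses a
+/- 50 bp window around the cut by default (configurable; the window
used by the source analysis is not stated).

## Somatic comparison

The exome/genome analyses compare an edited sample ("tumor") against
Mock ("normal"). The production somatic caller used by the source
pipeline is proprietary and undocumented, so the comparison here is a
documented stand-in: a one-sided Fisher exact test on the 2x2 table
(alt, ref) x (tumor, normal), calling somatic when p <= alpha (default
0.01) and tumor VAF > normal VAF. Sites absent from the normal
contribute zero alt reads at the normal's local depth (depth track if
supplied, else its MEC): absence of a call is not absence of coverage.

Printed screening filters are applied with strict boundary semantics:

- exome mode: remove normal VAF > 0.01 (0.01 exactly is retained);
- genome mode: remove tumor VAF < 0.001 and normal VAF > 0.01;
- background subtraction: adjusted VAF = max(0, tumor - normal),
  which never changes set membership, only the reported VAF.

The **inversion control** reruns the full comparison with labels
swapped. With no true edits the two directions differ only by noise,
so their call counts should be of the same order; the package reports
both counts and their ratio rather than asserting equality, because
each count is a small Poisson-like number and per-pair ratios are
intrinsically unstable. Coverage checks are deliberately simple: a
Pearson correlation of positional depth tracks, and a depth-dropout
ratio (mean depth within +/- 50 bp of the cut over the median of the
rest; flagged below 0.5 — the flag threshold is an invention, recorded
as configurable, since the source analysis reports only the absence of
an apparent drop).

## Synthetic cohort

The generator emulates the study design: 3 donors x {Mock, AAVS1, HBB,
ZFPM2} x {day 0 (Mock only, one replicate), 4, 10} x 3 technical
replicates = 75 samples. Defaults:

| parameter | default | rationale |
|---|---|---|
| target MEC | 3550 | panel's per-replicate operating depth |
| depth dispersion | 10 (negative binomial) | depth varies by donor more than by treatment; NB captures overdispersion Poisson cannot |
| germline variants / donor | 1490 | reproducible variants per condition at study scale |
| het fraction | 2/3 | typical het:hom ratio in a gene panel |
| synonymous fraction | 0.25 | keeps the synonymous filter load realistic |
| germline DB holdout | 0.3% with counts <= 10 | yields a small residual after filtering (a handful of variants from ~1490), and exercises the `>10` boundary |
| noise rate / sample | 8.5 (Poisson), VAF U(0.0005, 0.005) | calibrated so replicate concordance sits near the observed ~98.3% |
| chimerism / donor | 2, VAF U(0.05, 0.35) | intermediate-VAF donor-consistent variants; present in the germline DB, as observed; their VAF distribution is not stated anywhere, so uniform is used |
| default planted edits | on-target at total VAF 0.85 (d4, d10) per guide; one EZH2-embedded off-target for ZFPM2 at match count 20, total VAF 0.217 (d4) and 0.169 (d10) | the off-target trajectory is the package's worked example |
| indel spectrum | {-1: 0.50, +1: 0.25, -2: 0.15, +3: 0.10} | short-deletion-dominated spectrum typical of blunt double-strand-break repair |

Reads are sampled per variant: depth ~ NB(mean MEC, dispersion)
floored at 1, alt reads ~ Binomial(depth, true VAF); variants with
zero observed alt reads are not emitted (call-based inputs carry no
reference calls; the somatic module backfills zeros). Germline truth
is per-donor and donors are disjoint — the screen treats donors
independently, so shared polymorphism adds nothing tested here.
Off-target sites are engineered by mutating 23-k positions of the
spacer+PAM 23-mer (never the PAM's N position, which matches any base)
and are verified post-hoc to score exactly k, re-randomizing on
collision. Everything is deterministic given (config, seed):
re-running yields byte-identical files.

**What the generator does not emulate** — and therefore what passing
tests do *not* establish about real data: alignment and calling
artifacts (strand bias, mapping error, UMI consensus failure),
trinucleotide-context-dependent error rates, structural variants and
chromothripsis, shared inter-donor polymorphism, and real germline
database composition. Recovery results on synthetic cohorts bound the
pipeline's logic, not the wet-lab assay's sensitivity.

## Problem sizes and numerics

Tests and the acceptance experiments run cohorts at the default
(study-scale) configuration: ~1500 variants per sample, 75 samples,
10 seeds for recovery, 20 seeds for inversion symmetry — a few minutes
end to end on one core, which is the scale at which the statistical
assertions (binomial CLT bounds, pooled ratios) are already tight.
The LoD bisection converges to 1e-9 in VAF; the exact test delegates
to `scipy.stats.fisher_exact` and is verified against a hypergeometric
enumeration oracle for all tables with margins <= 30. Degenerate
inputs are handled explicitly: zero-variance depth tracks return a NaN
sentinel, zero-depth-in-both sites are skipped with a warning, and
variants straddling a CDS boundary are labeled noncoding with a
warning rather than guessed.

## Known limitations

- Effect annotation is single-isoform, CDS-only (no splice, UTR, or
  HGVS); only the synonymous/non-synonymous distinction feeds the
  cascade.
- Adjacent SNVs are not merged into MNVs on ingestion; inputs decide
  the representation.
- The somatic stand-in has no realignment, quality or strand-bias
  modeling; its absolute call counts are not comparable to a
  production caller's, which is why the inversion control reports
  ratios rather than absolute rates.
- The germline filter is only as good as the supplied database; the
  `>10` threshold is fixed by the screening design, the database is an
  input.
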
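# editscreen

Genotoxicity screening of CRISPR-edited cell populations from
ultra-deep variant calls.

When primary cells (for example hematopoietic stem and progenitor
cells) are edited ex vivo with Cas9 ribonucleoprotein and deep-sequenced
on a cancer-gene panel, exome or genome, almost every called variant is
germline polymorphism, sequencing noise, or culture drift — not
nuclease damage. `editscreen` implements the screening analysis that
separates the two: a replicate-concordance and filter cascade for panel
data, a depth-to-LoD detection model, a simplified tumor–normal somatic
comparison with a label-inversion control for exome/genome data, and a
spacer+PAM homology annotator that asks whether any surviving variant
is mechanistically attributable to the guide. A synthetic-cohort
generator with a complete ground-truth table makes every stage testable
without sequencing data.

It is written for people running or reviewing preclinical off-target
assessments of nuclease-edited cell products.

## The model in brief

A variant is a candidate nuclease lesion only if it is

1. called in **all** technical replicates (concordance = |∩|/|∪| of
   replicate key sets; depths pooled by summation),
2. not synonymous and not reported **> 10** times in a germline
   occurrence database (count 10 exactly is retained),
3. absent from the same donor's Mock arm at every timepoint
   (key-exact subtraction, VAF-blind), and — in strict mode —
4. an indel/MNV whose flanks score **≥ 10 / 23** positional matches to
   the spacer+PAM in the best ungapped placement within ±20 bp
   (N matches any base, both strands).

Detection is governed by a constant-expected-alt-reads law calibrated
at the panel's operating point (LoD 0.205% VAF at median exon coverage
3550, 95% sensitivity):

    λ* = 3550 × 0.00205 = 7.2775        LoD(d) = λ*/d

so pooling three replicates (depth 10 650) pushes the LoD to 0.068%
VAF. For exome/genome comparisons, somatic calls use a one-sided
Fisher exact test on (alt, ref) × (tumor, normal) with the printed VAF
filters (normal > 0.01 removed; genome mode additionally tumor < 0.001
removed), plus the inversion control (labels swapped) to estimate the
background call rate.

## Worked example

```python
from editscreen import calibrate, lod_at_depth
from editscreen.detection_model import pooled_depth
from editscreen.synthetic_cohort import CohortConfig, generate_cohort
from editscreen.panel_cascade import PipelineThresholds, run_panel_cascade

model = calibrate(depth_anchor=3550, lod_anchor=0.00205, sensitivity_target=0.95)
print(f"pooled-triplicate LoD: {100 * lod_at_depth(model, pooled_depth([3550]*3)):.4f}% VAF")

bundle = generate_cohort(CohortConfig(seed=1))      # 75 samples, truth table
results = run_panel_cascade(
    bundle.samples, PipelineThresholds(), bundle.guides,
    bundle.reference, bundle.germline_db, detection=model, strict=True,
)
res = results[("D2", "ZFPM2", 4)]                    # donor 2, ZFPM2 guide, day 4
for stage in res.ledger.stages:
    print(f"{stage.name:24s} {stage.input_count:5d} -> {stage.output_count}")
```

prints

```
pooled-triplicate LoD: 0.0683% VAF
replicate_concordance     1520 -> 1500
synonymous                1500 -> 1095
germline_db               1095 -> 11
mock_subtraction            11 -> 8
strict_cas9                  8 -> 8
```

Of ~1520 variants called in the arm, 1500 are replicate-reproducible;
the synonymous and germline-database filters remove all but 11; Mock
subtraction removes the database-holdout stragglers; the 8 survivors
are exactly the planted edit spectra — four indels at the on-target
cut site (summed VAF ≈ 0.85) and four at the engineered EZH2 off-target
site (summed VAF ≈ 0.217 at day 4, declining to ≈ 0.169 by day 10,
averaging ≈ 19.3% off-target activity). The ledger conserves counts at
every stage, and each removed variant carries its reason.

The same workflow is available from the shell:

```
editscreen simulate --config cohort.yaml --out cohort/
editscreen run-panel --config run.yaml --strict
editscreen run-somatic --config run.yaml --tumor D1_AAVS1_d10_r1 \
    --normal D1_MOCK_d10_r1 --mode wes
editscreen report --run out/
```

## Layout

- `editscreen.variant_model` — variant/sample data types, VCF/TSV I/O,
  left-alignment, classification
- `editscreen.effect_annotation` — CDS gene models, codon-table effect
  calls (GFF3 in/out)
- `editscreen.detection_model` — depth → LoD calibration, binomial
  sensitivity
- `editscreen.guide_homology` — spacer+PAM scoring, on-target windows
- `editscreen.panel_cascade` — the filter cascade with conservation-
  checked ledgers
- `editscreen.somatic_compare` — tumor–normal comparison, inversion
  control, coverage checks
- `editscreen.synthetic_cohort` — cohort generator and truth table
- `editscreen.cli` / `editscreen.cli_reporting` — command line and
  summary tables

See `docs/methods.md` for the full description of the models, the
generator's assumptions, and known limitations.
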
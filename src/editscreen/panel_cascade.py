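"""The panel screening cascade.

Per donor x treatment x timepoint: technical-replicate concordance
(intersection of key sets, depths pooled by summation), the synonymous
filter, the germline-database filter (remove occurrences > 10), Mock
subtraction (any variant seen reproducibly in the donor's Mock arm at
any timepoint is removed, regardless of VAF), and an optional strict
nuclease filter (drop SNVs, drop sites without spacer+PAM homology).
Every stage is logged in a ledger that conserves counts exactly:
input = output + removed at each stage.  Samples whose median exon
coverage falls below the lower specification limit (1300) are flagged
in the report but never excluded.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from editscreen.detection_model import DetectionModel, lod_at_depth
from editscreen.guide_homology import GuideRNA, flag_grna_homology
from editscreen.variant_model import SampleRecord, VariantCall, VariantKey


@dataclass(frozen=True)
class PipelineThresholds:
    """Filter cascade thresholds; defaults are the published values."""

    germline_max_occurrences: int = 10
    mock_subtraction: bool = True
    strict_flank: int = 20
    strict_min_match: int = 10
    mec_lower_spec: float = 1300.0
    chip_gene_list: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.germline_max_occurrences < 1:
            raise ValueError("germline_max_occurrences must be positive")
        if self.strict_flank < 1 or self.strict_min_match < 1:
            raise ValueError("strict filter thresholds must be positive")
        if self.mec_lower_spec <= 0:
            raise ValueError("mec_lower_spec must be positive")


@dataclass
class LedgerStage:
    name: str
    input_count: int
    output_count: int
    removed: list[tuple[VariantKey, str]]


@dataclass
class FilterLedger:
    """Ordered audit trail of the cascade: every removal is accounted for."""

    stages: list[LedgerStage] = field(default_factory=list)

    def record(
        self,
        name: str,
        inputs: Sequence[VariantCall],
        outputs: Sequence[VariantCall],
        removed: Sequence[tuple[VariantKey, str]],
    ) -> None:
        stage = LedgerStage(name, len(inputs), len(outputs), list(removed))
        if stage.input_count != stage.output_count + len(stage.removed):
            raise AssertionError(
                f"ledger stage {name}: {stage.input_count} != "
                f"{stage.output_count} + {len(stage.removed)}"
            )
        if self.stages and stage.input_count > self.stages[-1].output_count:
            raise AssertionError(
                f"ledger stage {name}: input exceeds previous stage output"
            )
        self.stages.append(stage)

    def removal_reason(self, key: VariantKey) -> str | None:
        for stage in self.stages:
            for k, reason in stage.removed:
                if k == key:
                    return reason
        return None

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "name": s.name,
                    "input": s.input_count,
                    "output": s.output_count,
                    "removed": [
                        {"key": list(k), "reason": reason} for k, reason in s.removed
                    ],
                }
                for s in self.stages
            ]
        }


def reproducible_variants(
    replicate_samples: Sequence[SampleRecord],
) -> tuple[list[VariantCall], float]:
    """Variants called in every technical replicate, with concordance.

    The reproducible set is the intersection of the replicates' key
    sets; concordance is |intersection| / |union| (1.0 when the union
    is empty or there is a single replicate).  For reproducible
    variants, alt_reads and depth are summed across replicates, so the
    pooled depth drives the pooled LoD.
    """
    if not replicate_samples:
        raise ValueError("need at least one replicate")
    conditions = {
        (s.donor, s.treatment, s.timepoint_days) for s in replicate_samples
    }
    if len(conditions) > 1:
        raise ValueError(f"replicates from mixed conditions: {sorted(conditions)}")
    key_sets = [s.key_set for s in replicate_samples]
    intersection = frozenset.intersection(*key_sets)
    union = frozenset.union(*key_sets)
    concordance = len(intersection) / len(union) if union else 1.0
    pooled: list[VariantCall] = []
    maps = [s.by_key() for s in replicate_samples]
    for key in sorted(intersection):
        calls = [m[key] for m in maps]
        template = calls[0]
        pooled.append(
            VariantCall(
                chrom=key.chrom,
                pos=key.pos,
                ref=key.ref,
                alt=key.alt,
                alt_reads=sum(c.alt_reads for c in calls),
                depth=sum(c.depth for c in calls),
                gene=template.gene,
                effect=template.effect,
            )
        )
    return pooled, concordance


def filter_synonymous(
    variants: Sequence[VariantCall],
) -> tuple[list[VariantCall], list[tuple[VariantKey, str]]]:
    """Drop synonymous variants; everything else (noncoding included) passes.

    Unannotated variants pass with a warning — the cascade only removes
    positively identified non-pathogenic calls.
    """
    kept, removed = [], []
    for v in variants:
        if v.effect is None:
            warnings.warn(
                f"variant {v.chrom}:{v.pos} has no effect annotation; retained",
                stacklevel=2,
            )
            kept.append(v)
        elif v.effect == "synonymous":
            removed.append((v.key, "synonymous"))
        else:
            kept.append(v)
    return kept, removed


def filter_germline(
    variants: Sequence[VariantCall],
    germline_db: Mapping[VariantKey, int],
    max_occurrences: int = 10,
) -> tuple[list[VariantCall], list[tuple[VariantKey, str]]]:
    """Drop variants reported more than ``max_occurrences`` times in the
    germline database (strict inequality: a count of exactly 10 is
    retained at the default threshold); absent keys are retained."""
    kept, removed = [], []
    for v in variants:
        count = germline_db.get(v.key, 0)
        if count > max_occurrences:
            removed.append((v.key, f"germline_db_occurrences={count}"))
        else:
            kept.append(v)
    return kept, removed


def subtract_mock(
    treated_variants: Sequence[VariantCall],
    mock_keys: Iterable[VariantKey],
) -> tuple[list[VariantCall], list[tuple[VariantKey, str]]]:
    """Remove treated variants whose key appears in the donor's Mock
    reproducible set at any timepoint, regardless of VAF."""
    mock_set = frozenset(mock_keys)
    kept, removed = [], []
    for v in treated_variants:
        if v.key in mock_set:
            removed.append((v.key, "present_in_mock"))
        else:
            kept.append(v)
    return kept, removed


def strict_cas9_filter(
    variants: Sequence[VariantCall],
    guide: GuideRNA,
    reference: Mapping[str, str],
    thresholds: PipelineThresholds = PipelineThresholds(),
) -> tuple[list[VariantCall], list[tuple[VariantKey, str]]]:
    """Strict nuclease-attribution filter: remove SNVs, then remove
    remaining variants without spacer+PAM homology in their flanks."""
    kept, removed = [], []
    for v in variants:
        if v.variant_class == "SNV":
            removed.append((v.key, "strict:SNV"))
            continue
        hit = flag_grna_homology(
            v,
            reference,
            guide,
            flank=thresholds.strict_flank,
            min_match=thresholds.strict_min_match,
        )
        if hit.flagged:
            kept.append(v)
        else:
            removed.append(
                (v.key, f"strict:no_homology(best={hit.best_match_count})")
            )
    return kept, removed


def flag_chip_genes(
    variants: Sequence[VariantCall], chip_gene_list: Iterable[str]
) -> list[VariantCall]:
    """Variants in genes associated with clonal hematopoiesis (CHIP).

    Annotation only — never a removal stage."""
    chip = set(chip_gene_list)
    return [v for v in variants if v.gene in chip]


@dataclass
class ConditionResult:
    """Cascade outcome for one donor x treatment x timepoint."""

    donor: str
    treatment: str
    timepoint_days: int
    concordance: float
    pooled_mec: float
    lod: float | None
    mec_flags: list[str]
    final_variants: list[VariantCall]
    chip_flagged: list[VariantCall]
    ledger: FilterLedger


def group_by_condition(
    cohort: Sequence[SampleRecord],
) -> dict[tuple[str, str, int], list[SampleRecord]]:
    groups: dict[tuple[str, str, int], list[SampleRecord]] = defaultdict(list)
    for s in cohort:
        groups[(s.donor, s.treatment, s.timepoint_days)].append(s)
    return dict(groups)


MOCK = "MOCK"


def run_panel_cascade(
    cohort: Sequence[SampleRecord],
    thresholds: PipelineThresholds,
    guides: Mapping[str, GuideRNA],
    reference: Mapping[str, str] | None,
    germline_db: Mapping[VariantKey, int],
    detection: DetectionModel | None = None,
    strict: bool = False,
) -> dict[tuple[str, str, int], ConditionResult]:
    """Run the full screening cascade over a cohort of sample records.

    Stage order per condition: replicate concordance, synonymous
    filter, germline filter, Mock subtraction, then (``strict=True``)
    the SNV/homology filter.  Returns one :class:`ConditionResult` per
    donor x treatment x timepoint, each with a conservation-checked
    ledger.
    """
    groups = group_by_condition(cohort)
    donors = {donor for donor, _, _ in groups}
    mock_keys_by_donor: dict[str, set[VariantKey]] = {d: set() for d in donors}
    reproducible: dict[tuple[str, str, int], tuple[list[VariantCall], float]] = {}
    for cond, samples in groups.items():
        reproducible[cond] = reproducible_variants(samples)
        donor, treatment, _ = cond
        if treatment == MOCK:
            mock_keys_by_donor[donor].update(v.key for v in reproducible[cond][0])

    if thresholds.mock_subtraction:
        for donor in donors:
            has_mock = any(t == MOCK for d, t, _ in groups if d == donor)
            if not has_mock:
                raise ValueError(
                    f"donor {donor} has no Mock arm but Mock subtraction is enabled"
                )

    results: dict[tuple[str, str, int], ConditionResult] = {}
    for cond in sorted(groups):
        donor, treatment, timepoint = cond
        samples = groups[cond]
        pooled, concordance = reproducible[cond]
        ledger = FilterLedger()
        union_keys = frozenset.union(*[s.key_set for s in samples])
        pooled_keys = {v.key for v in pooled}
        ledger.stages.append(
            LedgerStage(
                "replicate_concordance",
                len(union_keys),
                len(pooled),
                [
                    (k, "not_in_all_replicates")
                    for k in sorted(union_keys - pooled_keys)
                ],
            )
        )
        current = pooled
        kept, removed = filter_synonymous(current)
        ledger.record("synonymous", current, kept, removed)
        current = kept
        kept, removed = filter_germline(
            current, germline_db, thresholds.germline_max_occurrences
        )
        ledger.record("germline_db", current, kept, removed)
        current = kept
        if thresholds.mock_subtraction and treatment != MOCK:
            kept, removed = subtract_mock(current, mock_keys_by_donor[donor])
            ledger.record("mock_subtraction", current, kept, removed)
            current = kept
        if strict and treatment != MOCK:
            if treatment not in guides:
                raise ValueError(f"no guide registered for treatment {treatment!r}")
            if reference is None:
                raise ValueError("strict filter requires a reference sequence")
            kept, removed = strict_cas9_filter(
                current, guides[treatment], reference, thresholds
            )
            ledger.record("strict_cas9", current, kept, removed)
            current = kept

        mec_flags = [
            s.sample_id
            for s in samples
            if s.median_exon_coverage < thresholds.mec_lower_spec
        ]
        if mec_flags:
            warnings.warn(
                f"samples below MEC lower specification limit "
                f"({thresholds.mec_lower_spec}): {mec_flags}",
                stacklevel=2,
            )
        pooled_mec = float(sum(s.median_exon_coverage for s in samples))
        lod = lod_at_depth(detection, pooled_mec) if detection is not None else None
        results[cond] = ConditionResult(
            donor=donor,
            treatment=treatment,
            timepoint_days=timepoint,
            concordance=concordance,
            pooled_mec=pooled_mec,
            lod=lod,
            mec_flags=mec_flags,
            final_variants=current,
            chip_flagged=flag_chip_genes(current, thresholds.chip_gene_list),
            ledger=ledger,
        )
    return results


def load_germline_db(path: str) -> dict[VariantKey, int]:
    """Load a germline occurrence database.

    TSV columns chrom, pos, ref, alt, occurrence_count; or a VCF whose
    INFO carries an allele count key ``AC``.
    """
    if path.endswith((".vcf", ".vcf.gz")):
        import pysam

        db: dict[VariantKey, int] = {}
        with pysam.VariantFile(path) as vcf:
            for rec in vcf:
                ac = rec.info.get("AC")
                counts = ac if isinstance(ac, tuple) else (ac,) * len(rec.alts or ())
                for alt, count in zip(rec.alts or (), counts):
                    if count is None:
                        raise ValueError(
                            f"{path}: record {rec.chrom}:{rec.pos} lacks INFO AC"
                        )
                    db[VariantKey(rec.chrom, rec.pos, rec.ref, alt)] = int(count)
        return db
    frame = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "ref", "alt", "occurrence_count"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"germline db {path} lacks columns: {sorted(missing)}")
    db = {}
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            key = VariantKey(str(row.chrom), int(row.pos), row.ref, row.alt)
            db[key] = int(row.occurrence_count)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"germline db {path} row {i}: {exc}") from exc
    return db
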
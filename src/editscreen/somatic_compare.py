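"""Simplified tumor-normal somatic comparison with inversion control.

The edited sample plays "tumor", the Mock control plays "normal".  For
each tumor variant a one-sided exact test (hypergeometric / Fisher) on
the 2x2 table (alt, ref) x (tumor, normal) asks whether the alt
fraction is higher in the tumor; a call is somatic when p <= alpha and
tumor VAF exceeds normal VAF.  A site absent from the normal sample
contributes zero alt reads at the normal's local depth (from a depth
track when supplied, else the sample's median exon coverage) —
absence of a call is not absence of coverage.

The printed screening filters are applied verbatim with strict
boundary semantics: exome mode removes calls with normal VAF > 0.01;
genome mode removes calls below 0.1% tumor VAF or above 1% normal
VAF.  The inversion control re-runs the comparison with labels
swapped to estimate the pipeline's background call rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import fisher_exact, pearsonr

from editscreen.guide_homology import GuideRNA, HomologyHit, flag_grna_homology, is_on_target
from editscreen.variant_model import SampleRecord, VariantKey


@dataclass(frozen=True)
class SomaticThresholds:
    """Somatic-comparison thresholds; defaults are the published filters."""

    alpha: float = 0.01
    wes_max_normal_vaf: float = 0.01
    wgs_min_tumor_vaf: float = 0.001
    wgs_max_normal_vaf: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")


@dataclass(frozen=True)
class SomaticCall:
    """One tumor-vs-normal comparison outcome at a variant site."""

    key: VariantKey
    tumor_alt: int
    tumor_depth: int
    normal_alt: int
    normal_depth: int
    p_value: float
    on_target: bool = False
    homology: HomologyHit | None = None

    @property
    def tumor_vaf(self) -> float:
        return self.tumor_alt / self.tumor_depth if self.tumor_depth else 0.0

    @property
    def normal_vaf(self) -> float:
        return self.normal_alt / self.normal_depth if self.normal_depth else 0.0

    @property
    def adjusted_vaf(self) -> float:
        """Tumor VAF with the normal (background) VAF subtracted, floored at 0."""
        return max(0.0, self.tumor_vaf - self.normal_vaf)


def somatic_p_value(
    tumor_alt: int, tumor_depth: int, normal_alt: int, normal_depth: int
) -> float:
    """One-sided exact test that the tumor alt fraction exceeds the normal's.

    Fisher's exact test (hypergeometric tail) on the 2x2 table
    [[tumor_alt, tumor_ref], [normal_alt, normal_ref]], alternative:
    tumor enriched for alt reads.
    """
    table = [
        [tumor_alt, tumor_depth - tumor_alt],
        [normal_alt, normal_depth - normal_alt],
    ]
    return float(fisher_exact(table, alternative="greater")[1])


def call_somatic(
    tumor_sample: SampleRecord,
    normal_sample: SampleRecord,
    thresholds: SomaticThresholds = SomaticThresholds(),
    normal_depth_track: Mapping[tuple[str, int], int] | None = None,
) -> list[SomaticCall]:
    """Call variants private to the tumor against the matched normal.

    Every tumor variant is tested; a call is somatic iff p <= alpha and
    tumor VAF > normal VAF.  Sites with zero depth in both samples are
    skipped with a warning.
    """
    normal_by_key = normal_sample.by_key()
    default_normal_depth = int(round(normal_sample.median_exon_coverage))
    calls: list[SomaticCall] = []
    for v in sorted(tumor_sample.variants, key=lambda v: v.key):
        counterpart = normal_by_key.get(v.key)
        if counterpart is not None:
            n_alt, n_depth = counterpart.alt_reads, counterpart.depth
        else:
            if normal_depth_track is not None:
                n_depth = int(normal_depth_track.get((v.chrom, v.pos), 0))
            else:
                n_depth = default_normal_depth
            n_alt = 0
        if v.depth == 0 and n_depth == 0:
            warnings.warn(
                f"site {v.chrom}:{v.pos} has zero depth in both samples; skipped",
                stacklevel=2,
            )
            continue
        if n_depth == 0:
            # no normal coverage: test degenerates to the tumor-only row
            n_depth = 1
        p = somatic_p_value(v.alt_reads, v.depth, n_alt, n_depth)
        call = SomaticCall(
            key=v.key,
            tumor_alt=v.alt_reads,
            tumor_depth=v.depth,
            normal_alt=n_alt,
            normal_depth=n_depth,
            p_value=p,
        )
        if p <= thresholds.alpha and call.tumor_vaf > call.normal_vaf:
            calls.append(call)
    return calls


def filter_normal_vaf(
    calls: Sequence[SomaticCall], max_normal_vaf: float = 0.01
) -> list[SomaticCall]:
    """Exome-style filter: remove calls with normal VAF strictly above
    the threshold (a call exactly at the boundary is retained)."""
    return [c for c in calls if c.normal_vaf <= max_normal_vaf]


def wgs_filter(
    calls: Sequence[SomaticCall],
    thresholds: SomaticThresholds = SomaticThresholds(),
) -> list[SomaticCall]:
    """Genome-style filter: remove calls below the minimum tumor VAF or
    above the maximum normal VAF (both strict, as printed)."""
    return [
        c
        for c in calls
        if c.tumor_vaf >= thresholds.wgs_min_tumor_vaf
        and c.normal_vaf <= thresholds.wgs_max_normal_vaf
    ]


def subtract_background_vaf(calls: Sequence[SomaticCall]) -> list[SomaticCall]:
    """Identity on fields; the adjusted (tumor - normal, floored) VAF is
    exposed via :attr:`SomaticCall.adjusted_vaf` on every call."""
    return list(calls)


def annotate_somatic_calls(
    calls: Sequence[SomaticCall],
    guide: GuideRNA,
    reference: Mapping[str, str],
    on_target_window_bp: int = 50,
    flank: int = 20,
    min_match: int = 10,
) -> list[SomaticCall]:
    """Attach gRNA-homology and on-target-window annotation to calls."""
    from editscreen.variant_model import VariantCall

    annotated = []
    for c in calls:
        v = VariantCall(
            chrom=c.key.chrom,
            pos=c.key.pos,
            ref=c.key.ref,
            alt=c.key.alt,
            alt_reads=c.tumor_alt,
            depth=c.tumor_depth,
        )
        hit = flag_grna_homology(v, reference, guide, flank=flank, min_match=min_match)
        annotated.append(
            replace(c, on_target=is_on_target(v, guide, on_target_window_bp), homology=hit)
        )
    return annotated


@dataclass
class InversionReport:
    """Forward (A as tumor) and reverse (labels swapped) call counts."""

    forward_calls: list[SomaticCall]
    reverse_calls: list[SomaticCall]

    @property
    def forward_count(self) -> int:
        return len(self.forward_calls)

    @property
    def reverse_count(self) -> int:
        return len(self.reverse_calls)

    @property
    def ratio(self) -> float:
        """forward/reverse count ratio; inf when reverse is empty but
        forward is not, 1.0 when both are empty."""
        if self.reverse_count == 0:
            return 1.0 if self.forward_count == 0 else float("inf")
        return self.forward_count / self.reverse_count

    def to_dict(self) -> dict:
        return {
            "forward": {
                "count": self.forward_count,
                "keys": [list(c.key) for c in self.forward_calls],
            },
            "reverse": {
                "count": self.reverse_count,
                "keys": [list(c.key) for c in self.reverse_calls],
            },
            "ratio": self.ratio,
        }


def inversion_control(
    sample_a: SampleRecord,
    sample_b: SampleRecord,
    thresholds: SomaticThresholds = SomaticThresholds(),
    mode: str = "wes",
) -> InversionReport:
    """Run the somatic comparison in both label orders.

    Forward treats ``sample_a`` as tumor; reverse swaps the labels.
    The two counts and their ratio estimate the pipeline's background
    call rate: with no true edits, forward and reverse should be of
    the same order.
    """
    if mode not in ("wes", "wgs"):
        raise ValueError("mode must be 'wes' or 'wgs'")

    def one_direction(tumor: SampleRecord, normal: SampleRecord) -> list[SomaticCall]:
        calls = call_somatic(tumor, normal, thresholds)
        if mode == "wes":
            return filter_normal_vaf(calls, thresholds.wes_max_normal_vaf)
        return wgs_filter(subtract_background_vaf(calls), thresholds)

    return InversionReport(
        forward_calls=one_direction(sample_a, sample_b),
        reverse_calls=one_direction(sample_b, sample_a),
    )


def coverage_concordance(
    depth_track_a: Sequence[float], depth_track_b: Sequence[float]
) -> float:
    """Pearson correlation of two positional depth tracks.

    Returns NaN (flagged sentinel) when either track has zero variance.
    """
    a = np.asarray(depth_track_a, dtype=float)
    b = np.asarray(depth_track_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("depth tracks must have equal length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("zero-variance depth track; correlation undefined", stacklevel=2)
        return float("nan")
    return float(pearsonr(a, b)[0])


def coverage_dropout_check(
    depth_track: Sequence[float],
    cut_pos: int,
    window_bp: int = 50,
    flag_ratio: float = 0.5,
) -> tuple[float, bool]:
    """Depth-drop proxy for large on-target lesions near the cut site.

    ``depth_track[i]`` is the depth at 1-based position ``i + 1``.
    The ratio is the mean depth within ``cut_pos +/- window_bp`` over
    the median of the rest of the track; a ratio below ``flag_ratio``
    flags a drop.
    """
    track = np.asarray(depth_track, dtype=float)
    lo, hi = cut_pos - window_bp, cut_pos + window_bp  # 1-based inclusive
    if lo < 1 or hi > len(track):
        raise ValueError(
            f"window [{lo}, {hi}] outside depth track of length {len(track)}"
        )
    window = track[lo - 1 : hi]
    background = np.concatenate([track[: lo - 1], track[hi:]])
    if background.size == 0:
        raise ValueError("no background positions outside the window")
    denom = float(np.median(background))
    if denom == 0:
        raise ValueError("background depth is zero; ratio undefined")
    ratio = float(np.mean(window)) / denom
    return ratio, ratio < flag_ratio
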
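"""Depth-to-LoD mapping calibrated to the panel's operating point.

The default model assumes a constant expected number of supporting alt
reads at the limit of detection: calibrating at an anchor point
(depth_anchor, lod_anchor) fixes lambda_star = depth_anchor *
lod_anchor, and LoD(d) = lambda_star / d thereafter.  The panel's
printed operating pair (LoD 0.205% VAF at median exon coverage 3550,
95% sensitivity) is a vendor-validated anchor, not a quantity this
model derives; an explicit binomial k-of-n detection mode (``k_min``)
is provided for sensitivity analyses.  Pooling technical replicates
sums their depths, which is what drives the pooled LoD below the
single-replicate value.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import binom


@dataclass(frozen=True)
class DetectionModel:
    """Calibrated depth -> minimum-detectable-VAF mapping."""

    sensitivity_target: float = 0.95
    lambda_star: float = 7.2775
    k_min: int | None = None
    anchor: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.sensitivity_target < 1:
            raise ValueError("sensitivity_target must be in (0, 1)")
        if self.lambda_star <= 0:
            raise ValueError("lambda_star must be positive")
        if self.k_min is not None and self.k_min < 1:
            raise ValueError("k_min must be >= 1 when set")

    def lod_at_depth(self, depth: float) -> float:
        return lod_at_depth(self, depth)


def calibrate(
    depth_anchor: float,
    lod_anchor: float,
    sensitivity_target: float = 0.95,
    k_min: int | None = None,
) -> DetectionModel:
    """Calibrate the constant-expected-alt-reads model at an anchor point.

    ``lambda_star = depth_anchor * lod_anchor``, so the returned model
    reproduces the anchor exactly: ``lod_at_depth(depth_anchor) ==
    lod_anchor``.
    """
    if depth_anchor <= 0:
        raise ValueError("depth_anchor must be positive")
    if not 0 < lod_anchor < 1:
        raise ValueError("lod_anchor must be a VAF in (0, 1)")
    return DetectionModel(
        sensitivity_target=sensitivity_target,
        lambda_star=depth_anchor * lod_anchor,
        k_min=k_min,
        anchor=(depth_anchor, lod_anchor),
    )


def detection_sensitivity(vaf: float, depth: int, k_min: int) -> float:
    """P(at least k_min alt reads) for alt reads ~ Binomial(depth, vaf)."""
    if not 0 <= vaf <= 1:
        raise ValueError("vaf must be in [0, 1]")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if k_min < 0:
        raise ValueError("k_min must be >= 0")
    if k_min == 0:
        return 1.0
    # survival function: stable upper-tail sum
    return float(binom.sf(k_min - 1, depth, vaf))


def lod_at_depth(model: DetectionModel, depth: float) -> float:
    """Minimum detectable VAF at the given depth.

    Constant-lambda law ``lambda_star / depth`` by default; with
    ``k_min`` set, the smallest VAF whose binomial detection
    probability reaches the sensitivity target (bisection to 1e-9).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if model.k_min is None:
        return model.lambda_star / depth
    n = int(round(depth))
    target = model.sensitivity_target
    lo, hi = 0.0, 1.0
    if detection_sensitivity(1.0, n, model.k_min) < target:
        raise ValueError(
            f"k_min={model.k_min} unreachable at depth {n} even at VAF 1"
        )
    while hi - lo > 1e-9:
        mid = 0.5 * (lo + hi)
        if detection_sensitivity(mid, n, model.k_min) >= target:
            hi = mid
        else:
            lo = mid
    return hi


def pooled_depth(replicate_depths: list[float]) -> float:
    """Effective depth of pooled technical replicates: the sum."""
    if not replicate_depths or any(d <= 0 for d in replicate_depths):
        raise ValueError("replicate depths must be positive")
    return float(sum(replicate_depths))
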
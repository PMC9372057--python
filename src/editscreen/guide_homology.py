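"""gRNA (spacer+PAM) homology scoring around variant loci.

A variant is annotated with the best ungapped placement of the 23-mer
(20-nt spacer concatenated with the 3-nt PAM pattern) within a window
of the reference flanking the variant, on either strand.  Following
the screening rule used downstream, a site is "homologous" when the
best placement matches at >= 10 of the 23 positions within 20 bp
upstream or downstream of the variant; the threshold counts total
positional matches, not a contiguous run (a contiguous-run mode is
available).  N in the PAM pattern matches any base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

from editscreen.variant_model import VariantCall

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_GUIDE_CHARS = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GuideRNA:
    """One nuclease treatment: spacer, PAM pattern and genomic target site.

    ``cut_pos`` is the 1-based position of the blunt cut, between
    protospacer positions 17 and 18 (3 bp 5' of the PAM).
    """

    name: str
    spacer: str
    pam: str
    target_chrom: str
    cut_pos: int
    strand: str

    def __post_init__(self) -> None:
        if len(self.spacer) != 20:
            raise ValueError(f"{self.name}: spacer must be 20 nt")
        if len(self.pam) != 3:
            raise ValueError(f"{self.name}: PAM pattern must be 3 nt")
        if not _GUIDE_CHARS.issuperset(self.spacer.upper() + self.pam.upper()):
            raise ValueError(f"{self.name}: spacer/PAM characters must be ACGTN")
        if self.strand not in "+-":
            raise ValueError(f"{self.name}: strand must be + or -")

    @property
    def query(self) -> str:
        """Spacer+PAM 23-mer used for homology scoring."""
        return (self.spacer + self.pam).upper()


@dataclass(frozen=True)
class HomologyHit:
    """Best spacer+PAM placement near one variant."""

    chrom: str
    pos: int
    ref: str
    alt: str
    best_match_count: int
    best_offset: int
    best_strand: str
    flagged: bool

    def __post_init__(self) -> None:
        if not 0 <= self.best_match_count <= 23:
            raise ValueError("best_match_count must be in [0, 23]")


def _match_count(query: str, window: str, offset: int) -> int:
    return sum(
        q == "N" or q == w for q, w in zip(query, window[offset : offset + len(query)])
    )


def best_homology(
    window_seq: str, spacer: str, pam: str, contiguous: bool = False
) -> tuple[int, int, str]:
    """Best ungapped placement of spacer+PAM in a window, both strands.

    Slides the 23-mer across every offset of ``window_seq`` and of its
    reverse complement, counting positional matches (N matches any
    base).  Returns ``(match_count, offset, strand)`` where ``offset``
    is the 0-based start of the placement in the given window's
    coordinates.  Ties break toward the smallest offset, plus strand
    first.  With ``contiguous=True`` the score is the longest run of
    consecutive matches instead of the total.
    """
    query = (spacer + pam).upper()
    window_seq = window_seq.upper()
    k = len(query)
    if len(window_seq) < k:
        raise ValueError(
            f"window length {len(window_seq)} shorter than query length {k}"
        )
    scorer = _longest_run if contiguous else _match_count
    n_offsets = len(window_seq) - k + 1
    rc = reverse_complement(window_seq)
    placements: list[tuple[int, int, int, str]] = []  # (-count, strand_rank, offset, strand)
    for offset in range(n_offsets):
        placements.append((-scorer(query, window_seq, offset), 0, offset, "+"))
    for rc_offset in range(n_offsets):
        # report minus-strand placements in the original window's coordinates
        offset = len(window_seq) - k - rc_offset
        placements.append((-scorer(query, rc, rc_offset), 1, offset, "-"))
    neg_count, _, offset, strand = min(placements)
    return -neg_count, offset, strand


def _longest_run(query: str, window: str, offset: int) -> int:
    run = best = 0
    for q, w in zip(query, window[offset : offset + len(query)]):
        run = run + 1 if (q == "N" or q == w) else 0
        best = max(best, run)
    return best


def flag_grna_homology(
    variant: VariantCall,
    reference: Mapping[str, str],
    guide: GuideRNA,
    flank: int = 20,
    min_match: int = 10,
    contiguous: bool = False,
) -> HomologyHit:
    """Score spacer+PAM homology in the flanks of a variant.

    The scored window spans ``flank`` bases upstream of the variant
    through ``flank`` bases downstream of the REF allele end, extended
    by 22 bases on each side so that every 23-mer placement overlapping
    the window is evaluated.  The hit is flagged when the best
    placement matches at >= ``min_match`` positions.
    """
    chrom_seq = reference[variant.chrom]
    span_start, span_end = variant.ref_span
    lo = span_start - flank - 22  # 1-based
    hi = span_end + flank + 22
    if lo < 1 or hi > len(chrom_seq):
        warnings.warn(
            f"homology window for {variant.chrom}:{variant.pos} truncated at "
            "contig edge",
            stacklevel=2,
        )
        lo = max(lo, 1)
        hi = min(hi, len(chrom_seq))
    window = chrom_seq[lo - 1 : hi]
    count, offset, strand = best_homology(
        window, guide.spacer, guide.pam, contiguous=contiguous
    )
    return HomologyHit(
        chrom=variant.chrom,
        pos=variant.pos,
        ref=variant.ref,
        alt=variant.alt,
        best_match_count=count,
        best_offset=(lo + offset) - variant.pos,  # signed, relative to variant
        best_strand=strand,
        flagged=count >= min_match,
    )


def is_on_target(variant: VariantCall, guide: GuideRNA, window_bp: int = 50) -> bool:
    """True iff any REF base lies within ``window_bp`` of the cut site
    (inclusive) on the guide's target chromosome."""
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    if variant.chrom != guide.target_chrom:
        return False
    span_start, span_end = variant.ref_span
    if span_start <= guide.cut_pos <= span_end:
        return True
    distance = min(abs(span_start - guide.cut_pos), abs(span_end - guide.cut_pos))
    return distance <= window_bp


def cut_position(protospacer_start: int, strand: str) -> int:
    """Blunt-cut position for a protospacer starting at the given
    1-based position: between spacer positions 17 and 18 (3 bp 5' of
    the PAM).  Returns the position of spacer base 17 on the plus
    strand, base 18's genomic equivalent for minus-strand protospacers."""
    if strand == "+":
        return protospacer_start + 16
    return protospacer_start + 3
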
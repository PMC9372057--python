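"""Coding-effect classification against a toy gene model.

Only the distinction the downstream cascade needs is modeled:
synonymous vs everything else, with the usual finer labels (missense,
nonsense, frameshift, in-frame indel, noncoding).  Gene models are CDS
intervals only — no UTRs, splice sites or alternative isoforms — which
is all the synonymous filter requires.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from editscreen.variant_model import VariantCall

_DNA = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_STOPS = {"TAA", "TAG", "TGA"}


class GeneModelError(ValueError):
    """A gene model violates its structural invariants."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(seq: str) -> str:
    """Translate a CDS with the standard table, stop rendered as '*'.

    Requires length a multiple of 3 and ACGT characters only.
    """
    seq = seq.upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} is not a multiple of 3")
    if not _DNA.issuperset(seq):
        raise ValueError("CDS contains non-ACGT characters")
    if not seq:
        return ""
    return str(Seq(seq).translate(table=1))


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript gene: strand plus ordered CDS intervals.

    ``cds_intervals`` are 1-based inclusive genomic intervals ordered
    5'->3' in transcript orientation (descending genomic coordinate for
    minus-strand genes).
    """

    gene: str
    chrom: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GeneModelError(f"{self.gene}: strand must be + or -")
        if not self.cds_intervals:
            raise GeneModelError(f"{self.gene}: no CDS intervals")
        for start, end in self.cds_intervals:
            if start > end:
                raise GeneModelError(f"{self.gene}: interval {start}-{end} inverted")
        genomic = sorted(self.cds_intervals)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise GeneModelError(f"{self.gene}: overlapping CDS intervals")
        if self.cds_length % 3 != 0:
            raise GeneModelError(
                f"{self.gene}: CDS length {self.cds_length} not a multiple of 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds_intervals)

    def contains(self, pos: int) -> bool:
        return any(start <= pos <= end for start, end in self.cds_intervals)

    def genomic_to_cds(self, pos: int) -> int:
        """0-based CDS coordinate of a genomic position inside the CDS."""
        offset = 0
        for start, end in self.cds_intervals:
            if start <= pos <= end:
                return offset + (pos - start if self.strand == "+" else end - pos)
            offset += end - start + 1
        raise ValueError(f"{self.chrom}:{pos} not in CDS of {self.gene}")

    def cds_sequence(self, reference: Mapping[str, str]) -> str:
        """Coding-strand CDS sequence spliced from the reference."""
        chrom_seq = reference[self.chrom]
        parts = []
        for start, end in self.cds_intervals:
            piece = chrom_seq[start - 1 : end].upper()
            if self.strand == "-":
                piece = reverse_complement(piece)
            parts.append(piece)
        return "".join(parts)

    def validate_against(self, reference: Mapping[str, str]) -> None:
        cds = self.cds_sequence(reference)
        if not cds.startswith("ATG"):
            raise GeneModelError(f"{self.gene}: CDS does not start with ATG")
        if cds[-3:] not in _STOPS:
            raise GeneModelError(f"{self.gene}: CDS does not end in a stop codon")


def annotate_effect(
    variant: VariantCall,
    gene_models: Iterable[GeneModel],
    reference: Mapping[str, str],
) -> str:
    """Classify a variant's coding effect against the gene models.

    Substitutions fully inside a CDS are re-translated as a block:
    identical protein -> synonymous, stop gained -> nonsense, else
    missense.  CDS indels are frameshift unless the net length change
    is a multiple of 3 (inframe_indel).  Variants outside every CDS are
    noncoding; a variant straddling a CDS boundary is labeled noncoding
    with a warning rather than guessed.
    """
    span_start, span_end = variant.ref_span
    for model in gene_models:
        if model.chrom != variant.chrom:
            continue
        inside_start = model.contains(span_start)
        inside_end = model.contains(span_end)
        if not (inside_start or inside_end):
            continue
        if not (inside_start and inside_end):
            warnings.warn(
                f"variant {variant.chrom}:{variant.pos} straddles a CDS boundary "
                f"of {model.gene}; labeled noncoding",
                stacklevel=2,
            )
            return "noncoding"
        if variant.variant_class in ("INS", "DEL"):
            net = abs(len(variant.alt) - len(variant.ref))
            return "frameshift" if net % 3 else "inframe_indel"
        return _substitution_effect(variant, model, reference)
    return "noncoding"


def _substitution_effect(
    variant: VariantCall, model: GeneModel, reference: Mapping[str, str]
) -> str:
    cds = model.cds_sequence(reference)
    ref_allele, alt_allele = variant.ref, variant.alt
    positions = [
        model.genomic_to_cds(variant.pos + i) for i in range(len(ref_allele))
    ]
    if model.strand == "-":
        ref_allele = reverse_complement(ref_allele)
        alt_allele = reverse_complement(alt_allele)
        positions = positions[::-1]
    # contiguity holds because the variant lies fully inside one interval
    start = positions[0]
    if cds[start : start + len(ref_allele)] != ref_allele:
        raise ValueError(
            f"reference allele mismatch for {variant.chrom}:{variant.pos} "
            f"in {model.gene}"
        )
    mutated = cds[:start] + alt_allele + cds[start + len(ref_allele) :]
    codon_lo = start // 3
    codon_hi = (start + len(ref_allele) - 1) // 3
    ref_block = cds[codon_lo * 3 : (codon_hi + 1) * 3]
    alt_block = mutated[codon_lo * 3 : (codon_hi + 1) * 3]
    ref_aa = translate_cds(ref_block)
    alt_aa = translate_cds(alt_block)
    if alt_aa == ref_aa:
        return "synonymous"
    if any(a == "*" and r != "*" for r, a in zip(ref_aa, alt_aa)):
        return "nonsense"
    return "missense"


def load_gene_models_gff3(path: str) -> list[GeneModel]:
    """Load gene models from a GFF3 subset: CDS features with a gene attribute."""
    import gffutils

    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    by_gene: dict[str, dict] = {}
    for feat in db.features_of_type("CDS"):
        gene = feat.attributes.get("gene", feat.attributes.get("Parent", [None]))[0]
        if gene is None:
            raise GeneModelError(f"{path}: CDS feature without a gene attribute")
        entry = by_gene.setdefault(
            gene, {"chrom": feat.seqid, "strand": feat.strand, "intervals": []}
        )
        if entry["chrom"] != feat.seqid or entry["strand"] != feat.strand:
            raise GeneModelError(f"{gene}: CDS features disagree on chrom/strand")
        entry["intervals"].append((feat.start, feat.end))
    models = []
    for gene, entry in by_gene.items():
        intervals = sorted(entry["intervals"], reverse=entry["strand"] == "-")
        models.append(
            GeneModel(
                gene=gene,
                chrom=entry["chrom"],
                strand=entry["strand"],
                cds_intervals=tuple(intervals),
            )
        )
    return models


def write_gene_models_gff3(models: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            for start, end in sorted(m.cds_intervals):
                fh.write(
                    f"{m.chrom}\teditscreen\tCDS\t{start}\t{end}\t.\t{m.strand}\t0"
                    f"\tgene={m.gene}\n"
                )
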
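"""Core variant data types and VCF/TSV ingestion and emission.

Coordinates are 1-based, inclusive, VCF-style throughout.  Variant
identity across samples (Mock subtraction, germline lookup) is purely
key-based, so indels are left-aligned and minimally represented on
ingestion before keying.  VAF is always recomputed as alt_reads/depth,
even when the input carries an AF field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
import pysam

_DNA = frozenset("ACGT")

VARIANT_CLASSES = ("SNV", "MNV", "INS", "DEL")
EFFECTS = (
    "synonymous",
    "missense",
    "nonsense",
    "frameshift",
    "inframe_indel",
    "noncoding",
)


class VcfFormatError(ValueError):
    """Input VCF lacks required fields or has an unparseable record."""


class VariantConsistencyError(ValueError):
    """Counts violate a variant invariant (e.g. alt_reads > depth)."""


class VariantKey(NamedTuple):
    """Identity of a variant: two calls are the same variant iff keys match."""

    chrom: str
    pos: int
    ref: str
    alt: str


def classify_variant(ref: str, alt: str) -> str:
    """Classify an allele pair as SNV, MNV, INS or DEL.

    Single-base substitution -> SNV; equal-length multi-base
    substitution -> MNV; longer alt -> INS; longer ref -> DEL.

    Raises ``ValueError`` for ref == alt or non-ACGT characters.
    """
    if not ref or not alt:
        raise ValueError("ref and alt must be non-empty")
    if not _DNA.issuperset(ref) or not _DNA.issuperset(alt):
        raise ValueError(f"non-ACGT characters in allele pair ({ref!r}, {alt!r})")
    if ref == alt:
        raise ValueError("ref == alt is not a variant")
    if len(ref) == len(alt):
        return "SNV" if len(ref) == 1 else "MNV"
    return "INS" if len(alt) > len(ref) else "DEL"


@dataclass
class VariantCall:
    """One called variant with read support and optional annotation.

    ``vaf`` and ``variant_class`` are derived from the other fields and
    validated on construction.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    alt_reads: int
    depth: int
    gene: str | None = None
    effect: str | None = None
    vaf: float = field(init=False)
    variant_class: str = field(init=False)

    def __post_init__(self) -> None:
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        self.variant_class = classify_variant(self.ref, self.alt)
        if self.depth < 1:
            raise VariantConsistencyError(
                f"depth must be >= 1 for a called variant, got {self.depth}"
            )
        if not 0 <= self.alt_reads <= self.depth:
            raise VariantConsistencyError(
                f"alt_reads {self.alt_reads} outside [0, depth={self.depth}] "
                f"at {self.chrom}:{self.pos}"
            )
        if self.effect is not None and self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")
        self.vaf = self.alt_reads / self.depth

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)

    @property
    def ref_span(self) -> tuple[int, int]:
        """1-based inclusive interval of reference bases covered by REF."""
        return self.pos, self.pos + len(self.ref) - 1


@dataclass
class SampleRecord:
    """One sequenced condition with its variant calls and depth QC metric."""

    sample_id: str
    donor: str
    treatment: str
    timepoint_days: int
    replicate: int
    variants: list[VariantCall]
    median_exon_coverage: float

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if self.median_exon_coverage <= 0:
            raise ValueError("median_exon_coverage must be positive")
        keys = [v.key for v in self.variants]
        if len(keys) != len(set(keys)):
            dupes = {k for k in keys if keys.count(k) > 1}
            raise VariantConsistencyError(
                f"duplicate variant keys within sample {self.sample_id}: {sorted(dupes)}"
            )

    @property
    def key_set(self) -> frozenset[VariantKey]:
        return frozenset(v.key for v in self.variants)

    def by_key(self) -> dict[VariantKey, VariantCall]:
        return {v.key: v for v in self.variants}


def normalize_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    reference: Mapping[str, str] | None = None,
) -> tuple[int, str, str]:
    """Left-align and minimally represent an allele pair.

    Standard normalization: trim shared suffix bases (left-extending
    from the reference when an allele would become empty), then trim
    shared prefix bases.  Without a reference only trimming is applied,
    which is sufficient for alleles already anchored VCF-style.
    """
    ref, alt = ref.upper(), alt.upper()
    while True:
        changed = False
        if len(ref) >= 1 and len(alt) >= 1 and ref[-1] == alt[-1] and not (
            len(ref) == 1 and len(alt) == 1
        ):
            if len(ref) == 1 or len(alt) == 1:
                if reference is None:
                    break
                seq = reference[chrom]
                if pos < 2:
                    break
                base = seq[pos - 2].upper()
                ref = base + ref[:-1]
                alt = base + alt[:-1]
                pos -= 1
            else:
                ref, alt = ref[:-1], alt[:-1]
            changed = True
        if not changed:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _sample_record_from_calls(
    calls: Iterable[VariantCall], sample_metadata: Mapping[str, object]
) -> SampleRecord:
    return SampleRecord(
        sample_id=str(sample_metadata["sample_id"]),
        donor=str(sample_metadata["donor"]),
        treatment=str(sample_metadata["treatment"]),
        timepoint_days=int(sample_metadata["timepoint_days"]),  # type: ignore[arg-type]
        replicate=int(sample_metadata["replicate"]),  # type: ignore[arg-type]
        variants=list(calls),
        median_exon_coverage=float(sample_metadata["median_exon_coverage"]),  # type: ignore[arg-type]
    )


def parse_vcf(
    path: str,
    sample_metadata: Mapping[str, object],
    reference: Mapping[str, str] | None = None,
) -> SampleRecord:
    """Read a single-sample VCF into a :class:`SampleRecord`.

    Depth is taken from FORMAT ``DP`` and per-allele support from FORMAT
    ``AD`` (ref followed by one count per alt).  Multi-allelic records
    are split into one :class:`VariantCall` per alt allele.  The coding
    effect is read from INFO ``EFF`` when present.  Alleles are
    normalized (left-aligned, minimal) before keying when a reference
    is supplied.

    ``sample_metadata`` must carry sample_id, donor, treatment,
    timepoint_days, replicate and median_exon_coverage: metadata comes
    from a sidecar sample sheet, never from file names.
    """
    calls: list[VariantCall] = []
    with pysam.VariantFile(path) as vcf:
        if len(vcf.header.samples) != 1:
            raise VcfFormatError(
                f"{path}: expected exactly one sample column, "
                f"found {len(vcf.header.samples)}"
            )
        sample_name = vcf.header.samples[0]
        has_eff = "EFF" in vcf.header.info
        has_gene = "GENE" in vcf.header.info
        for rec in vcf:
            fmt = rec.samples[sample_name]
            where = f"{path}: record {rec.chrom}:{rec.pos}"
            if "DP" not in fmt or fmt["DP"] is None:
                raise VcfFormatError(f"{where} lacks FORMAT DP")
            if "AD" not in fmt or fmt["AD"] is None:
                raise VcfFormatError(f"{where} lacks FORMAT AD")
            depth = int(fmt["DP"])
            ad = tuple(int(x) for x in fmt["AD"])
            alts = rec.alts or ()
            if len(ad) != 1 + len(alts):
                raise VcfFormatError(
                    f"{where}: AD has {len(ad)} entries for {len(alts)} alt allele(s)"
                )
            effect = rec.info.get("EFF") if has_eff else None
            gene = rec.info.get("GENE") if has_gene else None
            for i, alt in enumerate(alts):
                alt_reads = ad[1 + i]
                if alt_reads > depth:
                    raise VariantConsistencyError(
                        f"{where}: alt_reads {alt_reads} exceeds depth {depth}"
                    )
                pos, ref_a, alt_a = normalize_variant(
                    rec.chrom, rec.pos, rec.ref, alt, reference
                )
                calls.append(
                    VariantCall(
                        chrom=rec.chrom,
                        pos=pos,
                        ref=ref_a,
                        alt=alt_a,
                        alt_reads=alt_reads,
                        depth=depth,
                        gene=gene,
                        effect=effect,
                    )
                )
    return _sample_record_from_calls(calls, sample_metadata)


_VCF_HEADER_LINES = (
    '##INFO=<ID=EFF,Number=1,Type=String,Description="Coding effect">',
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
)

TSV_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "alt_reads",
    "depth",
    "vaf",
    "gene",
    "effect",
    "variant_class",
)


def variants_to_frame(variants: Sequence[VariantCall]) -> pd.DataFrame:
    """Tabulate calls in stable (chrom, pos, ref, alt) order."""
    rows = [
        {
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "alt_reads": v.alt_reads,
            "depth": v.depth,
            "vaf": v.vaf,
            "gene": v.gene,
            "effect": v.effect,
            "variant_class": v.variant_class,
        }
        for v in sorted(variants, key=lambda v: v.key)
    ]
    return pd.DataFrame(rows, columns=list(TSV_COLUMNS))


def write_variants(
    sample_or_variants: SampleRecord | Sequence[VariantCall],
    path: str,
    format: str = "VCF",
) -> None:
    """Write calls as VCF (FORMAT DP/AD, INFO EFF/GENE) or TSV.

    Round-trip safe: ``parse_vcf(write_variants(s))`` reproduces keys,
    alt_reads and depths exactly.
    """
    if isinstance(sample_or_variants, SampleRecord):
        variants = sample_or_variants.variants
        sample_name = sample_or_variants.sample_id
    else:
        variants = list(sample_or_variants)
        sample_name = "SAMPLE"
    variants = sorted(variants, key=lambda v: v.key)
    fmt = format.upper()
    if fmt == "TSV":
        variants_to_frame(variants).to_csv(path, sep="\t", index=False)
        return
    if fmt != "VCF":
        raise ValueError(f"unknown format {format!r}")

    header = pysam.VariantHeader()
    for line in _VCF_HEADER_LINES:
        header.add_line(line)
    contigs: list[str] = []
    for v in variants:
        if v.chrom not in contigs:
            contigs.append(v.chrom)
    for chrom in contigs:
        header.contigs.add(chrom)
    header.add_sample(sample_name)
    with pysam.VariantFile(path, "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                alleles=(v.ref, v.alt),
            )
            if v.effect is not None:
                rec.info["EFF"] = v.effect
            if v.gene is not None:
                rec.info["GENE"] = v.gene
            rec.samples[sample_name]["DP"] = v.depth
            rec.samples[sample_name]["AD"] = (v.depth - v.alt_reads, v.alt_reads)
            out.write(rec)


def load_sample_sheet(path: str) -> pd.DataFrame:
    """Read the sample sheet TSV mapping sample ids to design metadata."""
    required = {
        "sample_id",
        "donor",
        "treatment",
        "timepoint_days",
        "replicate",
        "vcf_path",
    }
    sheet = pd.read_csv(path, sep="\t", dtype={"donor": str})
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet {path} lacks columns: {sorted(missing)}")
    return sheet
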
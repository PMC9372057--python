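"""Synthetic cohort generator.

Emulates the screening study's design — donors x {Mock, guide
treatments} x harvest days x technical replicates — on a small
synthetic reference, so every pipeline stage is testable without
external data.  Each donor carries heterozygous/homozygous germline
variants (true VAF 0.5 / 1.0, binomial read sampling at
negative-binomial depths), low-VAF sequencing-noise variants,
optional intermediate-VAF chimerism variants, and planted on- and
off-target edit indel spectra at configured per-timepoint VAFs.
Guides are embedded in the reference as protospacer+PAM sites;
off-target sites are engineered to an exact spacer+PAM match count.

Everything is deterministic given (config, seed): the same
configuration yields byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from editscreen.effect_annotation import (
    GeneModel,
    annotate_effect,
    reverse_complement,
    write_gene_models_gff3,
)
from editscreen.guide_homology import GuideRNA, best_homology, cut_position
from editscreen.variant_model import (
    SampleRecord,
    VariantCall,
    VariantKey,
    normalize_variant,
    write_variants,
)

MOCK = "MOCK"

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}

# genes of the synthetic panel; a CHIP-associated subset is flagged downstream
DEFAULT_GENES = (
    "TP53", "EZH2", "DNMT3A", "TET2", "ASXL1", "JAK2",
    "KRAS", "NRAS", "RUNX1", "GATA2", "BRAF", "SF3B1",
)
DEFAULT_CHIP_GENES = frozenset(
    {"DNMT3A", "TET2", "ASXL1", "JAK2", "RUNX1", "GATA2", "SF3B1"}
)


@dataclass(frozen=True)
class PlantedEdit:
    """One engineered cut site and the indel spectrum planted there.

    ``vaf_by_timepoint`` gives the total edit VAF per harvest day; the
    spectrum weights split it across net indel lengths (negative =
    deletion).  ``homology_match_count`` is the engineered spacer+PAM
    match count of the site (23 = perfect, i.e. the on-target site).
    """

    guide: str
    kind: str  # "on_target" | "off_target"
    homology_match_count: int = 23
    vaf_by_timepoint: Mapping[int, float] = field(
        default_factory=lambda: {4: 0.85, 10: 0.85}
    )
    indel_spectrum: Mapping[int, float] = field(
        default_factory=lambda: {-1: 0.5, 1: 0.25, -2: 0.15, 3: 0.1}
    )
    gene: str | None = None  # place the site inside this gene's CDS

    def __post_init__(self) -> None:
        if self.kind not in ("on_target", "off_target"):
            raise ValueError("kind must be on_target or off_target")
        if not 0 <= self.homology_match_count <= 23:
            raise ValueError("homology_match_count must be in [0, 23]")
        if any(not 0 <= v <= 1 for v in self.vaf_by_timepoint.values()):
            raise ValueError("per-timepoint VAFs must be in [0, 1]")
        if any(l == 0 for l in self.indel_spectrum):
            raise ValueError("indel spectrum lengths must be nonzero")
        if abs(sum(self.indel_spectrum.values()) - 1.0) > 1e-9:
            raise ValueError("indel spectrum weights must sum to 1")


def _default_edits() -> tuple[PlantedEdit, ...]:
    # one high-activity on-target edit per guide, plus one homologous
    # off-target inside EZH2 with the declining VAF trajectory used as
    # the worked example (21.7% at d4, 16.9% at d10)
    return (
        PlantedEdit(guide="AAVS1", kind="on_target"),
        PlantedEdit(guide="HBB", kind="on_target"),
        PlantedEdit(guide="ZFPM2", kind="on_target"),
        PlantedEdit(
            guide="ZFPM2",
            kind="off_target",
            homology_match_count=20,
            vaf_by_timepoint={4: 0.217, 10: 0.169},
            gene="EZH2",
        ),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Study-design and noise parameters of the synthetic cohort.

    Defaults emulate the screening study's conditions: 3 donors, Mock
    plus three guide treatments, harvests at days 0 (Mock only), 4 and
    10, 3 technical replicates, median exon coverage around 3550, and
    about 1490 germline variants per donor.
    """

    seed: int = 0
    n_donors: int = 3
    guide_names: tuple[str, ...] = ("AAVS1", "HBB", "ZFPM2")
    timepoints_days: tuple[int, ...] = (0, 4, 10)
    n_replicates: int = 3
    target_mec: float = 3550.0
    mec_dispersion: float = 10.0
    n_germline_per_donor: int = 1490
    het_fraction: float = 2 / 3
    germline_synonymous_fraction: float = 0.25
    germline_db_holdout_fraction: float = 0.003
    noise_rate: float = 8.5
    noise_vaf_range: tuple[float, float] = (0.0005, 0.005)
    chimerism_per_donor: int = 2
    chimerism_vaf_range: tuple[float, float] = (0.05, 0.35)
    planted_edits: tuple[PlantedEdit, ...] = field(default_factory=_default_edits)
    reference_length: int = 60_000
    chrom: str = "chr1"
    gene_names: tuple[str, ...] = DEFAULT_GENES
    cds_length: int = 900

    def __post_init__(self) -> None:
        if self.n_donors < 1 or self.n_replicates < 1:
            raise ValueError("n_donors and n_replicates must be >= 1")
        if not 0 <= self.het_fraction <= 1:
            raise ValueError("het_fraction must be in [0, 1]")
        if not 0 <= self.germline_db_holdout_fraction <= 1:
            raise ValueError("germline_db_holdout_fraction must be in [0, 1]")
        if self.noise_rate < 0 or self.n_germline_per_donor < 0:
            raise ValueError("counts and rates must be >= 0")
        if self.cds_length % 3 != 0:
            raise ValueError("cds_length must be a multiple of 3")
        for edit in self.planted_edits:
            if edit.guide not in self.guide_names:
                raise ValueError(
                    f"planted edit references unknown guide {edit.guide!r}"
                )

    @property
    def treatments(self) -> tuple[str, ...]:
        return (MOCK,) + self.guide_names

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["planted_edits"] = [
            {
                **dataclasses.asdict(e),
                "vaf_by_timepoint": {int(k): float(v) for k, v in e.vaf_by_timepoint.items()},
                "indel_spectrum": {int(k): float(v) for k, v in e.indel_spectrum.items()},
            }
            for e in self.planted_edits
        ]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "planted_edits" in d:
            d["planted_edits"] = tuple(
                PlantedEdit(
                    guide=e["guide"],
                    kind=e["kind"],
                    homology_match_count=e.get("homology_match_count", 23),
                    vaf_by_timepoint={
                        int(k): float(v) for k, v in e["vaf_by_timepoint"].items()
                    },
                    indel_spectrum={
                        int(k): float(v) for k, v in e["indel_spectrum"].items()
                    },
                    gene=e.get("gene"),
                )
                for e in d["planted_edits"]
            )
        for key in ("guide_names", "timepoints_days", "gene_names"):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("noise_vaf_range", "chimerism_vaf_range"):
            if key in d:
                d[key] = tuple(float(x) for x in d[key])
        return cls(**d)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted variant."""

    key: VariantKey
    category: str  # germline_het | germline_hom | noise | chimerism |
    #                on_target_edit | off_target_edit
    true_vaf: float | None  # constant-VAF categories
    vaf_by_timepoint: Mapping[int, float] | None  # edits
    donor: str | None  # None = present in every donor
    treatment: str | None  # edits: the guide arm carrying it
    gene: str | None
    effect: str | None
    homology_match_count: int | None


@dataclass
class TruthTable:
    records: list[TruthRecord]

    def __post_init__(self) -> None:
        seen: dict[tuple[str | None, VariantKey], str] = {}
        for r in self.records:
            ident = (r.donor, r.key)
            if ident in seen and seen[ident] != r.category:
                raise ValueError(f"key {r.key} planted in two categories")
            seen[ident] = r.category

    def by_category(self, category: str) -> list[TruthRecord]:
        return [r for r in self.records if r.category == category]

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "key": list(r.key),
                    "category": r.category,
                    "true_vaf": r.true_vaf,
                    "vaf_by_timepoint": (
                        {str(k): v for k, v in r.vaf_by_timepoint.items()}
                        if r.vaf_by_timepoint is not None
                        else None
                    ),
                    "donor": r.donor,
                    "treatment": r.treatment,
                    "gene": r.gene,
                    "effect": r.effect,
                    "homology_match_count": r.homology_match_count,
                }
                for r in self.records
            ],
            indent=1,
        )


@dataclass(frozen=True)
class PlantedSite:
    """Realized genomic location of one planted edit."""

    edit: PlantedEdit
    cut_pos: int
    gene: str | None


@dataclass
class CohortBundle:
    """Everything one synthetic run produces, in memory."""

    config: CohortConfig
    reference: dict[str, str]
    gene_models: list[GeneModel]
    guides: dict[str, GuideRNA]
    germline_db: dict[VariantKey, int]
    samples: list[SampleRecord]
    truth: TruthTable
    sites: list[PlantedSite]
    chip_genes: frozenset[str] = DEFAULT_CHIP_GENES


# ---------------------------------------------------------------------------
# reference, genes, guides


def _random_cds(length: int, rng: np.random.Generator) -> str:
    """ATG + random non-stop codons + one stop codon."""
    n_codons = length // 3 - 2
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(_BASES, size=3))
        if c not in _STOPS and c != "ATG":
            codons.append(c)
    stop = str(rng.choice(["TAA", "TAG", "TGA"]))
    return "ATG" + "".join(codons) + stop


def simulate_reference(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[GeneModel], dict[str, GuideRNA], list[PlantedSite]]:
    """Build the synthetic reference bundle.

    Random background sequence; non-overlapping single-exon CDS gene
    models with valid start/stop; one embedded protospacer+PAM per
    guide (the on-target site); engineered off-target sites mutated to
    the requested spacer+PAM match count (the PAM's N position, which
    matches any base, is never one of the mutated positions).
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 0])
    n_genes = len(config.gene_names)
    slot = config.reference_length // (n_genes + 1)
    if slot < config.cds_length + 200:
        raise ValueError("reference too short for requested genes without overlap")
    seq = rng.choice(_BASES, size=config.reference_length)

    gene_models: list[GeneModel] = []
    gene_span: dict[str, tuple[int, int]] = {}
    for i, name in enumerate(config.gene_names):
        start = slot // 2 + i * slot  # 1-based
        end = start + config.cds_length - 1
        cds = _random_cds(config.cds_length, rng)
        strand = "+" if i % 2 == 0 else "-"
        genomic = cds if strand == "+" else reverse_complement(cds)
        seq[start - 1 : end] = list(genomic)
        gene_models.append(
            GeneModel(
                gene=name,
                chrom=config.chrom,
                strand=strand,
                cds_intervals=((start, end),),
            )
        )
        gene_span[name] = (start, end)

    # guides: random spacers, SpCas9 NGG PAM, embedded in intergenic gaps
    guides: dict[str, GuideRNA] = {}
    sites: list[PlantedSite] = []
    gaps = _intergenic_gaps(config, gene_span)
    gap_cursor = 0
    for gi, name in enumerate(config.guide_names):
        spacer = "".join(rng.choice(_BASES, size=20))
        site23 = spacer + str(rng.choice(_BASES)) + "GG"
        start, gap_cursor = _take_slot(gaps, gap_cursor, 23)
        seq[start - 1 : start + 22] = list(site23)
        guides[name] = GuideRNA(
            name=name,
            spacer=spacer,
            pam="NGG",
            target_chrom=config.chrom,
            cut_pos=cut_position(start, "+"),
            strand="+",
        )

    for edit in config.planted_edits:
        guide = guides[edit.guide]
        if edit.kind == "on_target":
            sites.append(PlantedSite(edit, guide.cut_pos, gene=None))
            continue
        if edit.gene is not None:
            g_start, g_end = gene_span[edit.gene]
            start = (g_start + g_end) // 2 - 11
        else:
            start, gap_cursor = _take_slot(gaps, gap_cursor, 23)
        _engineer_off_target(
            seq, start, guide, edit.homology_match_count, rng
        )
        sites.append(PlantedSite(edit, cut_position(start, "+"), gene=edit.gene))

    reference = {config.chrom: "".join(seq)}
    return reference, gene_models, guides, sites


def _intergenic_gaps(
    config: CohortConfig, gene_span: dict[str, tuple[int, int]]
) -> list[tuple[int, int]]:
    occupied = sorted(gene_span.values())
    gaps = []
    prev_end = 100
    for start, end in occupied:
        if start - 1 - prev_end > 200:
            gaps.append((prev_end + 50, start - 50))
        prev_end = end
    if config.reference_length - 100 - prev_end > 200:
        gaps.append((prev_end + 50, config.reference_length - 100))
    return gaps


def _take_slot(
    gaps: list[tuple[int, int]], cursor: int, width: int
) -> tuple[int, int]:
    for i in range(cursor, len(gaps)):
        lo, hi = gaps[i]
        if hi - lo + 1 >= width + 100:
            gaps[i] = (lo + width + 100, hi)
            return lo + 50, i
    raise ValueError("cannot place guide/off-target site without overlap")


def _engineer_off_target(
    seq: np.ndarray,
    start: int,
    guide: GuideRNA,
    match_count: int,
    rng: np.random.Generator,
    max_attempts: int = 100,
) -> None:
    """Embed a degenerate copy of spacer+PAM achieving an exact best
    match count at this placement (verified; re-randomized on ties)."""
    query = guide.query  # 23-mer with N at PAM position 20
    n_pos = [i for i, q in enumerate(query) if q == "N"]
    mutable = [i for i in range(23) if i not in n_pos]
    n_mutations = 23 - match_count
    if n_mutations > len(mutable):
        raise ValueError(
            f"match_count {match_count} unreachable: only {len(mutable)} "
            "non-N positions"
        )
    for _ in range(max_attempts):
        site = list(query)
        for i in n_pos:
            site[i] = str(rng.choice(_BASES))
        for i in rng.choice(mutable, size=n_mutations, replace=False):
            choices = [b for b in "ACGT" if b != query[i]]
            site[i] = str(rng.choice(choices))
        seq[start - 1 : start + 22] = site
        window_lo = max(0, start - 1 - 30)
        window = "".join(seq[window_lo : start + 22 + 30])
        best, _, _ = best_homology(window, guide.spacer, guide.pam)
        if best == match_count:
            return
    raise RuntimeError(
        f"could not engineer off-target site at match_count={match_count}"
    )


# ---------------------------------------------------------------------------
# germline, noise, samples


def _genomic_base(reference: Mapping[str, str], chrom: str, pos: int) -> str:
    return reference[chrom][pos - 1]


def simulate_germline(
    donor: str,
    config: CohortConfig,
    reference: Mapping[str, str],
    gene_models: Sequence[GeneModel],
    rng: np.random.Generator,
    used_positions: set[int],
) -> tuple[list[TruthRecord], dict[VariantKey, int]]:
    """Plant one donor's germline variants and their database rows.

    A configured fraction is synonymous by construction (third-codon-
    position substitutions that preserve the amino acid); the rest are
    random substitutions annotated against the gene models.  All
    variants get database occurrence counts > 10 except a small
    holdout with counts <= 10 that exercises the filter boundary.
    """
    chrom = config.chrom
    records: list[TruthRecord] = []
    db: dict[VariantKey, int] = {}
    n_syn = int(round(config.n_germline_per_donor * config.germline_synonymous_fraction))
    n_other = config.n_germline_per_donor - n_syn

    syn_sites = _synonymous_sites(config, reference, gene_models)
    if n_syn > len(syn_sites):
        raise ValueError("not enough synonymous sites for requested fraction")
    order = rng.permutation(len(syn_sites))
    planted: list[tuple[VariantKey, str, str | None]] = []
    taken = 0
    for idx in order:
        pos, ref_b, alt_b, gene = syn_sites[idx]
        if pos in used_positions:
            continue
        used_positions.add(pos)
        planted.append((VariantKey(chrom, pos, ref_b, alt_b), "synonymous", gene))
        taken += 1
        if taken == n_syn:
            break

    while n_other > 0:
        pos = int(rng.integers(100, config.reference_length - 100))
        if pos in used_positions:
            continue
        used_positions.add(pos)
        ref_b = _genomic_base(reference, chrom, pos)
        alt_b = str(rng.choice([b for b in "ACGT" if b != ref_b]))
        call = VariantCall(chrom, pos, ref_b, alt_b, 1, 2)
        effect = annotate_effect(call, gene_models, reference)
        gene = _containing_gene(gene_models, chrom, pos)
        planted.append((VariantKey(chrom, pos, ref_b, alt_b), effect, gene))
        n_other -= 1

    n_holdout = int(round(len(planted) * config.germline_db_holdout_fraction))
    holdout = set(rng.choice(len(planted), size=n_holdout, replace=False).tolist())
    for i, (key, effect, gene) in enumerate(planted):
        het = rng.random() < config.het_fraction
        records.append(
            TruthRecord(
                key=key,
                category="germline_het" if het else "germline_hom",
                true_vaf=0.5 if het else 1.0,
                vaf_by_timepoint=None,
                donor=donor,
                treatment=None,
                gene=gene,
                effect=effect,
                homology_match_count=None,
            )
        )
        if i in holdout:
            db[key] = int(rng.integers(1, 11))  # <= 10: retained by the filter
        else:
            db[key] = int(rng.integers(11, 5000))
    return records, db


def _synonymous_sites(
    config: CohortConfig,
    reference: Mapping[str, str],
    gene_models: Sequence[GeneModel],
) -> list[tuple[int, str, str, str]]:
    """All third-codon-position substitutions that preserve the amino acid."""
    from editscreen.effect_annotation import translate_cds

    sites = []
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for model in gene_models:
        cds = model.cds_sequence(reference)
        start, end = model.cds_intervals[0]
        for ci in range(len(cds) // 3):
            codon = cds[ci * 3 : ci * 3 + 3]
            aa = translate_cds(codon)
            for alt in "ACGT":
                if alt == codon[2]:
                    continue
                if translate_cds(codon[:2] + alt) != aa:
                    continue
                cds_idx = ci * 3 + 2
                if model.strand == "+":
                    pos, ref_b, alt_b = start + cds_idx, codon[2], alt
                else:
                    pos, ref_b, alt_b = end - cds_idx, comp[codon[2]], comp[alt]
                sites.append((pos, ref_b, alt_b, model.gene))
                break  # one synonymous alt per codon is enough
    return sites


def _containing_gene(
    gene_models: Sequence[GeneModel], chrom: str, pos: int
) -> str | None:
    for m in gene_models:
        if m.chrom == chrom and m.contains(pos):
            return m.gene
    return None


def _edit_variants(
    site: PlantedSite,
    reference: Mapping[str, str],
    config: CohortConfig,
    rng: np.random.Generator,
) -> list[tuple[VariantKey, float]]:
    """Realize an edit's indel spectrum as keyed variants with weights."""
    chrom = config.chrom
    seq = reference[chrom]
    out = []
    for net_len, weight in sorted(site.edit.indel_spectrum.items()):
        anchor_pos = site.cut_pos
        anchor = seq[anchor_pos - 1]
        if net_len < 0:
            ref_a = seq[anchor_pos - 1 : anchor_pos - net_len]
            alt_a = anchor
        else:
            ins = "".join(rng.choice(_BASES, size=net_len))
            ref_a = anchor
            alt_a = anchor + ins
        pos, ref_a, alt_a = normalize_variant(chrom, anchor_pos, ref_a, alt_a, reference)
        out.append((VariantKey(chrom, pos, ref_a, alt_a), weight))
    return out


def simulate_sample(
    donor: str,
    treatment: str,
    timepoint: int,
    replicate: int,
    config: CohortConfig,
    donor_truth: Sequence[TruthRecord],
    edit_truth: Sequence[TruthRecord],
    rng: np.random.Generator,
    reference: Mapping[str, str],
    gene_models: Sequence[GeneModel],
    noise_log: list[TruthRecord] | None = None,
) -> SampleRecord:
    """Draw one sample's observed variant calls.

    Per-variant depth ~ NegativeBinomial(target_mec, dispersion)
    floored at 1; alt reads ~ Binomial(depth, true VAF); variants with
    zero observed alt reads are not emitted.  Noise variants are drawn
    fresh per sample (Poisson count, uniform positions, VAF uniform in
    the configured range).  Edits appear only in the matching guide arm
    at timepoints > 0; Mock arms carry germline + chimerism + noise.
    """
    m, disp = config.target_mec, config.mec_dispersion
    p_nb = disp / (disp + m)

    def draw_depth() -> int:
        return max(1, int(rng.negative_binomial(disp, p_nb)))

    calls: list[VariantCall] = []
    seen: set[VariantKey] = set()

    def emit(key: VariantKey, true_vaf: float, gene: str | None, effect: str | None) -> None:
        if key in seen:
            return
        depth = draw_depth()
        alt_reads = int(rng.binomial(depth, true_vaf))
        if alt_reads == 0:
            return
        seen.add(key)
        calls.append(
            VariantCall(
                chrom=key.chrom,
                pos=key.pos,
                ref=key.ref,
                alt=key.alt,
                alt_reads=alt_reads,
                depth=depth,
                gene=gene,
                effect=effect,
            )
        )

    for rec in donor_truth:  # germline + chimerism, all arms
        emit(rec.key, rec.true_vaf, rec.gene, rec.effect)

    if treatment != MOCK and timepoint > 0:
        for rec in edit_truth:
            if rec.treatment != treatment:
                continue
            vaf = rec.vaf_by_timepoint.get(timepoint, 0.0)
            if vaf > 0:
                emit(rec.key, vaf, rec.gene, rec.effect)

    n_noise = int(rng.poisson(config.noise_rate))
    lo, hi = config.noise_vaf_range
    for _ in range(n_noise):
        pos = int(rng.integers(100, config.reference_length - 100))
        ref_b = _genomic_base(reference, config.chrom, pos)
        alt_b = str(rng.choice([b for b in "ACGT" if b != ref_b]))
        key = VariantKey(config.chrom, pos, ref_b, alt_b)
        if key in seen:
            continue
        vaf = float(rng.uniform(lo, hi))
        call = VariantCall(config.chrom, pos, ref_b, alt_b, 1, 2)
        effect = annotate_effect(call, gene_models, reference)
        gene = _containing_gene(gene_models, config.chrom, pos)
        emit(key, vaf, gene, effect)
        if noise_log is not None and key in seen:
            noise_log.append(
                TruthRecord(
                    key=key,
                    category="noise",
                    true_vaf=vaf,
                    vaf_by_timepoint=None,
                    donor=f"{donor}_{treatment}_d{timepoint}_r{replicate}",
                    treatment=treatment,
                    gene=gene,
                    effect=effect,
                    homology_match_count=None,
                )
            )

    mec = float(np.median(rng.negative_binomial(disp, p_nb, size=len(gene_models))))
    sample_id = f"{donor}_{treatment}_d{timepoint}_r{replicate}"
    return SampleRecord(
        sample_id=sample_id,
        donor=donor,
        treatment=treatment,
        timepoint_days=timepoint,
        replicate=replicate,
        variants=calls,
        median_exon_coverage=max(mec, 1.0),
    )


def generate_cohort(
    config: CohortConfig, out_dir: str | None = None
) -> CohortBundle:
    """Generate the full cohort; optionally write the file bundle.

    Design: n_donors x (Mock + guides) x timepoints x replicates, with
    day 0 sequenced for Mock only (a single replicate), matching the
    study layout.  Writes reference FASTA, gene GFF3, guide and sample
    sheets, germline DB, one VCF per sample, the truth table and the
    round-trippable config when ``out_dir`` is given.
    """
    reference, gene_models, guides, sites = simulate_reference(config)
    chrom = config.chrom
    used_positions: set[int] = set()
    for site in sites:
        used_positions.update(range(site.cut_pos - 30, site.cut_pos + 31))

    truth_records: list[TruthRecord] = []
    germline_db: dict[VariantKey, int] = {}
    donor_truth: dict[str, list[TruthRecord]] = {}
    donors = [f"D{i + 1}" for i in range(config.n_donors)]
    for di, donor in enumerate(donors):
        rng = np.random.default_rng([config.seed, 1, di])
        recs, db = simulate_germline(
            donor, config, reference, gene_models, rng, used_positions
        )
        lo, hi = config.chimerism_vaf_range
        for _ in range(config.chimerism_per_donor):
            while True:
                pos = int(rng.integers(100, config.reference_length - 100))
                if pos not in used_positions:
                    break
            used_positions.add(pos)
            ref_b = _genomic_base(reference, chrom, pos)
            alt_b = str(rng.choice([b for b in "ACGT" if b != ref_b]))
            key = VariantKey(chrom, pos, ref_b, alt_b)
            call = VariantCall(chrom, pos, ref_b, alt_b, 1, 2)
            recs.append(
                TruthRecord(
                    key=key,
                    category="chimerism",
                    true_vaf=float(rng.uniform(lo, hi)),
                    vaf_by_timepoint=None,
                    donor=donor,
                    treatment=None,
                    gene=_containing_gene(gene_models, chrom, pos),
                    effect=annotate_effect(call, gene_models, reference),
                    homology_match_count=None,
                )
            )
            # chimerism variants sit in the germline database too: the
            # study saw them filtered by the database despite their
            # intermediate VAF
            db[key] = int(rng.integers(11, 5000))
        donor_truth[donor] = recs
        truth_records.extend(recs)
        germline_db.update(db)

    edit_truth: list[TruthRecord] = []
    edit_rng = np.random.default_rng([config.seed, 2])
    for site in sites:
        for key, weight in _edit_variants(site, reference, config, edit_rng):
            call = VariantCall(chrom, key.pos, key.ref, key.alt, 1, 2)
            edit_truth.append(
                TruthRecord(
                    key=key,
                    category=f"{site.edit.kind}_edit",
                    true_vaf=None,
                    vaf_by_timepoint={
                        t: v * weight for t, v in site.edit.vaf_by_timepoint.items()
                    },
                    donor=None,
                    treatment=site.edit.guide,
                    gene=site.gene,
                    effect=annotate_effect(call, gene_models, reference),
                    homology_match_count=site.edit.homology_match_count,
                )
            )
    truth_records.extend(edit_truth)

    samples: list[SampleRecord] = []
    for di, donor in enumerate(donors):
        for ti, treatment in enumerate(config.treatments):
            for timepoint in config.timepoints_days:
                if timepoint == 0 and treatment != MOCK:
                    continue
                reps = 1 if timepoint == 0 else config.n_replicates
                for replicate in range(1, reps + 1):
                    rng = np.random.default_rng(
                        [config.seed, 3, di, ti, timepoint, replicate]
                    )
                    samples.append(
                        simulate_sample(
                            donor,
                            treatment,
                            timepoint,
                            replicate,
                            config,
                            donor_truth[donor],
                            edit_truth,
                            rng,
                            reference,
                            gene_models,
                            noise_log=truth_records,
                        )
                    )

    bundle = CohortBundle(
        config=config,
        reference=reference,
        gene_models=gene_models,
        guides=guides,
        germline_db=germline_db,
        samples=samples,
        truth=TruthTable(truth_records),
        sites=sites,
    )
    if out_dir is not None:
        write_cohort(bundle, out_dir)
    return bundle


def write_cohort(bundle: CohortBundle, out_dir: str) -> None:
    """Write the cohort bundle as plain-text files."""
    os.makedirs(out_dir, exist_ok=True)
    cfg = bundle.config
    with open(os.path.join(out_dir, "reference.fasta"), "w") as fh:
        for chrom, seq in bundle.reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    write_gene_models_gff3(bundle.gene_models, os.path.join(out_dir, "genes.gff3"))
    with open(os.path.join(out_dir, "guides.tsv"), "w") as fh:
        fh.write("name\tspacer\tpam\tchrom\tcut_pos\tstrand\n")
        for g in bundle.guides.values():
            fh.write(
                f"{g.name}\t{g.spacer}\t{g.pam}\t{g.target_chrom}\t{g.cut_pos}\t{g.strand}\n"
            )
    with open(os.path.join(out_dir, "germline_db.tsv"), "w") as fh:
        fh.write("chrom\tpos\tref\talt\toccurrence_count\n")
        for key in sorted(bundle.germline_db):
            fh.write(
                f"{key.chrom}\t{key.pos}\t{key.ref}\t{key.alt}\t{bundle.germline_db[key]}\n"
            )
    with open(os.path.join(out_dir, "chip_genes.txt"), "w") as fh:
        for gene in sorted(bundle.chip_genes):
            fh.write(gene + "\n")
    vcf_dir = os.path.join(out_dir, "vcf")
    os.makedirs(vcf_dir, exist_ok=True)
    with open(os.path.join(out_dir, "sample_sheet.tsv"), "w") as fh:
        fh.write(
            "sample_id\tdonor\ttreatment\ttimepoint_days\treplicate\t"
            "median_exon_coverage\tvcf_path\n"
        )
        for s in bundle.samples:
            vcf_path = os.path.join("vcf", f"{s.sample_id}.vcf")
            write_variants(s, os.path.join(out_dir, vcf_path), format="VCF")
            fh.write(
                f"{s.sample_id}\t{s.donor}\t{s.treatment}\t{s.timepoint_days}\t"
                f"{s.replicate}\t{s.median_exon_coverage}\t{vcf_path}\n"
            )
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        fh.write(bundle.truth.to_json())
    with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
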
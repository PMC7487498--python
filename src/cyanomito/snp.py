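"""SNP density and coding/non-coding placement of mitogenome variants.

Density is reported per kbp of genome (the convention that reproduces the
published per-genome figures); "coding" defaults to the union of CDS, tRNA
and rRNA footprints, so "non-coding" means intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .seqio import Genome, VariantRecord

DEFAULT_CODING_KINDS = ("CDS", "tRNA", "rRNA")


@dataclass
class SnpSummary:
    genome_id: str
    n_snps: int
    genome_kbp: float
    density: float  # SNPs per kbp, unrounded; format to 3 decimals on output
    n_coding: int
    n_noncoding: int


def _coding_footprint(genome: Genome, kinds: Sequence[str]) -> list[tuple[int, int]]:
    """Merged half-open intervals covered by features of the given kinds."""
    ivs: list[tuple[int, int]] = []
    L = len(genome)
    for f in genome.features:
        if f.kind not in kinds:
            continue
        if f.wrap:
            ivs.append((f.start, L))
            ivs.append((0, f.end))
        else:
            ivs.append((f.start, f.end))
    ivs.sort()
    merged: list[tuple[int, int]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def annotate_coding(variants: Iterable[VariantRecord], genome: Genome,
                    coding_kinds: Sequence[str] = DEFAULT_CODING_KINDS) -> list[VariantRecord]:
    """Set each variant's ``in_coding`` flag against the genome's features."""
    footprint = _coding_footprint(genome, coding_kinds)
    out = []
    for v in variants:
        if v.position >= len(genome):
            raise ValueError(
                f"variant at {v.position} beyond genome length {len(genome)}"
            )
        inside = any(a <= v.position < b for a, b in footprint)
        out.append(replace(v, in_coding=inside))
    return out


def snp_density(variants: Iterable[VariantRecord], genome: Genome,
                coding_kinds: Sequence[str] = DEFAULT_CODING_KINDS) -> SnpSummary:
    """Per-genome SNP count, density (SNPs/kbp) and coding placement."""
    annotated = annotate_coding(variants, genome, coding_kinds)
    n = len(annotated)
    n_coding = sum(v.in_coding for v in annotated)
    kbp = len(genome) / 1000.0
    return SnpSummary(
        genome_id=genome.id, n_snps=n, genome_kbp=kbp, density=n / kbp,
        n_coding=n_coding, n_noncoding=n - n_coding,
    )
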
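"""Sequence, annotation, alignment and variant I/O plus genetic-code translation.

All downstream analysis modules consume only the domain types defined here.
Coordinates are 0-based half-open everywhere inside the package; GenBank's
1-based inclusive convention is converted exactly once, in :func:`read_genbank`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable

log = logging.getLogger(__name__)

NUCLEOTIDES = set("ACGTN")
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
ALIGNMENT_ALPHABET = AMINO_ACIDS | {"-", "X"}

#: Genetic codes the package accepts: the standard code and the protozoan
#: mitochondrial code (table 4), the two codes relevant for cyanidiophycean
#: mitogenome annotation.
SUPPORTED_CODES = (1, 4)


class FormatError(ValueError):
    """Raised for malformed input files (bad syntax, alphabet, structure)."""


@dataclass
class GeneFeature:
    """An annotated locus on a genome.

    ``start``/``end`` are 0-based half-open.  A feature that spans the
    circular origin has ``wrap=True`` and ``start > end``; its footprint is
    ``[start, length) ∪ [0, end)``.
    """

    name: str
    start: int
    end: int
    strand: Literal["+", "-"]
    kind: Literal["CDS", "tRNA", "rRNA", "other"] = "other"
    wrap: bool = False

    def length(self, genome_length: int | None = None) -> int:
        if self.wrap:
            if genome_length is None:
                raise ValueError("wrap-around feature needs genome length")
            return (genome_length - self.start) + self.end
        return self.end - self.start


@dataclass
class Genome:
    """A nucleotide sequence (uppercase over A,C,G,T,N) with optional features."""

    id: str
    sequence: str
    topology: Literal["circular", "linear"] = "circular"
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        if self.sequence != self.sequence.upper():
            raise ValueError(f"genome {self.id!r}: sequence must be uppercase")
        bad = set(self.sequence) - NUCLEOTIDES
        if bad:
            raise ValueError(f"genome {self.id!r}: invalid characters {sorted(bad)}")
        L = len(self.sequence)
        for f in self.features:
            if not (0 <= f.start < L and 0 < f.end <= L):
                raise ValueError(
                    f"feature {f.name!r}: coordinates ({f.start},{f.end}) "
                    f"outside genome of length {L}"
                )
            if not f.wrap and f.start >= f.end:
                raise ValueError(f"feature {f.name!r}: start >= end without wrap flag")

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_sequence(self, feat: GeneFeature) -> str:
        """Extract a feature's nucleotide sequence, strand-aware.

        Wrap-around features are materialized by concatenating the tail and
        head of the circular sequence.
        """
        if feat.wrap:
            nt = self.sequence[feat.start :] + self.sequence[: feat.end]
        else:
            nt = self.sequence[feat.start : feat.end]
        if feat.strand == "-":
            nt = reverse_complement(nt)
        return nt


@dataclass
class AlignmentMatrix:
    """Residues x taxa with group labels (G_type / C_type / outgroup)."""

    taxa: list[str]
    rows: list[str]
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise FormatError(f"duplicate taxon labels: {dupes}")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise FormatError(f"ragged alignment rows, lengths {sorted(lengths)}")
        for taxon, row in zip(self.taxa, self.rows):
            bad = set(row) - ALIGNMENT_ALPHABET
            if bad:
                raise FormatError(f"taxon {taxon!r}: invalid residues {sorted(bad)}")
        missing = [t for t in self.taxa if t not in self.group_of]
        if missing:
            raise ValueError(f"taxa absent from group map: {missing}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, i: int) -> str:
        return "".join(row[i] for row in self.rows)

    def groups(self) -> dict[str, list[str]]:
        """Rows partitioned by group label, preserving taxon order."""
        out: dict[str, list[str]] = {}
        for taxon, row in zip(self.taxa, self.rows):
            out.setdefault(self.group_of[taxon], []).append(row)
        return out


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide variant, 0-based position."""

    genome_id: str
    position: int
    ref: str
    alt: str
    in_coding: bool | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref == alt")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("VariantRecord is SNP-only (ref/alt length 1)")


@dataclass
class TranslationResult:
    """Protein product plus positions (codon index) of internal stops.

    Internal stops under the chosen code are rendered as '*' in ``protein``
    and reported in ``internal_stops``; a trailing stop is removed silently.
    """

    protein: str
    internal_stops: list[int] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.internal_stops


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize_nt(raw: str, record_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    for i, ch in enumerate(seq):
        if ch not in NUCLEOTIDES:
            raise FormatError(
                f"record {record_id!r}: non-IUPAC character {ch!r} at position {i}"
            )
    return seq


def read_fasta(path: str | Path, topology: str = "circular") -> list[Genome]:
    """Read a (multi-)FASTA of nucleotide sequences into :class:`Genome` objects.

    Lowercase is normalized to uppercase and U to T.  Characters outside
    {A,C,G,T,N,U} raise :class:`FormatError` naming the offending position.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return [
        Genome(id=r.id, sequence=_normalize_nt(str(r.seq), r.id), topology=topology)
        for r in records
    ]


def write_fasta(genomes: Iterable[Genome], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i : i + width] + "\n")


_FEATURE_KINDS = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


def read_genbank(path: str | Path) -> Genome:
    """Read a GenBank flat file: sequence, topology and gene features.

    GenBank 1-based inclusive locations become 0-based half-open here.  A
    ``join`` spanning the circular origin yields one feature with ``wrap=True``.
    """
    path = Path(path)
    try:
        record = next(SeqIO.parse(str(path), "genbank"))
        if len(record.seq) == 0:
            raise FormatError(f"{path}: missing ORIGIN sequence block")
        str(record.seq)  # raises on records with no sequence content
    except StopIteration:
        raise FormatError(f"{path}: no GenBank record") from None
    except FormatError:
        raise
    except ValueError as exc:  # malformed flat file or undefined sequence
        raise FormatError(f"{path}: {exc}") from exc
    topology = record.annotations.get("topology", "linear")
    if topology not in ("circular", "linear"):
        topology = "linear"

    L = len(record.seq)
    features: list[GeneFeature] = []
    for f in record.features:
        kind = _FEATURE_KINDS.get(f.type)
        if f.type == "source":
            continue
        if kind is None:
            if f.type == "gene":
                continue  # gene features duplicate CDS/tRNA/rRNA footprints
            kind = "other"
        name = (
            f.qualifiers.get("gene", f.qualifiers.get("locus_tag", [f.type]))[0]
        )
        strand = "-" if f.location.strand == -1 else "+"
        parts = sorted(f.location.parts, key=lambda p: int(p.start))
        start, end = int(f.location.start), int(f.location.end)
        wrap = False
        if len(parts) > 1 and int(parts[0].start) == 0 and int(parts[-1].end) == L:
            # join(a..L, 1..b): feature crosses the circular origin
            wrap = True
            start, end = int(parts[-1].start), int(parts[0].end)
        features.append(
            GeneFeature(name=name, start=start, end=end, strand=strand,
                        kind=kind, wrap=wrap)
        )
    sequence = _normalize_nt(str(record.seq), record.id)
    return Genome(id=record.id, sequence=sequence, topology=topology,
                  features=features)


def _codon_table(code: int) -> CodonTable.CodonTable:
    if code not in SUPPORTED_CODES:
        raise ValueError(f"genetic code {code} not supported; use one of {SUPPORTED_CODES}")
    return CodonTable.unambiguous_dna_by_id[code]


def translate_cds(nt: str, code: int = 1) -> TranslationResult:
    """Translate a CDS under NCBI genetic code 1 or 4.

    The trailing stop codon (if any) is removed; internal stops are retained
    as '*' and their codon indices reported in the result, never silently
    dropped.  Length must be a multiple of 3.
    """
    nt = nt.upper().replace("U", "T")
    if len(nt) % 3 != 0:
        raise ValueError(f"CDS length {len(nt)} not divisible by 3")
    table = _codon_table(code)
    stops = set(table.stop_codons)
    aa: list[str] = []
    for i in range(0, len(nt), 3):
        codon = nt[i : i + 3]
        if codon in stops:
            aa.append("*")
        elif codon in table.forward_table:
            aa.append(table.forward_table[codon])
        else:
            aa.append("X")  # ambiguous (contains N)
    if aa and aa[-1] == "*":
        aa.pop()
    internal = [i for i, a in enumerate(aa) if a == "*"]
    return TranslationResult(protein="".join(aa), internal_stops=internal)


def compare_genetic_codes(nt: str) -> dict:
    """Translate a CDS under codes 1 and 4 and flag divergent products.

    Used to decide which code an annotation should use: the protozoan
    mitochondrial code (4) reads TGA as Trp, which can extend or alter open
    reading frames relative to the standard code.
    """
    r1, r4 = translate_cds(nt, 1), translate_cds(nt, 4)
    return {
        "code1": r1,
        "code4": r4,
        "divergent": r1.protein != r4.protein or r1.internal_stops != r4.internal_stops,
    }


def read_alignment(path: str | Path, group_map: Mapping[str, str]) -> AlignmentMatrix:
    """Read an aligned FASTA of proteins and attach group labels.

    Every taxon must appear in ``group_map``; ragged rows and duplicate
    labels are rejected.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    taxa = [r.id for r in records]
    rows = [str(r.seq).upper() for r in records]
    missing = [t for t in taxa if t not in group_map]
    if missing:
        raise ValueError(f"{path}: taxa absent from group map: {missing}")
    return AlignmentMatrix(taxa=taxa, rows=rows,
                           group_of={t: group_map[t] for t in taxa})


def read_group_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV taxon<TAB>group -> dict."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
        out[parts[0]] = parts[1]
    return out


def read_vcf(path: str | Path, genome_id: str | None = None) -> list[VariantRecord]:
    """Read SNPs from a VCF 4.x file.

    Indels and other non-SNP records are skipped with a logged count.
    Multiallelic SNP sites expand to one record per alternate allele.
    ``in_coding`` is left unset; the snp module computes it against features.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib parse failure
        raise FormatError(f"{path}: not a readable VCF ({exc})") from exc
    records: list[VariantRecord] = []
    n_skipped = 0
    for var in vcf:
        gid = genome_id or var.CHROM
        for alt in var.ALT:
            if len(var.REF) == 1 and len(alt) == 1 and alt in "ACGT":
                records.append(
                    VariantRecord(genome_id=gid, position=var.POS - 1,
                                  ref=var.REF, alt=alt)
                )
            else:
                n_skipped += 1
    if n_skipped:
        log.info("read_vcf(%s): skipped %d non-SNP allele(s)", path, n_skipped)
    return records
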
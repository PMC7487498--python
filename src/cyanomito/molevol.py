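"""Site-rate estimation (TIGER) and pairwise Ka/Ks (Nei–Gojobori 1986).

TIGER (Tree-Independent Generation of Evolutionary Rates) scores each
alignment site by its mean partition agreement with every other site: sites
whose character-state partition of the taxa is compatible with most other
sites score near 1 (low variability), conflicting sites score low.  No tree
is required, which suits fast-evolving mitogenomes where topology is itself
uncertain.

Ka/Ks uses the NG86 counting method with Jukes–Cantor correction; the
estimator name is recorded in the result so downstream tables are explicit
about the model.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .seqio import AlignmentMatrix
from Bio.Data import CodonTable

UNKNOWN_STATES = set("-X?N")


@dataclass
class SiteRateVector:
    """Per-column TIGER rates in [0,1] (higher = more agreement = less
    variable) and their 1-based equal-width bin ranks."""

    rates: np.ndarray
    bins: np.ndarray | None = None


@dataclass
class KaKsResult:
    ka: float | None  # None when the JC correction is undefined (p >= 3/4)
    ks: float | None
    ratio: float | None  # None when Ks is 0 or undefined
    na: float
    ns: float
    n_sites: float
    s_sites: float
    method: str = "NG86"


def _site_partition(column: str) -> list[frozenset]:
    """Partition of taxon indices by character state; all unknown/gap states
    pool into a single set."""
    groups: dict[str, set[int]] = {}
    unknown: set[int] = set()
    for idx, ch in enumerate(column):
        if ch in UNKNOWN_STATES:
            unknown.add(idx)
        else:
            groups.setdefault(ch, set()).add(idx)
    parts = [frozenset(v) for v in groups.values()]
    if unknown:
        parts.append(frozenset(unknown))
    return parts


def partition_agreement(p_i: list[frozenset], p_j: list[frozenset]) -> float:
    """pa(i, j): fraction of sets in partition j that are subsets of some set
    in partition i (Cummins–McInerney agreement score)."""
    hits = sum(1 for s in p_j if any(s <= t for t in p_i))
    return hits / len(p_j)


def tiger_rates(aln: AlignmentMatrix) -> SiteRateVector:
    """TIGER rate per site: mean agreement of site i with all other sites.

    rate(i) = mean over j != i of pa(i, j).  Requires >= 3 taxa and >= 2
    columns; works on nucleotide or residue alignments alike since only the
    induced taxon partitions matter.
    """
    if len(aln.taxa) < 3:
        raise ValueError("TIGER needs at least 3 taxa")
    n_cols = aln.n_columns
    if n_cols < 2:
        raise ValueError("TIGER needs at least 2 columns")
    parts = [_site_partition(aln.column(i)) for i in range(n_cols)]
    rates = np.empty(n_cols)
    for i in range(n_cols):
        total = sum(partition_agreement(parts[i], parts[j])
                    for j in range(n_cols) if j != i)
        rates[i] = total / (n_cols - 1)
    return SiteRateVector(rates=rates)


def tiger_bins(rates: np.ndarray, n_bins: int = 100) -> np.ndarray:
    """Equal-width binning of [min, max] into ranks 1..n_bins.

    bin(x) = 1 + floor(n_bins * (x - min) / (max - min)), with the maximum
    clamped into bin n_bins (half-open bins, closed at the top).  Constant
    rates all land in bin 1.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.size == 0:
        raise ValueError("empty rate vector")
    lo, hi = rates.min(), rates.max()
    if hi == lo:
        return np.ones(rates.size, dtype=int)
    bins = 1 + np.floor(n_bins * (rates - lo) / (hi - lo)).astype(int)
    return np.minimum(bins, n_bins)


# ---------------------------------------------------------------------------
# NG86 Ka/Ks

_CODE1 = CodonTable.unambiguous_dna_by_id[1]
_STOPS = frozenset(_CODE1.stop_codons)
_BASES = "ACGT"


def _aa(codon: str) -> str:
    return _CODE1.forward_table[codon]


def _syn_fraction(codon: str, pos: int) -> float:
    """Fraction of the three possible changes at ``pos`` that are synonymous;
    mutations to stop codons count as nonsynonymous (standard NG86)."""
    syn = 0
    for b in _BASES:
        if b == codon[pos]:
            continue
        mut = codon[:pos] + b + codon[pos + 1 :]
        if mut not in _STOPS and _aa(mut) == _aa(codon):
            syn += 1
    return syn / 3.0


def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon; sums to 3."""
    if codon in _STOPS:
        raise ValueError(f"stop codon {codon}")
    s = sum(_syn_fraction(codon, p) for p in range(3))
    return s, 3.0 - s


def _path_counts(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous / nonsynonymous difference counts between two codons,
    averaging over all substitution orderings; paths through stops excluded
    (if all paths hit a stop, all are kept — degenerate fallback)."""
    diff_pos = [p for p in range(3) if c1[p] != c2[p]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0
        ok = True
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if nxt in _STOPS:
                ok = False
                break
            if _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:  # every path passes a stop; fall back to unfiltered paths
        for order in itertools.permutations(diff_pos):
            cur = c1
            sd = nd = 0
            for p in order:
                nxt = cur[:p] + c2[p] + cur[p + 1 :]
                if nxt in _STOPS or _aa(nxt) != _aa(cur):
                    nd += 1
                else:
                    sd += 1
                cur = nxt
            paths.append((sd, nd))
    s = sum(p[0] for p in paths) / len(paths)
    n = sum(p[1] for p in paths) / len(paths)
    return s, n


def _jc_correct(p: float) -> float | None:
    """Jukes–Cantor distance d = -(3/4) ln(1 - 4p/3); None when p >= 3/4."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0) + 0.0  # +0.0 avoids -0.0


def _codons(seq: str) -> list[str]:
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError("codon sequence length not divisible by 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for i, c in enumerate(codons):
        if c in _STOPS:
            raise ValueError(f"internal stop codon at codon {i}")
        if set(c) - set(_BASES):
            raise ValueError(f"ambiguous codon {c!r} at codon {i}")
    return codons


def ng86_ka_ks(seq1: str, seq2: str) -> KaKsResult:
    """Pairwise Ka and Ks by Nei–Gojobori (1986) counting under code 1.

    Site counts are averaged over the two sequences; multi-substitution
    codons average synonymous/nonsynonymous difference counts over equally
    weighted substitution paths (stop-passing paths excluded); pN and pS get
    the Jukes–Cantor correction.  Symmetric in its arguments.
    """
    cod1, cod2 = _codons(seq1), _codons(seq2)
    if len(cod1) != len(cod2):
        raise ValueError("codon sequences differ in length")
    s_sites = n_sites = 0.0
    ns = na = 0.0
    for a, b in zip(cod1, cod2):
        sa, _ = codon_sites(a)
        sb, _ = codon_sites(b)
        s_sites += (sa + sb) / 2.0
        n_sites += 3.0 - (sa + sb) / 2.0
        sd, nd = _path_counts(a, b)
        ns += sd
        na += nd
    ps = ns / s_sites if s_sites else 0.0
    pn = na / n_sites if n_sites else 0.0
    ks = _jc_correct(ps)
    ka = _jc_correct(pn)
    ratio = None
    if ka is not None and ks is not None and ks > 0:
        ratio = ka / ks
    return KaKsResult(ka=ka, ks=ks, ratio=ratio, na=na, ns=ns,
                      n_sites=n_sites, s_sites=s_sites)


def back_translate_alignment(protein_row: str, cds: str) -> str:
    """Map a gapped protein row back onto its CDS: each residue becomes its
    codon, each gap becomes '---'.  Helper for building codon alignments from
    protein alignments plus unaligned CDSs (trailing stop codon allowed)."""
    ungapped = protein_row.replace("-", "")
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    n_codons = len(cds) // 3
    if n_codons == len(ungapped) + 1 and cds[-3:] in _STOPS:
        cds = cds[:-3]
        n_codons -= 1
    if n_codons != len(ungapped):
        raise ValueError(
            f"CDS has {n_codons} codons but protein row has {len(ungapped)} residues"
        )
    out, k = [], 0
    for ch in protein_row:
        if ch == "-":
            out.append("---")
        else:
            out.append(cds[3 * k : 3 * k + 3])
            k += 1
    return "".join(out)
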
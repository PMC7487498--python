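"""Conserved-site extraction and protein physicochemical properties.

"Conserved sites" follows the comparative-mitogenomics usage: alignment
columns with no gap (and no 'X') in any taxon — sites present in every
species — not invariant columns.  Group contrasts (G-type vs C-type vs
outgroup) are computed on those columns so every taxon contributes the same
homologous residue set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import AlignmentMatrix
from .tables import DIWV, KD_HYDROPATHY

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ClassScheme:
    """Residue class membership used for composition rollups.

    Defaults: positive = {R, K, H}, negative = {D, E}; hydrophobic = residues
    with positive Kyte–Doolittle hydropathy, hydrophilic the rest.  Both
    partitions are configurable.
    """

    positive: frozenset = frozenset("RKH")
    negative: frozenset = frozenset("DE")
    hydrophobic: frozenset = frozenset(
        aa for aa, v in KD_HYDROPATHY.items() if v > 0
    )

    @property
    def neutral(self) -> frozenset:
        return frozenset(AA20) - self.positive - self.negative

    @property
    def hydrophilic(self) -> frozenset:
        return frozenset(AA20) - self.hydrophobic


DEFAULT_SCHEME = ClassScheme()


@dataclass
class ConservedSites:
    """Gap-free alignment columns (0-based, strictly increasing)."""

    column_indices: list[int]
    n_total: int

    @property
    def n_conserved(self) -> int:
        return len(self.column_indices)


@dataclass
class ProteinPropertyRecord:
    taxon: str
    gene: str
    length: int
    composition: dict[str, float]  # per-AA relative frequency, %
    class_pct: dict[str, float]
    gravy: float
    aliphatic_index: float
    instability_index: float | None  # None when length < 2


def conserved_columns(aln: AlignmentMatrix) -> ConservedSites:
    """Columns containing no gap and no 'X' in any row."""
    if not aln.rows:
        raise ValueError("empty alignment")
    arr = np.array([list(r) for r in aln.rows])
    ok = ~np.any((arr == "-") | (arr == "X"), axis=0)
    return ConservedSites(column_indices=np.flatnonzero(ok).tolist(),
                          n_total=aln.n_columns)


def restrict_to_columns(row: str, sites: ConservedSites) -> str:
    return "".join(row[i] for i in sites.column_indices)


def _check_protein(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set(AA20)
    if bad:
        raise ValueError(
            f"non-standard residues {sorted(bad)}; restrict to conserved "
            "(gap-free, X-free) columns first"
        )
    return seq


def aa_class_composition(seq: str, scheme: ClassScheme = DEFAULT_SCHEME) -> dict:
    """Per-residue relative frequencies (%) and class rollups.

    Returns ``{"composition": {aa: %}, "class_pct": {...}}`` where class_pct
    holds positive/negative/neutral (charge partition) and
    hydrophilic/hydrophobic (hydropathy-sign partition); each partition sums
    to 100.
    """
    seq = _check_protein(seq)
    if not seq:
        raise ValueError("empty sequence")
    L = len(seq)
    comp = {aa: 100.0 * seq.count(aa) / L for aa in AA20}
    pct = lambda members: sum(comp[aa] for aa in members)
    class_pct = {
        "positive": pct(scheme.positive),
        "negative": pct(scheme.negative),
        "neutral": pct(scheme.neutral),
        "hydrophilic": pct(scheme.hydrophilic),
        "hydrophobic": pct(scheme.hydrophobic),
    }
    return {"composition": comp, "class_pct": class_pct}


def gravy(seq: str) -> float:
    """Grand average of hydropathy: mean Kyte–Doolittle value per residue."""
    seq = _check_protein(seq)
    if not seq:
        raise ValueError("empty sequence")
    return sum(KD_HYDROPATHY[aa] for aa in seq) / len(seq)


def aliphatic_index(seq: str) -> float:
    """Relative volume of aliphatic side chains:
    AI = X(Ala) + 2.9 X(Val) + 3.9 (X(Ile) + X(Leu)), X in mole percent."""
    seq = _check_protein(seq)
    if not seq:
        raise ValueError("empty sequence")
    L = len(seq)
    x = lambda aa: 100.0 * seq.count(aa) / L
    return x("A") + 2.9 * x("V") + 3.9 * (x("I") + x("L"))


def instability_index(seq: str) -> float:
    """Guruprasad instability index: (10/L) * sum of DIWV over adjacent pairs.

    Values above 40 predict an unstable protein in vivo.  Order-sensitive by
    construction (dipeptides), unlike the other indices here.
    """
    seq = _check_protein(seq)
    if len(seq) < 2:
        raise ValueError("instability index needs length >= 2")
    total = sum(DIWV[a][b] for a, b in zip(seq[:-1], seq[1:]))
    return 10.0 / len(seq) * total


def property_record(taxon: str, gene: str, seq: str,
                    scheme: ClassScheme = DEFAULT_SCHEME) -> ProteinPropertyRecord:
    comp = aa_class_composition(seq, scheme)
    return ProteinPropertyRecord(
        taxon=taxon, gene=gene, length=len(seq),
        composition=comp["composition"], class_pct=comp["class_pct"],
        gravy=gravy(seq), aliphatic_index=aliphatic_index(seq),
        instability_index=instability_index(seq) if len(seq) >= 2 else None,
    )


#: The conserved mitochondrial gene set encoded in all 13 compared taxa.
CONSERVED_GENES_16 = (
    "sdhC", "atp4", "atp6", "atp8", "atp9", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
)


def per_gene_property_table(
    alignments: dict[str, AlignmentMatrix],
    gene_set: tuple[str, ...] = CONSERVED_GENES_16,
    scheme: ClassScheme = DEFAULT_SCHEME,
    conserved_only: bool = True,
) -> pd.DataFrame:
    """One property record per taxon x gene, as a tidy DataFrame.

    ``alignments`` maps gene name -> per-gene protein alignment.  With
    ``conserved_only`` each taxon's sequence is restricted to the gap-free
    columns of that gene's alignment (the group-comparison convention);
    without it, full ungapped sequences are used (for e.g. length contrasts).
    A gene absent for a taxon is recorded as absent, never imputed.
    """
    rows = []
    for gene in gene_set:
        if gene not in alignments:
            continue
        aln = alignments[gene]
        sites = conserved_columns(aln) if conserved_only else None
        for taxon, row in zip(aln.taxa, aln.rows):
            seq = (restrict_to_columns(row, sites) if conserved_only
                   else row.replace("-", "").replace("X", ""))
            if not seq:
                continue
            rec = property_record(taxon, gene, seq, scheme)
            rows.append({
                "taxon": taxon, "gene": gene, "group": aln.group_of[taxon],
                "length": rec.length, "gravy": rec.gravy,
                "aliphatic_index": rec.aliphatic_index,
                "instability_index": rec.instability_index,
                **{f"pct_{k}": v for k, v in rec.class_pct.items()},
            })
    return pd.DataFrame(rows)


def group_summary(table: pd.DataFrame, value_cols: list[str] | None = None) -> pd.DataFrame:
    """Per-group means and standard errors over a property table."""
    if value_cols is None:
        value_cols = [c for c in table.columns
                      if c not in ("taxon", "gene", "group")]
    g = table.groupby("group")[value_cols]
    mean = g.mean().add_suffix("_mean")
    sem = g.sem(ddof=1).add_suffix("_se")
    return pd.concat([mean, sem], axis=1).sort_index(axis=1)


def concatenated_group_composition(
    aln: AlignmentMatrix, scheme: ClassScheme = DEFAULT_SCHEME
) -> pd.DataFrame:
    """Per-taxon composition over the conserved columns of one (possibly
    concatenated) alignment — the per-taxon-concatenation convention."""
    sites = conserved_columns(aln)
    rows = []
    for taxon, row in zip(aln.taxa, aln.rows):
        seq = restrict_to_columns(row, sites)
        comp = aa_class_composition(seq, scheme)
        rows.append({"taxon": taxon, "group": aln.group_of[taxon],
                     **{f"pct_{k}": v for k, v in comp["class_pct"].items()},
                     **comp["composition"]})
    return pd.DataFrame(rows)
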
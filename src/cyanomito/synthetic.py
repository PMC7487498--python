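"""Synthetic data with known truth for every pipeline input class.

The mitogenome simulator operationalizes the two replication cartoons the
skew classifier must distinguish: *unidirectional* replication makes the
whole analyzed strand leading (guanine-rich everywhere, so cumulative
GC-skew climbs around the entire circle), while *bidirectional* replication
from an origin to an antipodal terminus makes one arc leading and the other
lagging (V/Λ-shaped cumulative curve).  The draw model is site-independent:
no phylogeny, no rate heterogeneity, no fork mechanics — enough to exercise
every statistic with controllable effect sizes, not a mutational model of
real organelles.

All generators are bit-reproducible under a fixed seed; one integer seed
expands to independent substreams per operation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .seqio import AlignmentMatrix, GeneFeature, Genome
from .protprops import AA20
from .molevol import _BASES, _STOPS, _aa, _syn_fraction

#: Default base composition, G-type-like: GC content 0.43 split evenly, the
#: tilt parameters then redistribute mass within the G/C and A/T pairs.
DEFAULT_COMPOSITION = (0.285, 0.215, 0.215, 0.285)  # A, C, G, T


@dataclass
class SimulationTruth:
    mode: Literal["unidirectional", "bidirectional", "neutral"]
    asymmetry: float
    base_composition: tuple[float, float, float, float]
    seed: int
    origin_pos: int | None = None
    terminus_pos: int | None = None
    at_fraction: float = 0.4


def _rng_for(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), stream])


def _tilted(comp: Sequence[float], alpha: float, at_fraction: float) -> np.ndarray:
    """Tilt a base composition toward G over C (and A over T, scaled).

    The G+C mass m is preserved and split (1+alpha)/2 : (1-alpha)/2, so the
    expected GC-skew of an i.i.d. draw is exactly alpha; likewise A/T with
    alpha*at_fraction, giving expected AT-skew alpha*at_fraction.
    """
    pa, pc, pg, pt = comp
    gc, at = pc + pg, pa + pt
    b = alpha * at_fraction
    return np.array([
        at * (1 + b) / 2,   # A
        gc * (1 - alpha) / 2,  # C
        gc * (1 + alpha) / 2,  # G
        at * (1 - b) / 2,   # T
    ])


def simulate_mitogenome(
    length: int = 30000,
    mode: Literal["unidirectional", "bidirectional", "neutral"] = "unidirectional",
    alpha: float = 0.7,
    base_composition: Sequence[float] = DEFAULT_COMPOSITION,
    seed: int = 0,
    origin_pos: int | None = None,
    at_fraction: float = 0.4,
) -> tuple[Genome, SimulationTruth]:
    """Simulate a circular mitogenome with a chosen replication signature.

    unidirectional: every position is leading-strand on the emitted strand —
    i.i.d. draws from the alpha-tilted composition.  bidirectional: the arc
    clockwise from origin to terminus (antipodal) is tilted +alpha, the
    complementary arc -alpha.  neutral: i.i.d. from the untilted composition.
    Defaults emulate the strongly skewed reduced mitogenomes (GC-skew ~0.7
    with AT-skew ~0.28 at the default ``at_fraction``).
    """
    comp = tuple(float(x) for x in base_composition)
    if abs(sum(comp) - 1.0) > 1e-9:
        raise ValueError(f"base composition sums to {sum(comp)}, not 1")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if length < 5000:
        raise ValueError("length must be >= 5000")
    rng = _rng_for(seed, 0)
    bases = np.array(list("ACGT"))
    if mode == "neutral":
        seq = rng.choice(bases, size=length, p=np.array(comp))
        truth = SimulationTruth(mode=mode, asymmetry=0.0, base_composition=comp,
                                seed=seed, at_fraction=at_fraction)
    elif mode == "unidirectional":
        p = _tilted(comp, alpha, at_fraction)
        seq = rng.choice(bases, size=length, p=p)
        truth = SimulationTruth(mode=mode, asymmetry=alpha, base_composition=comp,
                                seed=seed, at_fraction=at_fraction)
    elif mode == "bidirectional":
        if origin_pos is None:
            origin_pos = int(rng.integers(0, length))
        terminus = (origin_pos + length // 2) % length
        p_lead = _tilted(comp, alpha, at_fraction)
        p_lag = _tilted(comp, -alpha, at_fraction)
        seq = np.empty(length, dtype="<U1")
        idx = (np.arange(length) - origin_pos) % length
        leading = idx < length // 2
        seq[leading] = rng.choice(bases, size=int(leading.sum()), p=p_lead)
        seq[~leading] = rng.choice(bases, size=int((~leading).sum()), p=p_lag)
        truth = SimulationTruth(mode=mode, asymmetry=alpha, base_composition=comp,
                                seed=seed, origin_pos=origin_pos,
                                terminus_pos=terminus, at_fraction=at_fraction)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    genome = Genome(id=f"sim_{mode}_{seed}", sequence="".join(seq),
                    topology="circular")
    return genome, truth


def annotate_toy_genes(genome: Genome, n_genes: int = 10,
                       coding_fraction: float = 0.7, seed: int = 0) -> Genome:
    """Add evenly spaced toy CDS features covering ``coding_fraction`` of the
    genome, so variant placement has coding/intergenic compartments."""
    L = len(genome)
    pitch = L // n_genes
    glen = int(pitch * coding_fraction)
    rng = _rng_for(seed, 1)
    features = [
        GeneFeature(name=f"orf{i+1}", start=i * pitch, end=i * pitch + glen,
                    strand="+" if rng.random() < 0.5 else "-", kind="CDS")
        for i in range(n_genes)
    ]
    return Genome(id=genome.id, sequence=genome.sequence,
                  topology=genome.topology, features=features)


# ---------------------------------------------------------------------------
# grouped protein alignments

#: Baseline residue frequencies for simulated proteins: uniform over the 20
#: amino acids.  Real proteomes are non-uniform, but the group contrast, not
#: the marginal composition, is the quantity under test.
BASELINE_AA_FREQ = {aa: 0.05 for aa in AA20}

POSITIVE_SET = frozenset("RKH")


def simulate_protein_groups(
    n_per_group: dict[str, int] | None = None,
    length: int = 3845,
    class_shift: float = 0.0,
    seed: int = 0,
    shifted_group: str = "G_type",
) -> tuple[AlignmentMatrix, dict]:
    """Gap-free grouped protein alignment with a positive-charge class shift.

    ``class_shift`` moves the shifted group's total R+K+H frequency up by
    that many percentage points (split evenly within the class), compensated
    proportionally across the other residues.  Defaults mirror the study
    geometry: 13 taxa in three groups over 3845 gap-free columns.
    """
    if n_per_group is None:
        n_per_group = {"C_type": 5, "G_type": 4, "outgroup": 4}
    base = np.array([BASELINE_AA_FREQ[aa] for aa in AA20])
    shift = class_shift / 100.0
    pos_idx = np.array([aa in POSITIVE_SET for aa in AA20])
    shifted = base.copy()
    add = shift / pos_idx.sum()
    shifted[pos_idx] += add
    rest_mass = base[~pos_idx].sum()
    if shift > rest_mass:
        raise ValueError("class shift infeasible: exceeds available mass")
    shifted[~pos_idx] *= (rest_mass - shift) / rest_mass
    if (shifted < 0).any():
        raise ValueError("class shift makes a frequency negative")

    rng = _rng_for(seed, 2)
    letters = np.array(list(AA20))
    taxa, rows, group_of = [], [], {}
    for group, n in sorted(n_per_group.items()):
        p = shifted if group == shifted_group else base
        for i in range(n):
            taxon = f"{group}_{i+1}"
            taxa.append(taxon)
            rows.append("".join(rng.choice(letters, size=length, p=p)))
            group_of[taxon] = group
    truth = {
        "shifted_group": shifted_group,
        "class_shift": class_shift,
        "target_positive_pct": 100.0 * float(shifted[pos_idx].sum()),
        "baseline_positive_pct": 100.0 * float(base[pos_idx].sum()),
        "seed": seed,
    }
    return AlignmentMatrix(taxa=taxa, rows=rows, group_of=group_of), truth


# ---------------------------------------------------------------------------
# codon pairs with specified divergence

def _random_cds(n_codons: int, rng: np.random.Generator) -> list[str]:
    sense = [a + b + c for a in _BASES for b in _BASES for c in _BASES
             if a + b + c not in _STOPS]
    return list(rng.choice(sense, size=n_codons))


def simulate_codon_pair(
    n_codons: int = 500,
    target_pn: float = 0.05,
    target_ps: float = 0.05,
    seed: int = 0,
) -> tuple[str, str, dict]:
    """A codon-sequence pair whose expected NG86 difference proportions match
    the targets.

    Each position of the ancestral CDS mutates synonymously with probability
    ``target_ps`` scaled by its synonymous-site fraction, nonsynonymously
    with ``target_pn`` times its nonsynonymous fraction, choosing uniformly
    among single-base alternatives of that class (stop codons excluded), so
    E[Nd] = target_pn * N_sites and E[Sd] = target_ps * S_sites.
    """
    for t, name in ((target_pn, "target_pn"), (target_ps, "target_ps")):
        if not 0.0 <= t <= 0.5:
            raise ValueError(f"{name} must be in [0, 0.5]")
    rng = _rng_for(seed, 3)
    anc = _random_cds(n_codons, rng)
    derived = []
    for codon in anc:
        out = codon
        for pos in range(3):
            fs = _syn_fraction(out, pos)
            syn_alts, non_alts = [], []
            for b in _BASES:
                if b == out[pos]:
                    continue
                mut = out[:pos] + b + out[pos + 1 :]
                if mut in _STOPS:
                    continue
                (syn_alts if _aa(mut) == _aa(out) else non_alts).append(mut)
            u = rng.random()
            p_syn = target_ps * fs if syn_alts else 0.0
            p_non = target_pn * (1.0 - fs) if non_alts else 0.0
            if u < p_syn:
                out = syn_alts[int(rng.integers(len(syn_alts)))]
            elif u < p_syn + p_non:
                out = non_alts[int(rng.integers(len(non_alts)))]
        derived.append(out)
    truth = {"target_pn": target_pn, "target_ps": target_ps,
             "n_codons": n_codons, "seed": seed}
    return "".join(anc), "".join(derived), truth


# ---------------------------------------------------------------------------
# variants

def simulate_variants(genome: Genome, n_coding: int, n_noncoding: int,
                      seed: int = 0) -> str:
    """Place SNPs uniformly within the coding / intergenic compartments and
    emit minimal VCF 4.2 text (1-based positions), byte-reproducible."""
    from .snp import _coding_footprint, DEFAULT_CODING_KINDS

    if not genome.features:
        raise ValueError("genome has no feature annotation")
    L = len(genome)
    footprint = _coding_footprint(genome, DEFAULT_CODING_KINDS)
    mask = np.zeros(L, dtype=bool)
    for a, b in footprint:
        mask[a:b] = True
    coding_pos = np.flatnonzero(mask)
    noncoding_pos = np.flatnonzero(~mask)
    if n_coding > coding_pos.size or n_noncoding > noncoding_pos.size:
        raise ValueError("requested counts exceed available positions")
    rng = _rng_for(seed, 4)
    chosen = np.concatenate([
        rng.choice(coding_pos, size=n_coding, replace=False),
        rng.choice(noncoding_pos, size=n_noncoding, replace=False),
    ])
    chosen.sort()
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={genome.id},length={L}>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for pos in chosen:
        ref = genome.sequence[pos]
        if ref == "N":
            ref = "A"
        alts = [b for b in "ACGT" if b != ref]
        alt = alts[int(rng.integers(3))]
        lines.append(f"{genome.id}\t{pos + 1}\t.\t{ref}\t{alt}\t50\tPASS\t.")
    return "\n".join(lines) + "\n"
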
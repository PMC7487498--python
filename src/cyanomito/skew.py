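"""Nucleotide composition, skew profiles, replication signatures, G4 scanning.

GC-skew = (G-C)/(G+C) and AT-skew = (A-T)/(A+T) are computed on the analyzed
strand.  On a replicating circular genome, a guanine excess marks the leading
strand: a mitogenome whose cumulative GC-skew rises monotonically around the
whole circle is consistent with unidirectional replication (the entire
analyzed strand is leading), whereas a V/Λ-shaped cumulative curve marks an
origin/terminus pair of a bidirectional replication fork.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .seqio import Genome

#: Default sliding-window parameters: GC-content uses disjoint 48 bp windows,
#: skews use 1 kbp windows advanced in 20 bp steps.
GC_CONTENT_WINDOW = 48
SKEW_WINDOW = 1000
SKEW_STEP = 20


@dataclass
class SkewProfile:
    """Per-window statistic series plus a cumulative per-chunk skew series.

    ``positions`` are window-center coordinates.  ``cumulative`` is the
    running sum of GC-skews over successive disjoint ``step``-sized chunks
    (a true running sum, independent of window overlap);
    ``cumulative_positions`` are the chunk end coordinates.
    """

    window: int
    step: int
    positions: np.ndarray
    values: np.ndarray
    cumulative: np.ndarray
    cumulative_positions: np.ndarray
    circular: bool
    statistic: str = "gc_skew"
    undefined: np.ndarray | None = None  # windows with zero denominator

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.values):
            raise ValueError("positions/values length mismatch")


@dataclass
class ReplicationSignature:
    """Classification of a genome's skew geometry.

    ``single_strand_biased``: one strand is leading over (nearly) the whole
    circle — the unidirectional-replication signature.  ``origin_flanked``:
    the cumulative curve is V/Λ-shaped with a single origin/terminus pair —
    the bidirectional signature.  ``none``: neither.
    """

    mode: Literal["single_strand_biased", "origin_flanked", "none"]
    origin_pos: int | None = None
    terminus_pos: int | None = None
    min_window_skew: float = 0.0
    max_window_skew: float = 0.0
    fraction_positive_windows: float = 0.0


@dataclass
class G4Hit:
    """A merged region whose G4Hunter window scores pass threshold."""

    start: int
    end: int
    mean_score: float
    strand: Literal["+", "-"]


def base_counts(seq: str) -> dict[str, int]:
    """Counts of A, C, G, T; N never enters any composition denominator."""
    return {b: seq.count(b) for b in "ACGT"}


def skew_stats(seq: str) -> dict[str, float]:
    """Whole-sequence GC-skew, AT-skew and GC-content (%).

    A zero denominator yields ``nan`` rather than raising.
    """
    c = base_counts(seq)
    gc, at = c["G"] + c["C"], c["A"] + c["T"]
    return {
        "gc_skew": (c["G"] - c["C"]) / gc if gc else math.nan,
        "at_skew": (c["A"] - c["T"]) / at if at else math.nan,
        "gc_content_pct": 100.0 * gc / (gc + at) if gc + at else math.nan,
    }


_STAT_BASES = {
    "gc_skew": ("G", "C"),
    "at_skew": ("A", "T"),
}


def _window_series(seq: str, window: int, step: int, circular: bool):
    """Start positions and per-window base-count arrays via cumulative sums."""
    L = len(seq)
    if circular:
        starts = np.arange(0, L, step)
        ext = seq + seq[: window]
    else:
        if window > L:
            raise ValueError(f"window {window} exceeds linear sequence length {L}")
        starts = np.arange(0, L - window + 1, step)
        ext = seq
    arr = np.frombuffer(ext.encode(), dtype=np.uint8)
    counts = {}
    for b in "ACGT":
        ind = np.concatenate([[0], np.cumsum(arr == ord(b))])
        counts[b] = ind[starts + window] - ind[starts]
    return starts, counts


def sliding_profile(
    genome: Genome | str,
    statistic: str = "gc_skew",
    window: int | None = None,
    step: int | None = None,
) -> SkewProfile:
    """Windowed skew or GC-content profile with the cumulative skew series.

    Circular genomes wrap windows across the origin so every start position
    0, step, 2*step, ... is covered; linear genomes truncate at the end.
    Windows with a zero denominator record value 0 and are flagged undefined
    so cumulative sums stay defined (AT-rich windows occur in C-type
    mitogenomes).
    """
    if statistic not in ("gc_skew", "at_skew", "gc_content"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if window is None:
        window = GC_CONTENT_WINDOW if statistic == "gc_content" else SKEW_WINDOW
    if step is None:
        step = GC_CONTENT_WINDOW if statistic == "gc_content" else SKEW_STEP
    seq = genome.sequence if isinstance(genome, Genome) else genome
    circular = genome.topology == "circular" if isinstance(genome, Genome) else True
    if step < 1:
        raise ValueError("step must be >= 1")
    if window > len(seq):
        raise ValueError(f"window {window} exceeds genome length {len(seq)}")

    starts, counts = _window_series(seq, window, step, circular)
    if statistic == "gc_content":
        denom = sum(counts[b] for b in "ACGT")  # N excluded
        with np.errstate(invalid="ignore"):
            values = np.where(denom > 0, 100.0 * (counts["G"] + counts["C"]) / denom, 0.0)
        undefined = denom == 0
    else:
        x, y = _STAT_BASES[statistic]
        denom = counts[x] + counts[y]
        with np.errstate(invalid="ignore"):
            values = np.where(denom > 0, (counts[x] - counts[y]) / denom, 0.0)
        undefined = denom == 0

    positions = (starts + window // 2) % len(seq) if circular else starts + window // 2
    cum_pos, cum = cumulative_gc_skew(seq, step)
    return SkewProfile(
        window=window, step=step, positions=positions, values=values,
        cumulative=cum, cumulative_positions=cum_pos,
        circular=circular, statistic=statistic, undefined=undefined,
    )


def cumulative_gc_skew(seq: str | Genome, step: int = SKEW_STEP):
    """Running sum of GC-skews over successive disjoint step-sized chunks.

    Returns (chunk end positions, cumulative array).  Chunks with G+C = 0
    contribute 0.  The final chunk may be shorter than ``step``.
    """
    if isinstance(seq, Genome):
        seq = seq.sequence
    bounds = list(range(0, len(seq), step)) + [len(seq)]
    skews = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        chunk = seq[a:b]
        g, c = chunk.count("G"), chunk.count("C")
        skews.append((g - c) / (g + c) if g + c else 0.0)
    return np.array(bounds[1:]), np.cumsum(skews)


def _chunk_skews(seq: str, chunk: int) -> np.ndarray:
    """Disjoint chunk GC-skews at classification resolution."""
    n = len(seq) // chunk
    out = np.empty(n)
    for i in range(n):
        s = seq[i * chunk : (i + 1) * chunk]
        g, c = s.count("G"), s.count("C")
        out[i] = (g - c) / (g + c) if g + c else 0.0
    return out


def _longest_negative_run(deltas: np.ndarray) -> int:
    worst = run = 0
    for d in deltas:
        run = run + 1 if d < 0 else 0
        worst = max(worst, run)
    return worst


def classify_replication_signature(
    profile: SkewProfile,
    genome: Genome | str | None = None,
    positive_fraction_threshold: float = 0.95,
    run_tol: int = 2,
    min_arm_fraction: float = 0.30,
    arm_sign_fraction: float = 0.90,
) -> ReplicationSignature:
    """Classify a whole-genome skew profile into a replication signature.

    ``single_strand_biased`` when >= ``positive_fraction_threshold`` of
    windows share one skew sign and the cumulative curve is monotone (no
    counter-directional run longer than ``run_tol``); ``origin_flanked``
    when the cumulative curve, rotated to its global minimum, rises then
    falls with both arms covering >= ``min_arm_fraction`` of the circle and
    each arm's chunk skews sign-consistent (>= ``arm_sign_fraction`` of the
    rising arm positive and of the falling arm negative — a null random walk
    can produce two superficially monotone arms, but not sign-consistent
    ones).

    Monotonicity is judged on the cumulative curve aggregated into disjoint
    window-sized chunks: at the raw 20 bp step resolution sampling noise
    alone produces short decreasing runs even under a strong uniform bias,
    so ``run_tol`` counts in window-sized units.
    """
    if len(profile.values) < 10:
        raise ValueError("profile has fewer than 10 windows; insufficient resolution")

    vals = profile.values
    frac_pos = float(np.mean(vals > 0))
    frac_neg = float(np.mean(vals < 0))
    sig = ReplicationSignature(
        mode="none",
        min_window_skew=float(vals.min()),
        max_window_skew=float(vals.max()),
        fraction_positive_windows=frac_pos,
    )

    # cumulative curve at window-chunk resolution
    if genome is not None:
        seq = genome.sequence if isinstance(genome, Genome) else genome
        chunks = _chunk_skews(seq, profile.window)
    else:
        # aggregate the step-chunk cumulative into window-sized super-chunks
        per = max(1, profile.window // profile.step)
        cum = profile.cumulative
        idx = np.arange(per - 1, len(cum), per)
        coarse = cum[idx]
        chunks = np.diff(np.concatenate([[0.0], coarse]))
    n = len(chunks)
    if n < 4:
        raise ValueError("genome too short for classification at this window size")

    if frac_pos >= positive_fraction_threshold or frac_neg >= positive_fraction_threshold:
        deltas = chunks if frac_pos >= frac_neg else -chunks
        if _longest_negative_run(deltas) <= run_tol:
            sig.mode = "single_strand_biased"
            return sig

    # bidirectional: rotate cumulative to its global minimum, expect one rise
    # to the maximum and one fall back, each arm covering enough of the circle
    cum = np.cumsum(chunks)
    lo = int(np.argmin(cum))
    rot = np.roll(chunks, -(lo + 1))  # chunk sequence starting after the minimum
    rcum = np.cumsum(rot)
    hi = int(np.argmax(rcum))
    arm1, arm2 = hi + 1, n - hi - 1
    if arm1 >= min_arm_fraction * n and arm2 >= min_arm_fraction * n:
        up, down = rot[: hi + 1], rot[hi + 1 :]
        up_ok = (_longest_negative_run(up) <= run_tol
                 and np.mean(up > 0) >= arm_sign_fraction)
        down_ok = (_longest_negative_run(-down) <= run_tol
                   and np.mean(down < 0) >= arm_sign_fraction)
        if up_ok and down_ok:
            chunk_bp = profile.window
            origin = ((lo + 1) * chunk_bp) % (n * chunk_bp)
            terminus = ((lo + 1 + hi + 1) * chunk_bp) % (n * chunk_bp)
            sig.mode = "origin_flanked"
            sig.origin_pos = int(origin)
            sig.terminus_pos = int(terminus)
    return sig


def _g4_base_scores(seq: str) -> np.ndarray:
    """Per-base G4Hunter scores: within a maximal G-run of length k each base
    scores min(k, 4); within a C-run, -min(k, 4); other bases 0."""
    scores = np.zeros(len(seq))
    i = 0
    while i < len(seq):
        ch = seq[i]
        j = i
        while j < len(seq) and seq[j] == ch:
            j += 1
        if ch == "G":
            scores[i:j] = min(j - i, 4)
        elif ch == "C":
            scores[i:j] = -min(j - i, 4)
        i = j
    return scores


def g4hunter_scan(seq: str, window: int = 25, threshold: float = 1.2) -> list[G4Hit]:
    """Scan for potential G-quadruplex-forming regions (G4Hunter scoring).

    Window means of the per-base run-capped scores are computed at every
    start; consecutive same-sign qualifying windows (|mean| >= threshold)
    merge into maximal regions, re-scored as the mean over the merged span.
    Strand '+' for G-driven (positive) scores, '-' for C-driven.
    """
    seq = seq.upper()
    if window > len(seq):
        return []
    scores = _g4_base_scores(seq)
    csum = np.concatenate([[0.0], np.cumsum(scores)])
    starts = np.arange(0, len(seq) - window + 1)
    means = (csum[starts + window] - csum[starts]) / window

    hits: list[G4Hit] = []
    cur_start: int | None = None
    cur_sign = 0
    cur_end = 0
    for s, m in zip(starts, means):
        sign = 1 if m >= threshold else (-1 if m <= -threshold else 0)
        if sign and sign == cur_sign and s <= cur_end:
            cur_end = s + window
        else:
            if cur_sign:
                region = slice(cur_start, cur_end)
                mean = float(scores[region].mean())
                hits.append(G4Hit(start=cur_start, end=cur_end, mean_score=mean,
                                  strand="+" if cur_sign > 0 else "-"))
            cur_sign = sign
            cur_start = s if sign else None
            cur_end = s + window if sign else 0
    if cur_sign:
        region = slice(cur_start, cur_end)
        mean = float(scores[region].mean())
        hits.append(G4Hit(start=cur_start, end=cur_end, mean_score=mean,
                          strand="+" if cur_sign > 0 else "-"))
    return hits
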
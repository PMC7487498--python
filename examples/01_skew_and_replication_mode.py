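"""Windowed GC-skew and replication-mode inference on simulated mitogenomes.

Simulates one genome per replication model, profiles GC-skew (1 kb windows,
20 bp steps) and classifies the cumulative-curve geometry.  A monotone
cumulative curve marks a genome whose whole analyzed strand is leading
(unidirectional replication); a V-shaped curve marks an origin/terminus
pair (bidirectional); a neutral genome shows neither.
"""

from cyanomito.skew import classify_replication_signature, skew_stats, sliding_profile
from cyanomito.synthetic import simulate_mitogenome

for mode in ("unidirectional", "bidirectional", "neutral"):
    genome, truth = simulate_mitogenome(30000, mode, alpha=0.5, seed=42)
    stats = skew_stats(genome.sequence)
    profile = sliding_profile(genome)
    sig = classify_replication_signature(profile, genome=genome)
    print(f"{mode:15s} GC-skew={stats['gc_skew']:+.3f} "
          f"AT-skew={stats['at_skew']:+.3f} -> classified {sig.mode}", end="")
    if sig.mode == "origin_flanked":
        print(f" (origin ~{sig.origin_pos} bp, truth {truth.origin_pos} bp)")
    else:
        print()

# Whole-genome skew near +alpha with a single-strand-biased call mirrors the
# extreme-skew geometry of reduced Galdieria-type mitogenomes; the neutral
# genome's near-zero skews mirror the symmetric Cyanidium-type composition.
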
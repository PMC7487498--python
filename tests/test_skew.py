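"""Composition statistics, skew profiles, replication signatures, G4 scan."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cyanomito.seqio import Genome, reverse_complement
from cyanomito.skew import (
    G4Hit,
    base_counts,
    classify_replication_signature,
    cumulative_gc_skew,
    g4hunter_scan,
    skew_stats,
    sliding_profile,
)
from cyanomito.synthetic import simulate_mitogenome

nt_text = st.text(alphabet="ACGT", min_size=1, max_size=300)


# -- base counts and whole-genome stats --------------------------------------


def test_base_counts_excludes_n():
    assert base_counts("GGNCC") == {"A": 0, "C": 2, "G": 2, "T": 0}
    assert base_counts("") == {"A": 0, "C": 0, "G": 0, "T": 0}
    assert base_counts("AAAA")["A"] == 4


def test_skew_stats_examples():
    assert skew_stats("GGGGCC")["gc_skew"] == pytest.approx(1 / 3)
    st_ = skew_stats("GGCCAT")
    assert st_["gc_skew"] == 0 and st_["at_skew"] == 0
    assert math.isnan(skew_stats("AATT")["gc_skew"])  # zero denominator -> nan


@given(nt_text)
def test_skew_antisymmetric_under_reverse_complement(seq):
    """GC- and AT-skew flip sign exactly on the opposite strand."""
    fwd, rev = skew_stats(seq), skew_stats(reverse_complement(seq))
    for key in ("gc_skew", "at_skew"):
        if math.isnan(fwd[key]):
            assert math.isnan(rev[key])
        else:
            assert rev[key] == -fwd[key]
    if not math.isnan(fwd["gc_content_pct"]):
        assert rev["gc_content_pct"] == pytest.approx(fwd["gc_content_pct"])


# -- sliding profiles --------------------------------------------------------


def brute_force_profile(seq, window, step, circular, stat="gc_skew"):
    """Independent oracle: explicit per-window base counting."""
    L = len(seq)
    starts = range(0, L if circular else L - window + 1, step)
    vals = []
    for s in starts:
        if circular:
            w = (seq * 2)[s : s + window]
        else:
            w = seq[s : s + window]
        g, c, a, t = (w.count(x) for x in "GCAT")
        if stat == "gc_skew":
            vals.append((g - c) / (g + c) if g + c else 0.0)
        else:
            vals.append((a - t) / (a + t) if a + t else 0.0)
    return np.array(vals)


def test_profile_homopolymer_all_ones():
    prof = sliding_profile(Genome(id="g", sequence="G" * 2000), "gc_skew", 1000, 20)
    assert np.all(prof.values == 1.0)


def test_profile_alternating_gc_all_zero():
    prof = sliding_profile(Genome(id="g", sequence="GC" * 1000), "gc_skew", 1000, 20)
    assert np.all(prof.values == 0.0)


def test_profile_two_block_circular_crosses_zero_at_boundaries():
    """G-block then C-block on a circle: windows centered on either junction
    mix the two blocks equally, so the profile passes through 0 twice."""
    seq = "G" * 1000 + "C" * 1000
    prof = sliding_profile(Genome(id="g", sequence=seq), "gc_skew", 1000, 20)
    oracle = brute_force_profile(seq, 1000, 20, circular=True)
    np.testing.assert_allclose(prof.values, oracle, atol=1e-12)
    signs = np.sign(prof.values)
    assert (signs > 0).any() and (signs < 0).any() and (signs == 0).any()


@given(st.text(alphabet="ACGTN", min_size=12, max_size=200),
       st.integers(2, 12), st.integers(1, 7), st.booleans())
def test_profile_matches_brute_force(seq, window, step, circular):
    window = min(window, len(seq))
    g = Genome(id="g", sequence=seq,
               topology="circular" if circular else "linear")
    prof = sliding_profile(g, "gc_skew", window, step)
    oracle = brute_force_profile(seq, window, step, circular)
    np.testing.assert_allclose(prof.values, oracle, atol=1e-12)


def test_profile_whole_genome_window_reproduces_skew_stats():
    seq = "GGGCATTACGTAGCTA"
    prof = sliding_profile(Genome(id="g", sequence=seq, topology="linear"),
                           "gc_skew", len(seq), len(seq))
    assert prof.values[0] == pytest.approx(skew_stats(seq)["gc_skew"])


def test_profile_rotation_equivariance():
    """Rotating a circular sequence by r rotates window values accordingly."""
    g, _ = simulate_mitogenome(6000, "neutral", seed=42)
    seq = g.sequence
    r = 40  # multiple of step
    rot = seq[r:] + seq[:r]
    p0 = sliding_profile(Genome(id="a", sequence=seq), "gc_skew", 500, 20)
    p1 = sliding_profile(Genome(id="b", sequence=rot), "gc_skew", 500, 20)
    shift = r // 20
    np.testing.assert_allclose(np.roll(p0.values, -shift), p1.values, atol=1e-12)


def test_profile_window_too_large_on_linear_errors():
    g = Genome(id="g", sequence="ACGT" * 10, topology="linear")
    with pytest.raises(ValueError):
        sliding_profile(g, "gc_skew", 100, 10)


# -- cumulative skew ---------------------------------------------------------


def test_cumulative_two_block_rises_then_falls_to_zero():
    pos, cum = cumulative_gc_skew("G" * 100 + "C" * 100, step=20)
    assert np.all(np.diff(cum[:5]) > 0)
    assert np.all(np.diff(cum[5:]) < 0)
    assert cum[-1] == pytest.approx(0.0)


def test_cumulative_all_a_flat_zero():
    _, cum = cumulative_gc_skew("A" * 200, step=20)
    assert np.all(cum == 0.0)


def test_cumulative_unidirectional_simulation_strictly_increasing():
    g, _ = simulate_mitogenome(30000, "unidirectional", alpha=0.7, seed=1)
    _, cum = cumulative_gc_skew(g.sequence, step=1000)
    assert np.all(np.diff(cum) > 0)
    assert cum[0] > 0


# -- replication-signature classification ------------------------------------


def test_classifier_requires_minimum_resolution():
    prof = sliding_profile(Genome(id="g", sequence="ACGT" * 500), "gc_skew",
                           1500, 500)
    assert len(prof.values) < 10
    with pytest.raises(ValueError, match="resolution"):
        classify_replication_signature(prof)


def test_classifier_recovers_simulated_modes():
    """Mode recovery at study-like asymmetry (alpha=0.3), small replicate
    smoke check; the full 100-replicate rates run in the acceptance suite."""
    for mode, expected in [("unidirectional", "single_strand_biased"),
                           ("neutral", "none"),
                           ("bidirectional", "origin_flanked")]:
        hits = 0
        for seed in range(10):
            g, truth = simulate_mitogenome(30000, mode, alpha=0.3, seed=seed)
            sig = classify_replication_signature(sliding_profile(g), genome=g)
            if sig.mode == expected:
                if mode == "bidirectional":
                    d = abs(sig.origin_pos - truth.origin_pos)
                    d = min(d, len(g) - d)
                    if d <= 2000:
                        hits += 1
                else:
                    hits += 1
        assert hits >= 8, f"{mode}: {hits}/10"


def test_classifier_origin_flanked_reports_both_extrema():
    g, truth = simulate_mitogenome(40000, "bidirectional", alpha=0.5, seed=9)
    sig = classify_replication_signature(sliding_profile(g), genome=g)
    assert sig.mode == "origin_flanked"
    assert sig.origin_pos is not None and sig.terminus_pos is not None
    d = abs(sig.terminus_pos - truth.terminus_pos)
    assert min(d, len(g) - d) <= 2000


# -- G4Hunter ----------------------------------------------------------------


def brute_force_g4_base_scores(seq):
    """Oracle: per-base scores via explicit run scanning."""
    scores = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        run = j - i
        if seq[i] == "G":
            scores.extend([min(run, 4)] * run)
        elif seq[i] == "C":
            scores.extend([-min(run, 4)] * run)
        else:
            scores.extend([0] * run)
        i = j
    return scores


def brute_force_g4_hits(seq, window, threshold):
    """Oracle: exhaustive per-window scoring, then same-sign merging."""
    scores = brute_force_g4_base_scores(seq)
    qual = []
    for s in range(len(seq) - window + 1):
        m = sum(scores[s : s + window]) / window
        if abs(m) >= threshold:
            qual.append((s, 1 if m > 0 else -1))
    regions = []
    for s, sign in qual:
        if regions and sign == regions[-1][2] and s <= regions[-1][1]:
            regions[-1] = (regions[-1][0], s + window, sign)
        else:
            regions.append((s, s + window, sign))
    return [
        (a, b, sum(scores[a:b]) / (b - a), "+" if sign > 0 else "-")
        for a, b, sign in regions
    ]


def test_g4_homopolymer_hits():
    (hit,) = g4hunter_scan("G" * 25)
    assert (hit.start, hit.end, hit.mean_score, hit.strand) == (0, 25, 4.0, "+")
    (hit,) = g4hunter_scan("C" * 25)
    assert (hit.mean_score, hit.strand) == (-4.0, "-")


def test_g4_alternating_below_threshold():
    assert g4hunter_scan(("ACGT" * 7)[:25]) == []


def test_g4_window_longer_than_sequence_is_empty():
    assert g4hunter_scan("GGGG", window=25) == []


@given(st.text(alphabet="ACGT", min_size=25, max_size=400),
       st.sampled_from([1.0, 1.2, 1.5]))
def test_g4_matches_exhaustive_scorer(seq, threshold):
    got = [(h.start, h.end, h.mean_score, h.strand)
           for h in g4hunter_scan(seq, 25, threshold)]
    want = brute_force_g4_hits(seq, 25, threshold)
    assert len(got) == len(want)
    for (a, b, m, s), (a2, b2, m2, s2) in zip(got, want):
        assert (a, b, s) == (a2, b2, s2)
        assert m == pytest.approx(m2)
    for h in g4hunter_scan(seq, 25, threshold):
        assert abs(h.mean_score) <= 4 and h.end - h.start >= 25
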
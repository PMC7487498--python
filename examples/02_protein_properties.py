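"""Conserved-site amino-acid composition and property indices by group.

Simulates a 13-taxon protein alignment in which one clade's positive-charge
composition (R+K+H) is shifted up by 4 percentage points — the scale of
contrast seen between reduced and conventional cyanidiophycean mitogenome
clades — then compares groups with a Kruskal–Wallis test and Dunn post-hoc.
"""

from cyanomito.protprops import concatenated_group_composition
from cyanomito.stats import pairwise_posthoc
from cyanomito.synthetic import simulate_protein_groups

aln, truth = simulate_protein_groups(length=3845, class_shift=4.0, seed=7)
table = concatenated_group_composition(aln)

print(table.groupby("group")["pct_positive"].agg(["mean", "sem"]).round(2))
print(f"\ngenerating frequencies: shifted group "
      f"{truth['target_positive_pct']:.1f}%, others "
      f"{truth['baseline_positive_pct']:.1f}%")

groups = [grp["pct_positive"].to_numpy() for _, grp in table.groupby("group")]
labels = sorted(table["group"].unique())
res = pairwise_posthoc(groups, labels)
print(f"\nKruskal-Wallis H={res.statistic:.2f} (df={res.df}) p={res.p_value:.2g}")
for a, b, p in res.pairwise:
    print(f"  {a} vs {b}: adjusted p={p:.3g}")
# The shifted group separates from both others; the two unshifted groups do
# not separate from each other.
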
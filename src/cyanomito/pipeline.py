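"""End-to-end orchestration: genome summaries, skew classification, protein
property comparison, optional Ka/Ks and TIGER tables, from a plain config.

The run is a pure function of (inputs, config, seed): rerunning with the
same config writes byte-identical tables.  Every output directory carries a
provenance file with the parameter set, package version and input content
digests, so results survive file renames.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from . import protprops, skew, snp, stats
from .seqio import Genome, read_alignment, read_fasta, read_genbank, read_group_map, read_vcf

VALID_GROUPS = {"G_type", "C_type", "outgroup"}


@dataclass
class RunConfig:
    genomes: dict[str, str] = field(default_factory=dict)  # path -> group
    alignments: dict[str, str] = field(default_factory=dict)  # gene -> path
    group_map: str | None = None
    gene_list: tuple[str, ...] = protprops.CONSERVED_GENES_16
    vcfs: dict[str, str] = field(default_factory=dict)  # genome id -> vcf path
    skew_window: int = skew.SKEW_WINDOW
    skew_step: int = skew.SKEW_STEP
    alpha: float = 0.05
    out_dir: str = "cyanomito_out"
    seed: int = 0

    def validate(self) -> None:
        for p in list(self.genomes) + list(self.alignments.values()) + list(self.vcfs.values()):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        bad = set(self.genomes.values()) - VALID_GROUPS
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}; use {sorted(VALID_GROUPS)}")


def read_config(path: str | Path) -> RunConfig:
    """Plain key=value config; repeated keys 'genome', 'alignment', 'vcf'
    take 'path:label' values."""
    cfg = RunConfig()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key == "genome":
            p, _, grp = value.rpartition(":")
            cfg.genomes[p] = grp
        elif key == "alignment":
            gene, _, p = value.partition(":")
            cfg.alignments[gene] = p
        elif key == "vcf":
            gid, _, p = value.partition(":")
            cfg.vcfs[gid] = p
        elif key == "group_map":
            cfg.group_map = value
        elif key in ("skew_window", "skew_step", "seed"):
            setattr(cfg, key, int(value))
        elif key == "alpha":
            cfg.alpha = float(value)
        elif key == "out_dir":
            cfg.out_dir = value
        else:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
    return cfg


def noncoding_fraction(genome: Genome) -> float:
    """Percent of the genome outside the union of feature footprints;
    overlapping features are merged before counting."""
    merged = snp._coding_footprint(genome, ("CDS", "tRNA", "rRNA", "other"))
    covered = sum(b - a for a, b in merged)
    return 100.0 * (len(genome) - covered) / len(genome)


def genome_summary(genome: Genome) -> dict:
    """A per-genome summary row: size, composition stats, gene counts,
    non-coding percent (when features are present)."""
    st = skew.skew_stats(genome.sequence)
    counts = {k: sum(1 for f in genome.features if f.kind == k)
              for k in ("CDS", "tRNA", "rRNA")}
    row = {
        "genome": genome.id,
        "size_bp": len(genome),
        "gc_content_pct": round(st["gc_content_pct"], 1),
        "gc_skew": round(st["gc_skew"], 2),
        "at_skew": round(st["at_skew"], 2),
        "n_genes": sum(counts.values()),
        **{f"n_{k}": v for k, v in counts.items()},
    }
    row["noncoding_pct"] = (round(noncoding_fraction(genome), 2)
                            if genome.features else None)
    return row


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _load_genome(path: str) -> Genome:
    if Path(path).suffix.lower() in (".gb", ".gbk", ".gbff", ".genbank"):
        return read_genbank(path)
    return read_fasta(path)[0]


def run_compare(config: RunConfig) -> Path:
    """Run every configured stage and write the report bundle.

    Emits summary.tsv (one characteristics row per genome), skew profiles and
    classifications, protein property tables with group tests, and optional
    SNP summaries; provenance.json records parameters, version and input
    digests.  Any stage failure aborts naming the stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {
        "package": "cyanomito", "version": __version__,
        "config": {k: v for k, v in asdict(config).items()},
        "input_digests": {p: _digest(p) for p in
                          list(config.genomes) + list(config.alignments.values())
                          + list(config.vcfs.values())},
    }

    stage = "genome summaries"
    try:
        genomes = {p: _load_genome(p) for p in config.genomes}
        rows = [genome_summary(g) | {"group": config.genomes[p]}
                for p, g in genomes.items()]
        pd.DataFrame(rows).to_csv(out / "summary.tsv", sep="\t", index=False)

        stage = "skew profiling"
        classifications = []
        for p, g in genomes.items():
            prof = skew.sliding_profile(g, "gc_skew", config.skew_window,
                                        config.skew_step)
            df = pd.DataFrame({"position": prof.positions, "gc_skew": prof.values})
            df.to_csv(out / f"skew_{g.id}.tsv", sep="\t", index=False,
                      float_format="%.6f")
            pd.DataFrame({"position": prof.cumulative_positions,
                          "cumulative_gc_skew": prof.cumulative}).to_csv(
                out / f"cumskew_{g.id}.tsv", sep="\t", index=False,
                float_format="%.6f")
            sig = skew.classify_replication_signature(prof, genome=g)
            classifications.append({
                "genome": g.id, "group": config.genomes[p], "mode": sig.mode,
                "origin_pos": sig.origin_pos, "terminus_pos": sig.terminus_pos,
                "fraction_positive_windows": round(sig.fraction_positive_windows, 4),
            })
        if classifications:
            pd.DataFrame(classifications).to_csv(
                out / "replication_signatures.tsv", sep="\t", index=False)

        stage = "protein properties"
        if config.alignments:
            gmap = read_group_map(config.group_map) if config.group_map else {}
            alns = {gene: read_alignment(p, gmap)
                    for gene, p in config.alignments.items()}
            table = protprops.per_gene_property_table(alns, tuple(alns))
            table.to_csv(out / "protein_properties.tsv", sep="\t", index=False,
                         float_format="%.4f")
            protprops.group_summary(table).to_csv(
                out / "protein_group_summary.tsv", sep="\t", float_format="%.4f")
            tests = []
            for col in ("pct_positive", "pct_hydrophilic", "gravy",
                        "aliphatic_index", "instability_index"):
                per_taxon = table.groupby(["taxon", "group"])[col].mean().reset_index()
                grouped = [grp[col].to_numpy()
                           for _, grp in per_taxon.groupby("group")]
                labels = sorted(per_taxon["group"].unique())
                if len(grouped) < 2:
                    continue
                res = stats.pairwise_posthoc(grouped, labels, alpha=config.alpha)
                tests.append({"factor": col, "H": round(res.statistic, 4),
                              "df": res.df, "p": res.p_value,
                              "pairwise": "; ".join(
                                  f"{a}|{b}:p={p:.4g}" for a, b, p in res.pairwise),
                              "note": res.note})
            pd.DataFrame(tests).to_csv(out / "group_tests.tsv", sep="\t", index=False)

        stage = "snp density"
        if config.vcfs:
            srows = []
            by_id = {g.id: g for g in genomes.values()}
            for gid, vp in config.vcfs.items():
                if gid not in by_id:
                    raise ValueError(f"vcf references unknown genome id {gid!r}")
                variants = read_vcf(vp, genome_id=gid)
                s = snp.snp_density(variants, by_id[gid])
                srows.append({"genome": gid, "n_snps": s.n_snps,
                              "genome_kbp": round(s.genome_kbp, 3),
                              "density_snps_per_kbp": f"{s.density:.3f}",
                              "n_coding": s.n_coding, "n_noncoding": s.n_noncoding})
            pd.DataFrame(srows).to_csv(out / "snp_summary.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "provenance.json").write_text(json.dumps(provenance, indent=2,
                                                    sort_keys=True) + "\n")
    return out
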
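"""End-to-end orchestration: simulate -> DE -> allele comparison -> motifs.

A single seeded run produces DE tables for every genotype, allele-comparison
tables for both genetic backgrounds, Venn and PCA summaries, a promoter
motif scan, and a JSON manifest recording the package version, seed,
parameters, and every file written.  Deterministic stages are bit-identical
under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__, compare, de, motifs, simulate
from .published import ART1_MOTIF

logger = logging.getLogger(__name__)

# (background, resistant-allele carrier, sensitive-allele carrier)
BACKGROUND_PAIRS = [("A", "parentA", "nilA"), ("B", "nilB", "parentB")]


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    n_genes: int = 4000
    de_criteria: compare.DECriteria = field(default_factory=compare.DECriteria)
    ratio_thresholds: tuple[float, ...] = (1.5, 2.0)
    motif: str = ART1_MOTIF
    n_promoters: int = 200
    promoter_length: int = 2000
    pca_top: int = 500


def run_full_pipeline(config: RunConfig) -> dict:
    """Run the whole synthetic analysis; returns the output manifest."""
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "n_genes": config.n_genes,
            "de_criteria": dataclasses.asdict(config.de_criteria),
            "ratio_thresholds": list(config.ratio_thresholds),
            "motif": config.motif,
            "n_promoters": config.n_promoters,
            "promoter_length": config.promoter_length,
            "pca_top": config.pca_top,
        },
        "files": {},
    }

    def save(key: str, name: str, writer) -> str:
        path = os.path.join(config.outdir, name)
        writer(path)
        manifest["files"][key] = name
        return path

    # --- simulate --------------------------------------------------------
    sim_cfg = simulate.SimConfig(n_genes=config.n_genes, seed=config.seed)
    counts, design, truth = simulate.simulate_counts(sim_cfg)
    save("counts", "counts.tsv", lambda p: counts.to_csv(p, sep="\t"))
    save("design", "design.tsv", lambda p: design.to_csv(p, sep="\t"))
    save("truth", "truth.json", truth.to_json)

    # --- DE --------------------------------------------------------------
    sf = de.estimate_size_factors(counts)
    filtered = de.prefilter_low_expression(counts, sf).filtered
    disp = de.estimate_dispersions(filtered, sf, design)
    norm = de.normalize_counts(filtered, sf)

    results, de_sets = {}, {}
    for genotype in simulate.GENOTYPES:
        res = de.nb_wald_contrast(filtered, sf, disp, design, genotype)
        results[genotype] = res
        save(f"de_{genotype}", f"de_{genotype}.tsv",
             lambda p, r=res: r.to_csv(p, sep="\t"))
        de_sets[genotype] = compare.call_de_genes(
            res, norm, config.de_criteria, genotype=genotype
        )

    # --- allele comparison per genetic background ------------------------
    venn_summary = {}
    for bg, ref_g, alt_g in BACKGROUND_PAIRS:
        ref, alt = results[ref_g], results[alt_g]
        shared_up = sorted(set(de_sets[ref_g][0].genes) | set(de_sets[alt_g][0].genes))
        rows = [
            (g, float(ref.loc[g, "log2FC"]), float(alt.loc[g, "log2FC"]))
            for g in shared_up
            if np.isfinite(ref.loc[g, "log2FC"]) and np.isfinite(alt.loc[g, "log2FC"])
        ]
        table, counts_by_thr = compare.classify_table(rows, config.ratio_thresholds)
        save(f"allele_comparison_{bg}", f"allele_comparison_{bg}.tsv",
             lambda p, t=table: t.to_csv(p, sep="\t", index=False))
        v = compare.venn_counts(de_sets[ref_g][0].genes, de_sets[alt_g][0].genes)
        venn_summary[bg] = {
            "up_only_resistant_allele": v.only_a,
            "up_shared": v.shared,
            "up_only_sensitive_allele": v.only_b,
            "ratio_class_counts": {str(k): v2 for k, v2 in counts_by_thr.items()},
        }
    save("venn", "venn.json",
         lambda p: json.dump(venn_summary, open(p, "w"), indent=2))

    # --- PCA -------------------------------------------------------------
    transformed = compare.transform_counts(filtered, sf)
    pca = compare.pca_top_variance(transformed, min(config.pca_top, filtered.shape[0]))
    save("pca_scores", "pca_scores.tsv", lambda p: pca.scores.to_csv(p, sep="\t"))

    # --- promoter motif scan ---------------------------------------------
    library = simulate.simulate_promoters(
        n_seqs=config.n_promoters, length=config.promoter_length,
        gc=0.5, seed=config.seed,
    )
    save("promoters", "promoters.fasta", library.to_fasta)
    scan = motifs.scan_counts(library, config.motif)
    prev = motifs.prevalence_summary(scan)
    motif_summary = {
        "motif": config.motif,
        "n_with_hit": prev.n_with_hit,
        "n_total": prev.n_total,
        "mean_hits_per_sequence": prev.mean_hits_per_sequence,
        "expected_hits_uniform": motifs.expected_hits(
            config.motif, config.promoter_length
        ),
    }
    save("motif_summary", "motif_summary.json",
         lambda p: json.dump(motif_summary, open(p, "w"), indent=2))

    save("manifest", "manifest.json",
         lambda p: json.dump(manifest, open(p, "w"), indent=2))
    return manifest
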
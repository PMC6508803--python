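"""Synthetic data generator for the reciprocal allele-swap NIL design.

Emulates a 4-genotype x 2-treatment x 4-replicate bulk RNA-seq experiment in
which two parental lines and their reciprocal near-isogenic lines (NILs) carry
either the resistant-parent or the sensitive-parent allele of a transcription
factor locus.  Counts are negative-binomial with a DESeq-style mean-variance
relationship Var = mu + alpha * mu^2, planted gene classes, per-sample depth
factors, and a ground-truth channel for parameter-recovery tests.

Genotype labels and their allele / background structure:

===========  =================  ===========
genotype     allele at locus    background
===========  =================  ===========
parentA      resistant          A
nilA         sensitive          A
parentB      sensitive          B
nilB         resistant          B
===========  =================  ===========

Gene classes:

``null``
    no treatment response anywhere.
``allele_dependent``
    stress-induced in all genotypes, but with a strictly larger log2
    fold-change in genotypes carrying the resistant allele.
``allele_independent``
    equally stress-induced in every genotype.
``background_specific``
    stress-induced only in background B, regardless of allele.
``introgression_effect``
    constant (treatment-independent) expression shift in the two NILs,
    mimicking genes resident on the introgressed segment; true stress
    log2FC is zero.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

GENOTYPES = ("parentA", "nilA", "parentB", "nilB")
TREATMENTS = ("control", "stress")
RESISTANT_ALLELE = {"parentA": True, "nilA": False, "parentB": False, "nilB": True}
BACKGROUND = {"parentA": "A", "nilA": "A", "parentB": "B", "nilB": "B"}

GENE_CLASSES = (
    "null",
    "allele_dependent",
    "allele_independent",
    "background_specific",
    "introgression_effect",
)


def default_design() -> list[tuple[str, str, int]]:
    """The study layout: 4 genotypes x 2 treatments x 4 replicates = 32 samples."""
    return [(g, t, 4) for g in GENOTYPES for t in TREATMENTS]


@dataclass
class SimConfig:
    """Parameters of the count simulation.

    Defaults reproduce the statistical structure the analysis assumes:
    log-normal baseline means (meanlog 4, sdlog 1.5) give a realistic dynamic
    range for the low-expression filter, depth factors are log-uniform on
    [0.5, 2] to exercise size-factor estimation, and the dispersion trend
    alpha(mu) = a0 + a1/mu decays with expression strength.  Planted effect
    sizes are modeled on the magnitudes seen in published allele-swap
    fold-change tables (resistant-allele log2FC around 2.5 against an
    attenuated sensitive-allele response).
    """

    n_genes: int = 8000
    design: list[tuple[str, str, int]] = field(default_factory=default_design)
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "null": 0.80,
            "allele_dependent": 0.05,
            "allele_independent": 0.05,
            "background_specific": 0.05,
            "introgression_effect": 0.05,
        }
    )
    effect_log2fc: Mapping[str, float] = field(
        default_factory=lambda: {
            "null": 0.0,
            "allele_dependent": 2.5,
            "allele_independent": 2.0,
            "background_specific": 2.0,
            "introgression_effect": 1.0,
        }
    )
    # fraction of the allele_dependent effect retained under the sensitive allele
    sensitive_attenuation: float = 0.3
    dispersion_trend: tuple[float, float] = (0.01, 1.0)
    mu_meanlog: float = 4.0
    mu_sdlog: float = 1.5
    lib_size_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not self.design:
            raise ValueError("design is empty")
        for genotype, treatment, n_rep in self.design:
            if genotype not in GENOTYPES:
                raise ValueError(f"unknown genotype label {genotype!r}")
            if treatment not in TREATMENTS:
                raise ValueError(f"unknown treatment {treatment!r}")
            if n_rep < 2:
                raise ValueError("n_replicates must be >= 2 in every design cell")
        total = sum(self.class_fractions.get(c, 0.0) for c in GENE_CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_fractions must sum to 1, got {total}")
        if any(f < 0 for f in self.class_fractions.values()):
            raise ValueError("class_fractions must be non-negative")
        for cls, eff in self.effect_log2fc.items():
            if not np.isfinite(eff):
                raise ValueError(f"effect_log2fc[{cls!r}] is not finite")
        lo, hi = self.lib_size_range
        if not (0 < lo <= hi):
            raise ValueError("lib_size_range must satisfy 0 < lo <= hi")


@dataclass
class SimTruth:
    """Ground truth of a simulated experiment.

    ``table`` has one row per gene with columns: ``gene_class``, ``mu``,
    ``alpha``, ``intro_shift`` (treatment-independent NIL log2 shift) and
    ``lfc_<genotype>`` — the true stress-vs-control log2FC in that genotype.
    ``size_factors`` are the depth factors used for each sample.
    """

    table: pd.DataFrame
    size_factors: pd.Series

    def true_lfc(self, genotype: str) -> pd.Series:
        return self.table[f"lfc_{genotype}"]

    def to_json(self, path) -> None:
        payload = {
            "genes": self.table.reset_index().to_dict(orient="list"),
            "size_factors": {
                "sample": list(self.size_factors.index),
                "value": [float(v) for v in self.size_factors],
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _class_log2fc(gene_class: str, genotype: str, cfg: SimConfig) -> float:
    """True stress log2FC for one gene class in one genotype."""
    eff = cfg.effect_log2fc.get(gene_class, 0.0)
    if gene_class in ("null", "introgression_effect"):
        return 0.0
    if gene_class == "allele_independent":
        return eff
    if gene_class == "background_specific":
        return eff if BACKGROUND[genotype] == "B" else 0.0
    if gene_class == "allele_dependent":
        return eff if RESISTANT_ALLELE[genotype] else cfg.sensitive_attenuation * eff
    raise ValueError(f"unknown gene class {gene_class!r}")


def sample_nb(rng: np.random.Generator, mean, alpha, size=None) -> np.ndarray:
    """Draw NB(mean, dispersion alpha) counts with Var = mean + alpha*mean^2.

    Uses the Gamma–Poisson mixture; alpha == 0 degenerates to Poisson.
    """
    if size is None:
        mean, alpha = np.broadcast_arrays(np.asarray(mean, float), np.asarray(alpha, float))
    else:
        mean = np.broadcast_to(np.asarray(mean, float), size)
        alpha = np.broadcast_to(np.asarray(alpha, float), size)
    pos = alpha > 0
    shape = np.where(pos, 1.0 / np.where(pos, alpha, 1.0), 1.0)
    lam = np.where(pos, rng.gamma(shape, np.where(pos, alpha, 0.0) * mean), mean)
    return rng.poisson(lam)


def simulate_counts(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate a count matrix, its design table, and the ground truth.

    Returns
    -------
    counts : DataFrame, genes x samples, integer
    design : DataFrame indexed by sample id with columns genotype, treatment,
        replicate
    truth : SimTruth
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- samples ---------------------------------------------------------
    rows = []
    for genotype, treatment, n_rep in config.design:
        for r in range(1, n_rep + 1):
            rows.append((f"{genotype}_{treatment}_r{r}", genotype, treatment, r))
    design = pd.DataFrame(
        rows, columns=["sample", "genotype", "treatment", "replicate"]
    ).set_index("sample")
    if design.index.duplicated().any():
        raise ValueError("duplicate design cells produce duplicate sample ids")
    n_samples = len(design)

    lo, hi = config.lib_size_range
    s = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))
    size_factors = pd.Series(s, index=design.index, name="size_factor")

    # --- genes -----------------------------------------------------------
    gene_ids = [f"gene{idx:05d}" for idx in range(config.n_genes)]
    fractions = np.array([config.class_fractions.get(c, 0.0) for c in GENE_CLASSES])
    classes = rng.choice(GENE_CLASSES, size=config.n_genes, p=fractions / fractions.sum())
    mu = rng.lognormal(config.mu_meanlog, config.mu_sdlog, size=config.n_genes)
    a0, a1 = config.dispersion_trend
    alpha = a0 + a1 / mu

    truth_tbl = pd.DataFrame(
        {"gene_class": classes, "mu": mu, "alpha": alpha},
        index=pd.Index(gene_ids, name="gene"),
    )
    intro = config.effect_log2fc.get("introgression_effect", 0.0)
    truth_tbl["intro_shift"] = np.where(classes == "introgression_effect", intro, 0.0)
    for genotype in GENOTYPES:
        truth_tbl[f"lfc_{genotype}"] = [
            _class_log2fc(c, genotype, config) for c in classes
        ]

    # --- counts ----------------------------------------------------------
    is_stress = (design["treatment"] == "stress").to_numpy()
    is_nil = design["genotype"].isin(["nilA", "nilB"]).to_numpy()
    lfc_by_sample = np.stack(
        [truth_tbl[f"lfc_{g}"].to_numpy() for g in design["genotype"]], axis=1
    )  # genes x samples
    log2_mean = (
        np.log2(mu)[:, None]
        + lfc_by_sample * is_stress[None, :]
        + truth_tbl["intro_shift"].to_numpy()[:, None] * is_nil[None, :]
    )
    mean = s[None, :] * np.exp2(log2_mean)
    counts = sample_nb(rng, mean, np.broadcast_to(alpha[:, None], mean.shape))
    counts = pd.DataFrame(counts, index=truth_tbl.index, columns=design.index)

    return counts, design, SimTruth(table=truth_tbl, size_factors=size_factors)


# ---------------------------------------------------------------------------
# promoter libraries
# ---------------------------------------------------------------------------

def simulate_promoters(
    n_seqs: int,
    length: int,
    gc: float = 0.5,
    planted_motif=None,
    planted_count: int = 0,
    seed: int = 0,
    avoid_motif=None,
    max_rejections: int = 1000,
):
    """Generate an i.i.d.-base promoter library, optionally planting motifs.

    Bases are drawn with P(G) = P(C) = gc/2 and P(A) = P(T) = (1-gc)/2.
    Each planted instance is a uniformly chosen concrete expansion of the
    IUPAC pattern, inserted at non-overlapping random positions.  When
    ``avoid_motif`` is given, background sequences containing that motif are
    re-drawn (rejection sampling), which gives a motif-free background to
    plant into.
    """
    from .motifs import MotifPattern, PromoterEntry, PromoterLibrary, scan_sequence

    if not 0 < gc < 1:
        raise ValueError("gc must be strictly between 0 and 1")
    if n_seqs < 0 or length < 0:
        raise ValueError("n_seqs and length must be non-negative")
    motif = MotifPattern(planted_motif) if isinstance(planted_motif, str) else planted_motif
    avoid = MotifPattern(avoid_motif) if isinstance(avoid_motif, str) else avoid_motif
    if motif is not None and planted_count > 0:
        if planted_count * len(motif) > length:
            raise ValueError("planted motifs do not fit in the sequence length")

    rng = np.random.default_rng(seed)
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.frombuffer(b"ACGT", dtype="S1")

    entries = []
    for i in range(n_seqs):
        for _ in range(max_rejections):
            seq_arr = rng.choice(bases, size=length, p=base_p)
            seq = seq_arr.tobytes().decode()
            if avoid is None or not scan_sequence(seq, avoid):
                break
        else:
            raise RuntimeError(
                f"could not draw a background free of {avoid.iupac} "
                f"in {max_rejections} attempts"
            )
        if motif is not None and planted_count > 0:
            positions = _nonoverlapping_positions(
                rng, length, len(motif), planted_count
            )
            chars = list(seq)
            for pos in positions:
                word = "".join(rng.choice(sorted(motif.position_sets[k]))
                               for k in range(len(motif)))
                chars[pos:pos + len(motif)] = word
            seq = "".join(chars)
        entries.append(PromoterEntry(gene_id=f"seq{i:05d}", sequence=seq))
    return PromoterLibrary(entries)


def _nonoverlapping_positions(
    rng: np.random.Generator, length: int, width: int, count: int
) -> list[int]:
    """Uniform non-overlapping start positions via gap allocation.

    Distributes the free slack uniformly (multivariate hypergeometric-style
    stars and bars) so every non-overlapping configuration is reachable.
    """
    slack = length - count * width
    if slack < 0:
        raise ValueError("motifs do not fit")
    cuts = np.sort(rng.integers(0, slack + 1, size=count))
    return [int(cuts[k] + k * width) for k in range(count)]


def write_outputs(outdir, counts, design, truth: SimTruth) -> dict:
    """Write counts/design as TSV and truth as JSON; return the file map."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "counts": os.path.join(outdir, "counts.tsv"),
        "design": os.path.join(outdir, "design.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    counts.to_csv(paths["counts"], sep="\t")
    design.to_csv(paths["design"], sep="\t")
    truth.to_json(paths["truth"])
    return paths
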
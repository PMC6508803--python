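"""Degenerate (IUPAC) motif scanning over promoter libraries.

The transcription-factor binding site studied here (GGNVS, and its less
degenerate form GGYMS) is short and highly degenerate, so it occurs by chance
in nearly every 2-kb upstream region.  This module builds promoter libraries
from a genome FASTA + GFF3 annotation, counts overlapping motif occurrences,
summarizes prevalence, and computes the analytic chance expectation

    E[hits] = (L - m + 1) * prod_i sum_{b in code_i} p_b

for an i.i.d. background with base frequencies p, doubled when both strands
are scanned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

# IUPAC nucleotide codes -> the set of concrete bases each matches.
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


class MotifPattern:
    """A degenerate DNA motif written in IUPAC one-letter codes."""

    def __init__(self, iupac: str):
        iupac = iupac.strip().upper()
        if not iupac:
            raise ValueError("motif must be non-empty")
        bad = [c for c in iupac if c not in IUPAC_CODES]
        if bad:
            raise ValueError(f"invalid IUPAC code(s) {bad} in motif {iupac!r}")
        self.iupac = iupac
        self.position_sets = [frozenset(IUPAC_CODES[c]) for c in iupac]

    def __len__(self) -> int:
        return len(self.iupac)

    def __repr__(self) -> str:
        return f"MotifPattern({self.iupac!r})"

    @property
    def degeneracy(self) -> int:
        """Number of concrete words the pattern expands to."""
        out = 1
        for s in self.position_sets:
            out *= len(s)
        return out

    def expansions(self) -> Iterator[str]:
        """All concrete words matched by the pattern, lexicographic order."""
        from itertools import product

        for word in product(*(sorted(s) for s in self.position_sets)):
            yield "".join(word)

    def matches(self, word: str) -> bool:
        word = word.upper()
        return len(word) == len(self) and all(
            b in s for b, s in zip(word, self.position_sets)
        )

    def reverse_complement(self) -> "MotifPattern":
        return MotifPattern(reverse_complement(self.iupac))


@dataclass
class PromoterEntry:
    """One upstream regulatory sequence (5'->3' on the gene's strand)."""

    gene_id: str
    sequence: str
    seqid: str | None = None
    start: int | None = None  # 1-based inclusive genomic interval
    end: int | None = None
    strand: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)


class PromoterLibrary:
    def __init__(self, entries: Sequence[PromoterEntry]):
        self.entries = list(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[PromoterEntry]:
        return iter(self.entries)

    def __getitem__(self, i) -> PromoterEntry:
        return self.entries[i]

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                header = e.gene_id
                if e.seqid is not None:
                    header += f" {e.seqid}:{e.start}-{e.end}({e.strand})"
                fh.write(f">{header}\n")
                for i in range(0, len(e.sequence), 70):
                    fh.write(e.sequence[i:i + 70] + "\n")

    @classmethod
    def from_fasta(cls, path) -> "PromoterLibrary":
        from Bio import SeqIO

        entries = [
            PromoterEntry(gene_id=rec.id, sequence=str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")
        ]
        return cls(entries)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _position_tables(motif: MotifPattern) -> np.ndarray:
    """Boolean lookup tables, one row per motif position, indexed by byte."""
    tables = np.zeros((len(motif), 256), dtype=bool)
    for i, allowed in enumerate(motif.position_sets):
        for b in allowed:
            tables[i, ord(b)] = True
            tables[i, ord(b.lower())] = True
    return tables


def scan_sequence(seq: str, motif: MotifPattern, strand_mode: str = "given") -> list[int]:
    """Start positions (0-based) of all overlapping motif occurrences.

    Ambiguity codes in the *sequence* (e.g. N) never match.  With
    ``strand_mode="both"`` the reverse complement of the motif is also
    scanned and its hit positions (on the given strand's coordinates) are
    appended.
    """
    if strand_mode not in ("given", "both"):
        raise ValueError("strand_mode must be 'given' or 'both'")
    m = len(motif)
    if len(seq) < m:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n_win = len(seq) - m + 1
    tables = _position_tables(motif)
    ok = tables[0][arr[:n_win]]
    for i in range(1, m):
        ok &= tables[i][arr[i:i + n_win]]
    positions = np.flatnonzero(ok).tolist()
    if strand_mode == "both":
        rc = motif.reverse_complement()
        if rc.iupac != motif.iupac:
            positions = sorted(set(positions) | set(scan_sequence(seq, rc)))
        # palindromic patterns: the reverse-complement scan adds nothing new
    return positions


@dataclass
class ScanResult:
    """Per-entry overlapping hit counts and positions for one motif."""

    motif: MotifPattern
    gene_ids: list[str]
    positions: list[list[int]]

    @property
    def counts(self) -> np.ndarray:
        return np.array([len(p) for p in self.positions])


def scan_counts(
    library: PromoterLibrary, motif: MotifPattern | str, strand_mode: str = "given"
) -> ScanResult:
    """Count overlapping motif occurrences in every library entry."""
    if isinstance(motif, str):
        motif = MotifPattern(motif)
    gene_ids, positions = [], []
    for entry in library:
        gene_ids.append(entry.gene_id)
        positions.append(scan_sequence(entry.sequence, motif, strand_mode))
    return ScanResult(motif=motif, gene_ids=gene_ids, positions=positions)


@dataclass
class PrevalenceSummary:
    n_with_hit: int
    n_total: int
    mean_hits_per_sequence: float


def prevalence_summary(scan: ScanResult) -> PrevalenceSummary:
    """How widespread the motif is: sequences with >=1 hit and mean hits."""
    if not scan.gene_ids:
        raise ValueError("empty scan result")
    counts = scan.counts
    return PrevalenceSummary(
        n_with_hit=int((counts >= 1).sum()),
        n_total=len(counts),
        mean_hits_per_sequence=float(counts.mean()),
    )


def expected_hits(
    motif: MotifPattern | str,
    seq_length: int,
    base_freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    strand_mode: str = "given",
) -> float:
    """Chance expectation of overlapping hits in an i.i.d. sequence.

    ``base_freqs`` are (pA, pC, pG, pT) and must sum to 1.
    """
    if isinstance(motif, str):
        motif = MotifPattern(motif)
    if strand_mode not in ("given", "both"):
        raise ValueError("strand_mode must be 'given' or 'both'")
    freqs = dict(zip("ACGT", base_freqs))
    if abs(sum(freqs.values()) - 1.0) > 1e-9:
        raise ValueError("base_freqs must sum to 1")
    n_win = seq_length - len(motif) + 1
    if n_win <= 0:
        return 0.0
    p_match = 1.0
    for allowed in motif.position_sets:
        p_match *= sum(freqs[b] for b in allowed)
    expectation = n_win * p_match
    if strand_mode == "both":
        expectation *= 2.0
    return expectation


# ---------------------------------------------------------------------------
# promoter extraction from genome + annotation
# ---------------------------------------------------------------------------

def extract_promoters(
    genome_fasta, annotation_gff3, length: int = 2000
) -> PromoterLibrary:
    """Extract the upstream region of every gene model's start codon.

    For a + strand gene whose leftmost CDS starts at 1-based position p the
    promoter is the genomic interval [max(1, p-length), p-1]; for a - strand
    gene with rightmost CDS end e it is the reverse complement of
    [e+1, min(contig_end, e+length)].  Intervals are clipped at contig
    boundaries, so extracted sequences may be shorter than requested.  Gene
    models without CDS features are skipped with a logged warning.
    """
    import gffutils
    from pyfaidx import Fasta

    fasta = Fasta(str(genome_fasta), sequence_always_upper=True)
    db = gffutils.create_db(
        str(annotation_gff3),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    entries: list[PromoterEntry] = []
    for gene in db.features_of_type("gene"):
        cds = list(db.children(gene, featuretype="CDS"))
        if not cds:
            logger.warning("gene %s has no CDS feature; skipped", gene.id)
            continue
        if gene.seqid not in fasta:
            raise ValueError(f"contig {gene.seqid!r} absent from FASTA")
        contig_len = len(fasta[gene.seqid])
        if gene.strand == "-":
            anchor = max(c.end for c in cds)  # start codon is at the CDS 3' end
            start = anchor + 1
            end = min(contig_len, anchor + length)
            if start > end:
                seq = ""
            else:
                seq = reverse_complement(fasta[gene.seqid][start - 1:end].seq)
        else:
            anchor = min(c.start for c in cds)
            start = max(1, anchor - length)
            end = anchor - 1
            seq = "" if start > end else fasta[gene.seqid][start - 1:end].seq.upper()
        entries.append(
            PromoterEntry(
                gene_id=gene.id,
                sequence=seq,
                seqid=gene.seqid,
                start=start,
                end=end,
                strand=gene.strand or "+",
            )
        )
    return PromoterLibrary(entries)
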
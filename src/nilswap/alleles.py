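"""Allele sequence analyses: CDS translation, frameshift reconstruction,
and protein difference counting.

The motivating case is a C2H2 zinc-finger transcription factor whose
loss-of-function allele carries a single-nucleotide deletion; the shifted
reading frame runs past the native stop codon into the 3' UTR, producing a
longer aberrant protein (465 -> 477 residues in the studied locus).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

logger = logging.getLogger(__name__)

_CODON_TABLE = standard_dna_table.forward_table
_STOP_CODONS = set(standard_dna_table.stop_codons)


def _clean(seq: str) -> str:
    seq = "".join(seq.split()).upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid nucleotide characters {sorted(bad)}")
    return seq


def _translate_frame(seq: str, to_first_stop: bool) -> tuple[str, bool]:
    """Translate codons from position 0; returns (protein, saw_stop)."""
    residues = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i:i + 3]
        if codon in _STOP_CODONS:
            return "".join(residues), True
        residues.append(_CODON_TABLE.get(codon, "X"))
    return "".join(residues), False


def translate_cds(seq: str, strict: bool = True) -> str:
    """Translate a CDS with the standard genetic code, up to (and excluding)
    the first stop codon.

    In strict mode the length must be divisible by 3 and a stop occurring
    before the final codon raises; a non-ATG start is only warned about.
    """
    seq = _clean(seq)
    if len(seq) % 3 != 0:
        if strict:
            raise ValueError(f"CDS length {len(seq)} is not divisible by 3")
        logger.warning("CDS length %d not divisible by 3; trailing bases ignored", len(seq))
    if not seq.startswith("ATG"):
        logger.warning("CDS does not start with ATG")
    protein, saw_stop = _translate_frame(seq, to_first_stop=True)
    if strict and saw_stop and (len(protein) + 1) * 3 != len(seq):
        raise ValueError(
            f"internal stop codon after residue {len(protein)} "
            f"(CDS encodes {len(seq) // 3 - 1} residues)"
        )
    return protein


def apply_frameshift(cds: str, deletion_pos: int, downstream: str) -> str:
    """Reconstruct the protein produced after a 1-bp deletion.

    ``deletion_pos`` is the 1-based coordinate of the deleted base within
    the CDS; ``downstream`` is the genomic sequence 3' of the native stop
    (the 3' UTR) that translation reads through into.  Translation proceeds
    from the start codon to the first stop in the shifted frame; absence of
    a stop raises rather than truncating silently.
    """
    cds = _clean(cds)
    downstream = _clean(downstream)
    if not 1 <= deletion_pos <= len(cds):
        raise ValueError(
            f"deletion position {deletion_pos} outside CDS of length {len(cds)}"
        )
    shifted = cds[: deletion_pos - 1] + cds[deletion_pos:] + downstream
    protein, saw_stop = _translate_frame(shifted, to_first_stop=True)
    if not saw_stop:
        raise ValueError("no in-frame stop codon found downstream of the deletion")
    return protein


@dataclass
class ProteinDiff:
    n_substitutions: int
    n_indel_events: int  # contiguous gap runs across both alignment rows
    alignment_score: float


def diff_proteins(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> ProteinDiff:
    """Count substitutions and indel events between two proteins.

    A global affine-gap alignment is computed (default BLOSUM62, gap
    open/extend 10/0.5); substitutions are aligned mismatch columns and each
    maximal run of gap columns in either row counts as one indel event.
    """
    if not a or not b:
        raise ValueError("empty protein sequence")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    alignment = aligner.align(a.upper(), b.upper())[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])

    n_sub = sum(
        1 for x, y in zip(row_a, row_b) if x != "-" and y != "-" and x != y
    )
    n_indels = 0
    in_gap = False
    for x, y in zip(row_a, row_b):
        gap = (x == "-") or (y == "-")
        if gap and not in_gap:
            n_indels += 1
        in_gap = gap
    return ProteinDiff(
        n_substitutions=n_sub,
        n_indel_events=n_indels,
        alignment_score=float(alignment.score),
    )
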
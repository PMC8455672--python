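"""Pairwise alignment helpers shared by the filtering and homology stages.

Alignments are computed with Biopython's PairwiseAligner (affine gaps);
identity is then counted as identical aligned columns under the denominator
convention each caller specifies (alignment length vs shorter sequence).
edlib provides a fast unit-cost global identity used where screening speed
matters; property tests pin its agreement with the DP path.
"""

from __future__ import annotations

from functools import lru_cache

import edlib
from Bio import Align

__all__ = [
    "global_alignment_identity",
    "identity_over_shorter",
    "local_containment",
    "kmer_set",
    "shared_kmers",
    "edlib_identity_over_shorter",
]


@lru_cache(maxsize=4)
def _aligner(mode: str, protein: bool) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    if protein:
        aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -2
    elif mode == "local":
        # blastn-like, for local containment scans
        aligner.match_score = 2
        aligner.mismatch_score = -3
        aligner.open_gap_score = -5
        aligner.extend_gap_score = -2
    else:
        # stiff gaps: keeps counted identity close to the per-site identity
        # of substitution-diverged sequences instead of inflating it by
        # recruiting gap columns
        aligner.match_score = 1
        aligner.mismatch_score = -2
        aligner.open_gap_score = -8
        aligner.extend_gap_score = -4
    return aligner


def _is_protein(seq: str) -> bool:
    return any(ch not in "ACGTN" for ch in seq.upper())


def _counts(alignment) -> tuple[int, int]:
    """(identical columns, total columns) of a pairwise alignment."""
    c = alignment.counts()
    return c.identities, alignment.length


def global_alignment_identity(a: str, b: str,
                              protein: bool | None = None) -> float:
    """Percent identity from a global affine alignment, identical columns
    over alignment length (gap columns included)."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if protein is None:
        protein = _is_protein(a) or _is_protein(b)
    if _is_protein(a) != _is_protein(b):
        raise ValueError("alphabet mismatch between sequences")
    aln = _aligner("global", protein).align(a.upper(), b.upper())[0]
    ident, cols = _counts(aln)
    return 100.0 * ident / cols


def identity_over_shorter(a: str, b: str,
                          protein: bool | None = None) -> float:
    """Identity fraction with the shorter sequence as denominator (the
    CD-HIT convention), from a global affine alignment."""
    if protein is None:
        protein = _is_protein(a) or _is_protein(b)
    aln = _aligner("global", protein).align(a.upper(), b.upper())[0]
    ident, _ = _counts(aln)
    return ident / min(len(a), len(b))


def edlib_identity_over_shorter(a: str, b: str) -> float:
    """Fast unit-cost variant of :func:`identity_over_shorter` (nucleotide
    screening path)."""
    res = edlib.align(a.upper(), b.upper(), mode="NW", task="path")
    matches = 0
    for n, op in _cigar_ops(res["cigar"]):
        if op == "=":
            matches += n
    return matches / min(len(a), len(b))


def _cigar_ops(cigar: str):
    n = ""
    for ch in cigar:
        if ch.isdigit():
            n += ch
        else:
            yield int(n), ch
            n = ""


def local_containment(short: str, long: str) -> tuple[float, float]:
    """Best local alignment of ``short`` against ``long``.

    Returns ``(coverage, identity)``: coverage is the fraction of ``short``
    spanned by the aligned region, identity is identical columns over
    aligned columns of the local alignment.
    """
    aligner = _aligner("local", False)
    alns = aligner.align(short.upper(), long.upper())
    if len(alns) == 0 or alns.score <= 0:
        return 0.0, 0.0
    aln = alns[0]
    ident, cols = _counts(aln)
    target_blocks = aln.aligned[0]
    covered = sum(int(e - s) for s, e in target_blocks)
    return covered / len(short), (ident / cols if cols else 0.0)


def kmer_set(seq: str, k: int) -> frozenset[str]:
    s = seq.upper()
    return frozenset(s[i:i + k] for i in range(len(s) - k + 1))


def shared_kmers(a: str, b: str, k: int) -> int:
    return len(kmer_set(a, k) & kmer_set(b, k))
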
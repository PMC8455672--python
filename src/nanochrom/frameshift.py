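"""Programmed +1 ribosomal frameshift candidate detection.

Euplotid ciliates shift the ribosome one nucleotide forward at specific
motifs consisting of a sense codon immediately followed by an in-frame stop
(TAA/TAG), producing a protein longer than the in-frame reading.  Gene
predictions trained without frameshifts therefore terminate prematurely at
the motif's stop: a gene whose CDS ends in one of the twelve known motifs,
whose predicted protein is shorter than its best database hit, and whose
alignment covers most of the prediction is a frameshift candidate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from nanochrom.seqio import HSP, GeneModel

__all__ = [
    "FRAMESHIFT_MOTIFS",
    "FrameshiftCandidate",
    "terminal_motif",
    "select_candidates",
    "frameshift_fraction",
    "expression_comparison",
]

# The twelve sense-codon+stop hexamers, ranked by abundance in E. crassus.
FRAMESHIFT_MOTIFS: tuple[str, ...] = (
    "AAATAA", "AATTAA", "ATTTAA", "TTATAA", "AACTAA", "ATATAA",
    "GAGTAA", "AAATAG", "GTATAA", "TTATAG", "ATATAG", "TCCTAA",
)

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class FrameshiftCandidate:
    gene_id: str
    motif: str | None
    predicted_protein_len: int
    top_hit_len: int | None
    blast_coverage: float | None
    passes: bool
    evaluable: bool = True


def terminal_motif(cds_sequence: str) -> str | None:
    """Return the terminal hexamer (final sense codon + stop codon) iff it
    is one of the twelve frameshift motifs; None otherwise.

    The motif is evaluated at the annotated CDS terminus only: internal
    occurrences are deliberately not scanned.
    """
    cds = cds_sequence.upper()
    if len(cds) < 6 or len(cds) % 3:
        return None
    if cds[-3:] not in _STOPS:
        warnings.warn("CDS does not end in a stop codon")
        return None
    hexamer = cds[-6:]
    return hexamer if hexamer in FRAMESHIFT_MOTIFS else None


def _top_hit(hsps: Sequence[HSP]) -> HSP:
    """Lowest e-value; ties broken by highest bitscore, then input order."""
    best = hsps[0]
    for h in hsps[1:]:
        if (h.evalue, -h.bitscore) < (best.evalue, -best.bitscore):
            best = h
    return best


def select_candidates(genes: Sequence[GeneModel],
                      cds_seqs: Mapping[str, str],
                      hsps: Sequence[HSP],
                      subject_lengths: Mapping[str, int] | None = None,
                      coverage_min: float = 0.8) -> list[FrameshiftCandidate]:
    """Apply the three-part candidate criterion gene by gene.

    A gene passes iff its CDS carries a terminal frameshift motif, its
    predicted protein is shorter than the top hit's subject protein length,
    and the top HSP covers more than ``coverage_min`` of the query.  Genes
    whose CDS carries a motif but which have no HSP are reported as
    motif-bearing-but-unevaluable (``evaluable=False``, excluded from the
    passing set).

    ``subject_lengths`` maps subject ids to their full protein lengths; when
    absent, the maximum observed subject end per subject is used as a lower
    bound.
    """
    gene_ids = {g.id for g in genes}
    by_gene: dict[str, list[HSP]] = {}
    for h in hsps:
        if h.query_id not in gene_ids:
            raise KeyError(f"HSP references unknown gene id {h.query_id!r}")
        by_gene.setdefault(h.query_id, []).append(h)
    if subject_lengths is None:
        subject_lengths = {}
        for h in hsps:
            prev = subject_lengths.get(h.subject_id, 0)
            subject_lengths[h.subject_id] = max(prev, h.s_end)
    out: list[FrameshiftCandidate] = []
    for g in genes:
        cds = cds_seqs[g.id]
        motif = terminal_motif(cds)
        prot_len = g.protein_length
        if prot_len is None:
            prot_len = len(cds) // 3 - 1
        gene_hsps = by_gene.get(g.id)
        if gene_hsps is None:
            out.append(FrameshiftCandidate(g.id, motif, prot_len, None, None,
                                           passes=False, evaluable=False))
            continue
        top = _top_hit(gene_hsps)
        hit_len = subject_lengths[top.subject_id]
        coverage = top.query_span / prot_len if prot_len else 0.0
        passes = (motif is not None and prot_len < hit_len
                  and coverage > coverage_min)
        out.append(FrameshiftCandidate(g.id, motif, prot_len, hit_len,
                                       coverage, passes))
    return out


def frameshift_fraction(candidates: Iterable[FrameshiftCandidate],
                        total_genes: int) -> float:
    """Percent of genes passing the candidate criterion: 100 * n_pass / total."""
    if total_genes <= 0:
        raise ValueError("total_genes must be positive")
    n_pass = sum(1 for c in candidates if c.passes)
    return 100.0 * n_pass / total_genes


def expression_comparison(expr: Mapping[str, float],
                          candidate_ids: set[str],
                          variant: str = "student",
                          log_transform: bool = False,
                          ) -> tuple[float, float, int, int]:
    """Two-sided two-sample t-test of candidate vs non-candidate abundances.

    ``variant`` selects Student's pooled-variance test (default) or Welch's.
    Returns (t, p, n_candidates, n_others).  Abundances are used
    untransformed unless ``log_transform`` applies log2(x+1).
    """
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    a = np.array([v for g, v in expr.items() if g in candidate_ids], float)
    b = np.array([v for g, v in expr.items() if g not in candidate_ids], float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 members")
    if log_transform:
        a, b = np.log2(a + 1), np.log2(b + 1)
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("zero variance in both groups (degenerate input)")
    t, p = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(t), float(p), len(a), len(b)
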
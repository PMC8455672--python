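"""Assembly clean-up: GC/coverage contaminant removal, redundant "chaff"
contig removal, and foreign-sequence flagging against a contaminant genome.

Euplotid MAC assemblies sit at low GC (~31-37%); bacterial associates of the
ciliate consortium sit higher, so high-GC/low-coverage contigs are treated
as contamination.  Short contigs almost entirely contained in longer ones
("chaff") are assembly redundancy, and an optional screen flags contigs
nearly identical to a user-supplied contaminant genome (e.g. the food alga).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from nanochrom._align import (identity_over_shorter, kmer_set,
                              local_containment)
from nanochrom.seqio import Contig

__all__ = ["FilterReport", "filter_gc_coverage", "remove_chaff",
           "flag_foreign"]


@dataclass
class FilterReport:
    """Partition of input contig ids into kept and removed (with reasons)."""

    kept: list[str]
    removed: list[tuple[str, str, str]]  # (contig_id, reason, evidence)

    @property
    def removed_ids(self) -> set[str]:
        return {cid for cid, _, _ in self.removed}

    def apply(self, contigs: list[Contig]) -> list[Contig]:
        removed = self.removed_ids
        return [c for c in contigs if c.id not in removed]


def filter_gc_coverage(contigs: list[Contig],
                       gc_threshold: float = 45.0,
                       cov_threshold: float = 10.0,
                       mode: str = "all") -> FilterReport:
    """Remove contigs by the GC/coverage rule.

    Default mode ``all`` removes contigs with GC percent > ``gc_threshold``
    AND coverage < ``cov_threshold`` (the conjunctive reading); ``any``
    removes on either condition.  Contigs without coverage are kept and
    flagged in the evidence of the report.
    """
    if mode not in ("all", "any"):
        raise ValueError(f"mode must be 'all' or 'any', got {mode!r}")
    kept, removed = [], []
    for c in contigs:
        high_gc = c.gc_percent > gc_threshold
        if c.coverage is None:
            kept.append(c.id)
            continue
        low_cov = c.coverage < cov_threshold
        hit = (high_gc and low_cov) if mode == "all" else (high_gc or low_cov)
        if hit:
            removed.append((c.id, "gc_coverage",
                            f"gc={c.gc_percent:.2f}%,cov={c.coverage:g}"))
        else:
            kept.append(c.id)
    return FilterReport(kept=kept, removed=removed)


def remove_chaff(contigs: list[Contig],
                 min_len: int = 500,
                 cov_frac: float = 0.8,
                 min_identity: float = 0.9,
                 k: int = 11,
                 min_shared_kmers: int = 3) -> FilterReport:
    """Remove short redundant contigs.

    A contig shorter than ``min_len`` is removed when some other contig in
    the full input set contains a local alignment covering at least
    ``cov_frac`` of its length at ``min_identity`` identity or better
    (identical columns / aligned columns).  Candidate pairs are screened by
    shared k-mers before alignment; the screen is an efficiency device only.
    Evaluation is single-pass against the full input set.
    """
    if not (0 < cov_frac <= 1 and 0 < min_identity <= 1):
        raise ValueError("cov_frac and min_identity must be in (0,1]")
    kept, removed = [], []
    long_kmers = [(c, kmer_set(c.sequence, k)) for c in contigs]
    for c in contigs:
        if c.length >= min_len:
            kept.append(c.id)
            continue
        ck = kmer_set(c.sequence, k)
        hit = None
        for other, ok_set in long_kmers:
            if other.id == c.id or other.length <= c.length:
                continue
            if len(ck & ok_set) < min_shared_kmers:
                continue
            coverage, identity = local_containment(c.sequence, other.sequence)
            if coverage >= cov_frac and identity >= min_identity:
                hit = (other.id, coverage, identity)
                break
        if hit:
            removed.append((c.id, "chaff",
                            f"contained_in={hit[0]},coverage={hit[1]:.3f},"
                            f"identity={hit[2]:.3f}"))
        else:
            kept.append(c.id)
    return FilterReport(kept=kept, removed=removed)


def flag_foreign(contigs: list[Contig],
                 contaminant_seqs: list[Contig],
                 min_identity: float = 0.95,
                 k: int = 11,
                 min_shared_kmers: int = 3) -> FilterReport:
    """Flag contigs matching a contaminant genome.

    A contig is flagged when its best match in the contaminant set reaches
    ``min_identity`` identity, with identical columns counted over the
    shorter of the two sequences (the cd-hit-2d convention).
    """
    if not contaminant_seqs:
        raise ValueError("contaminant set is empty")
    kept, removed = [], []
    cont_kmers = [(s, kmer_set(s.sequence, k)) for s in contaminant_seqs]
    for c in contigs:
        ck = kmer_set(c.sequence, k)
        best = None
        for cont, kset in cont_kmers:
            if len(ck & kset) < min_shared_kmers:
                continue
            ident = identity_over_shorter(c.sequence, cont.sequence,
                                          protein=False)
            if best is None or ident > best[1]:
                best = (cont.id, ident)
        if best is not None and best[1] >= min_identity:
            removed.append((c.id, "foreign",
                            f"match={best[0]},identity={best[1]:.3f}"))
        else:
            kept.append(c.id)
    return FilterReport(kept=kept, removed=removed)
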
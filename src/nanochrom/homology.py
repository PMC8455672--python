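"""Allele/paralog identity distributions, greedy clustering and
completeness scoring.

In all-vs-all best-nonself identity distributions over a MAC assembly,
heterozygous alleles show up as a peak above 90% identity and diverged
paralogous families as a lower peak around 40%.  Greedy incremental
clustering (CD-HIT style: length-sorted, identity over the shorter
sequence) at 0.95 merges alleles and at 0.40 gathers protein families.
Completeness is scored by presence of core eukaryotic gene (CEG) homologs
under e-value and reference-coverage criteria.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from nanochrom._align import (edlib_identity_over_shorter,
                              global_alignment_identity,
                              identity_over_shorter, kmer_set)
from nanochrom.seqio import HSP

__all__ = [
    "IdentityPair",
    "Cluster",
    "CompletenessReport",
    "pairwise_identity",
    "best_nonself_pairs",
    "greedy_cluster",
    "completeness",
]


@dataclass
class IdentityPair:
    a_id: str
    b_id: str
    identity: float | None  # percent, None when no screening hit at all
    method: str = "global"


@dataclass
class Cluster:
    representative_id: str
    member_ids: list[str]
    threshold: float


@dataclass
class CompletenessReport:
    per_protein: dict[str, tuple[float | None, float | None, bool]]
    percent_present: float


def pairwise_identity(a: str, b: str, mode: str = "global") -> float:
    """Percent identity of a global affine alignment: identical columns over
    alignment length, gap columns included."""
    if mode != "global":
        raise ValueError(f"unsupported mode {mode!r}")
    return global_alignment_identity(a, b)


def _screen_score(kmers_a: frozenset, kmers_b: frozenset) -> int:
    return len(kmers_a & kmers_b)


def best_nonself_pairs(seqs: Mapping[str, str] | Sequence[tuple[str, str]],
                       k: int | None = None,
                       screen_floor: int = 1) -> list[IdentityPair]:
    """Best non-self partner per sequence, with its global identity.

    The partner is chosen by shared-k-mer screening score (the BLAST best-hit
    stand-in); ties go to the longest partner, then lexicographic id.  The
    reported identity is then :func:`pairwise_identity` on the pair.
    Sequences with no screening hit at or above ``screen_floor`` shared
    k-mers are reported with ``identity=None``.
    """
    items = list(seqs.items()) if isinstance(seqs, Mapping) else list(seqs)
    if len(items) < 2:
        raise ValueError("need at least 2 sequences")
    if k is None:
        protein = any(ch not in "ACGTN" for _, s in items for ch in s.upper())
        k = 4 if protein else 8
    kmers = {sid: kmer_set(s, k) for sid, s in items}
    lengths = {sid: len(s) for sid, s in items}
    by_id = dict(items)
    out: list[IdentityPair] = []
    for sid, s in items:
        best_id, best_key = None, None
        for oid, _ in items:
            if oid == sid:
                continue
            score = _screen_score(kmers[sid], kmers[oid])
            if score < screen_floor:
                continue
            key = (-score, -lengths[oid], oid)
            if best_key is None or key < best_key:
                best_key, best_id = key, oid
        if best_id is None:
            out.append(IdentityPair(sid, "", None))
        else:
            out.append(IdentityPair(
                sid, best_id, pairwise_identity(s, by_id[best_id])))
    return out


def greedy_cluster(seqs: Mapping[str, str] | Sequence[tuple[str, str]],
                   threshold: float,
                   identity_def: str = "shorter-seq",
                   fast: bool = True) -> list[Cluster]:
    """CD-HIT-style greedy incremental clustering.

    Sequences are sorted by length descending (ties by id); each joins the
    first existing cluster whose representative it matches at or above
    ``threshold``, with identity counted as identical aligned columns over
    the shorter sequence's length; otherwise it founds a new cluster.
    Deterministic regardless of input order.

    With ``fast`` the unit-cost edit path (edlib) is used as a prefilter:
    it can only over-count matches relative to the affine aligner (gap
    scatter is free under unit costs), so representatives it scores below
    ``threshold`` are skipped and the affine aligner decides the rest.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0,1]")
    if identity_def != "shorter-seq":
        raise ValueError(f"unsupported identity_def {identity_def!r}")

    items = list(seqs.items()) if isinstance(seqs, Mapping) else list(seqs)
    items.sort(key=lambda kv: (-len(kv[1]), kv[0]))
    protein = any(ch not in "ACGTN" for _, s in items for ch in s.upper())
    k = 5 if protein else 11

    def ident(a: str, b: str, ka: frozenset, kb: frozenset) -> float:
        if fast:
            # sequences matching at >= threshold over the shorter length
            # retain a large fraction of exact k-mers when threshold is
            # high; unrelated pairs share almost none
            if threshold >= 0.75:
                lmin = min(len(a), len(b))
                if len(ka & kb) < 0.05 * max(lmin - k + 1, 1):
                    return 0.0
            if edlib_identity_over_shorter(a, b) < threshold:
                return 0.0
        return identity_over_shorter(a, b)

    clusters: list[Cluster] = []
    reps: list[tuple[str, frozenset]] = []
    for sid, s in items:
        placed = False
        sk = kmer_set(s, k)
        for cluster, (rep_seq, rep_k) in zip(clusters, reps):
            if ident(s, rep_seq, sk, rep_k) >= threshold:
                cluster.member_ids.append(sid)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(representative_id=sid, member_ids=[sid],
                                    threshold=threshold))
            reps.append((s, sk))
    return clusters


def completeness(hsps: Sequence[HSP],
                 reference_lengths: Mapping[str, int],
                 evalue_max: float = 1e-10,
                 coverage_min: float = 0.7) -> CompletenessReport:
    """Score presence of each reference (CEG-style) protein.

    Per reference protein, coverage of a hit is the matched reference span
    over the reference length; the protein is present iff its best (lowest)
    e-value is below ``evalue_max`` and its best (highest) coverage exceeds
    ``coverage_min``.
    """
    best_e: dict[str, float] = {}
    best_cov: dict[str, float] = {}
    for h in hsps:
        if h.subject_id not in reference_lengths:
            raise KeyError(f"HSP subject {h.subject_id!r} not in reference")
        cov = h.subject_span / reference_lengths[h.subject_id]
        best_e[h.subject_id] = min(h.evalue,
                                   best_e.get(h.subject_id, float("inf")))
        best_cov[h.subject_id] = max(cov, best_cov.get(h.subject_id, 0.0))
    per: dict[str, tuple[float | None, float | None, bool]] = {}
    n_present = 0
    for rid in reference_lengths:
        e = best_e.get(rid)
        c = best_cov.get(rid)
        present = e is not None and e < evalue_max and c > coverage_min
        n_present += present
        per[rid] = (e, c, present)
    pct = 100.0 * n_present / len(reference_lengths) if reference_lengths else 0.0
    return CompletenessReport(per_protein=per, percent_present=pct)
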
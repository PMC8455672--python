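"""Stop-codon readthrough analysis over translated-alignment windows.

In conserved translated alignments of reference proteins against the
nanochromosome assembly, the amino acid aligned to an in-frame subject stop
codon reveals how that codon is likely decoded: TGA aligns predominantly to
cysteine and TAA/TAG to glutamine in euplotids, with CAA/CAG (canonical
glutamine codons) serving as the positive control.  Windows are only
counted when the alignment around the focal codon is confidently homologous
(low e-value, gap-free flanks, flank identity above a floor), which
excludes frameshift sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from nanochrom.seqio import HSP

__all__ = [
    "FOCAL_CODONS",
    "CODON_CLASSES",
    "CodonAlignmentWindow",
    "AAFrequencyTable",
    "extract_codon_windows",
    "aa_frequency_table",
]

FOCAL_CODONS = ("TGA", "TAA", "TAG", "CAA", "CAG")
CODON_CLASSES: dict[str, str] = {
    "TGA": "TGA", "TAA": "TAA/TAG", "TAG": "TAA/TAG",
    "CAA": "CAA/CAG", "CAG": "CAA/CAG",
}


@dataclass
class CodonAlignmentWindow:
    query_id: str
    subject_id: str
    column: int            # alignment column index of the focal codon
    subject_codon: str
    aligned_aa: str
    flank_identity: float  # over the 20 flanking columns (focal excluded)
    accepted: bool
    reject_reason: str | None = None


@dataclass
class AAFrequencyTable:
    counts: dict[str, dict[str, int]]        # class -> aa -> count
    frequencies: dict[str, dict[str, float]]
    n: dict[str, int]                        # accepted windows per class


def _flank_stats(q: str, s: str, col: int, flank: int,
                 per_side: bool) -> tuple[bool, float]:
    """(flanks fit and are gap-free, identity over flanking columns)."""
    lo, hi = col - flank, col + flank
    if lo < 0 or hi >= len(q):
        return False, 0.0
    left = range(lo, col)
    right = range(col + 1, hi + 1)
    for i in [*left, *right]:
        if q[i] == "-" or s[i] == "-":
            return False, 0.0
    if per_side:
        ids = [sum(q[i] == s[i] for i in side) / flank
               for side in (left, right)]
        return True, min(ids)
    matches = sum(q[i] == s[i] for i in [*left, *right])
    return True, matches / (2 * flank)


def extract_codon_windows(hsps: Sequence[HSP],
                          evalue_max: float = 1e-20,
                          flank: int = 10,
                          identity_min: float = 0.4,
                          per_side: bool = False,
                          ) -> list[CodonAlignmentWindow]:
    """Emit one window per non-gap subject column whose codon is a focal
    codon (TGA, TAA, TAG, CAA, CAG).

    A window is accepted iff the HSP e-value is below ``evalue_max``, the
    ``flank`` columns either side exist within the alignment and contain no
    gaps in either sequence, the flanking amino-acid identity reaches
    ``identity_min`` (jointly over both flanks by default, per side with
    ``per_side``), and the query character at the focal column is not a
    gap.  The focal column is excluded from the identity computation.
    """
    windows: list[CodonAlignmentWindow] = []
    for h in hsps:
        if h.subject_codons is None:
            warnings.warn(f"HSP {h.query_id}/{h.subject_id} lacks subject "
                          "codons; skipped")
            continue
        q, s = h.q_aln, h.s_aln
        codon_iter = iter(h.subject_codons)
        for col in range(len(s)):
            if s[col] == "-":
                continue
            codon = next(codon_iter).upper()
            if codon not in FOCAL_CODONS:
                continue
            fits, ident = _flank_stats(q, s, col, flank, per_side)
            reason = None
            if h.evalue >= evalue_max:
                reason = "evalue"
            elif not fits:
                reason = "flank"
            elif q[col] == "-":
                reason = "query_gap"
            elif ident < identity_min:
                reason = "identity"
            windows.append(CodonAlignmentWindow(
                query_id=h.query_id, subject_id=h.subject_id, column=col,
                subject_codon=codon, aligned_aa=q[col],
                flank_identity=ident, accepted=reason is None,
                reject_reason=reason))
    return windows


def aa_frequency_table(windows: Iterable[CodonAlignmentWindow],
                       ) -> AAFrequencyTable:
    """Counts and relative frequencies of aligned amino acids over accepted
    windows, grouped into the three codon classes (TGA, TAA/TAG, CAA/CAG).
    """
    counts: dict[str, dict[str, int]] = {c: {} for c in
                                         ("TGA", "TAA/TAG", "CAA/CAG")}
    for w in windows:
        if not w.accepted:
            continue
        cls = CODON_CLASSES[w.subject_codon]
        counts[cls][w.aligned_aa] = counts[cls].get(w.aligned_aa, 0) + 1
    n = {cls: sum(d.values()) for cls, d in counts.items()}
    freqs = {cls: ({aa: c / n[cls] for aa, c in d.items()} if n[cls] else {})
             for cls, d in counts.items()}
    return AAFrequencyTable(counts=counts, frequencies=freqs, n=n)
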
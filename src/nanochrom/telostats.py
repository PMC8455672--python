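"""Telomere detection, contig classification and assembly statistics.

Euplotid macronuclear nanochromosomes are capped by short tandem telomeric
repeats, 5'-C4A4-3' at the 5' end and its reverse complement G4T4 at the
3' end.  A contig assembled end-to-end carries both caps ("2-telomere"); a
partial assembly carries one or none.  The repeat unit is a parameter
because it varies across ciliate lineages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from nanochrom.seqio import Contig

__all__ = [
    "TelomereEnd",
    "TelomereAnnotation",
    "AssemblyStats",
    "DEFAULT_REPEAT_UNIT",
    "detect_telomeres",
    "trim_telomeres",
    "assembly_stats",
    "gc_histogram",
]

DEFAULT_REPEAT_UNIT = "CCCCAAAA"


@dataclass
class TelomereEnd:
    present: bool
    repeat_copies: float = 0.0
    offset: int = 0
    run_start: int = 0  # 0-based start of the telomeric run on the contig
    run_end: int = 0    # 0-based end (exclusive)


@dataclass
class TelomereAnnotation:
    contig_id: str
    five_prime: TelomereEnd
    three_prime: TelomereEnd

    @property
    def telomere_class(self) -> int:
        return int(self.five_prime.present) + int(self.three_prime.present)


@dataclass
class AssemblyStats:
    n_contigs: int
    total_bp: int
    gc_percent: float
    n50: int
    mean_len: float
    max_len: int
    n_telomeres: int
    contigs_per_class: dict[int, int]
    mean_len_per_class: dict[int, float]
    pct_with_telomere: float


def _leading_run(seq: str, unit: str) -> tuple[float, int]:
    """Copies (fractional, partial terminal unit pro rata) of ``unit``
    tandem-repeated from the start of ``seq``, and the run length in bases."""
    k = len(unit)
    n = 0
    while seq[n * k:(n + 1) * k] == unit:
        n += 1
    # partial terminal copy
    tail = seq[n * k:n * k + k]
    partial = 0
    for a, b in zip(tail, unit):
        if a != b:
            break
        partial += 1
    return n + partial / k, n * k + partial


def _scan_five_prime(seq: str, unit: str, min_copies: float,
                     max_offset: int) -> TelomereEnd:
    best: TelomereEnd | None = None
    for off in range(0, max_offset + 1):
        copies, run_len = _leading_run(seq[off:], unit)
        if copies >= min_copies:
            end = TelomereEnd(True, copies, off, off, off + run_len)
            if best is None or copies > best.repeat_copies:
                best = end
            # earliest qualifying offset with the longest run wins
            break
    return best if best is not None else TelomereEnd(False)


def detect_telomeres(contig: Contig,
                     repeat_unit: str = DEFAULT_REPEAT_UNIT,
                     min_copies: float = 2.0,
                     max_offset: int = 5) -> TelomereAnnotation:
    """Detect telomeric repeat runs at both contig ends.

    The 5' end is scanned for tandem copies of ``repeat_unit`` beginning
    within the first ``max_offset`` bases; the 3' end for copies of its
    reverse complement ending within the last ``max_offset`` bases.
    Detection is strand-symmetric: running on the reverse complement swaps
    the two ends.  Matching is exact; partial terminal units count pro rata.
    """
    if not repeat_unit:
        raise ValueError("repeat_unit must be non-empty")
    seq = contig.sequence.upper()
    unit = repeat_unit.upper()
    five = _scan_five_prime(seq, unit, min_copies, max_offset)
    # 3' end of seq == 5' end of the reverse complement scanned with the
    # same (5'-form) unit; map coordinates back.
    rc = str(Seq(seq).reverse_complement())
    three_rc = _scan_five_prime(rc, unit, min_copies, max_offset)
    if three_rc.present:
        n = len(seq)
        three = TelomereEnd(True, three_rc.repeat_copies, three_rc.offset,
                            run_start=n - three_rc.run_end,
                            run_end=n - three_rc.run_start)
    else:
        three = TelomereEnd(False)
    return TelomereAnnotation(contig.id, five, three)


def trim_telomeres(contig: Contig,
                   annotation: TelomereAnnotation) -> Contig:
    """Return the subsequence between the detected telomeric runs.

    Identity for class-0 contigs; a telomere-only contig (runs overlapping)
    yields an empty-sequence contig with a warning.
    """
    if annotation.contig_id != contig.id:
        raise ValueError("annotation does not belong to this contig")
    start = annotation.five_prime.run_end if annotation.five_prime.present else 0
    end = (annotation.three_prime.run_start
           if annotation.three_prime.present else len(contig.sequence))
    if start >= end:
        warnings.warn(f"{contig.id}: telomeric runs overlap; empty insert")
        return Contig(id=contig.id, sequence="", coverage=contig.coverage)
    return Contig(id=contig.id, sequence=contig.sequence[start:end],
                  coverage=contig.coverage)


def compute_n50(lengths: list[int] | np.ndarray) -> int:
    """Largest L such that contigs of length >= L sum to >= total/2."""
    arr = np.sort(np.asarray(lengths))[::-1]
    half = arr.sum() / 2.0
    csum = np.cumsum(arr)
    idx = int(np.searchsorted(csum, half))
    return int(arr[idx])


def assembly_stats(contigs: list[Contig],
                   annotations: list[TelomereAnnotation]) -> AssemblyStats:
    """Assembly-wide statistics over contigs and their telomere classes.

    GC is computed over full contigs including telomeric runs (the
    assembly-wide convention); N50 by descending cumulative sum.
    """
    if not contigs:
        raise ValueError("empty contig list")
    if len(contigs) != len(annotations):
        raise ValueError("one annotation per contig required")
    lengths = np.array([c.length for c in contigs])
    gc = at = 0
    for c in contigs:
        s = c.sequence
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    classes = np.array([a.telomere_class for a in annotations])
    per_class = {k: int((classes == k).sum()) for k in (2, 1, 0)}
    mean_per_class = {
        k: float(lengths[classes == k].mean()) if per_class[k] else 0.0
        for k in (2, 1, 0)}
    n = len(contigs)
    return AssemblyStats(
        n_contigs=n,
        total_bp=int(lengths.sum()),
        gc_percent=100.0 * gc / (gc + at) if gc + at else 0.0,
        n50=compute_n50(lengths),
        mean_len=float(lengths.mean()),
        max_len=int(lengths.max()),
        n_telomeres=2 * per_class[2] + per_class[1],
        contigs_per_class=per_class,
        mean_len_per_class=mean_per_class,
        pct_with_telomere=100.0 * (per_class[1] + per_class[2]) / n,
    )


def gc_histogram(contigs: list[Contig],
                 bin_width: float = 1.0) -> dict[float, int]:
    """Histogram of per-contig GC percent in half-open bins [lo, lo+width).

    Keys are bin lower edges (multiples of ``bin_width``); only non-empty
    bins are reported.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    hist: dict[float, int] = {}
    for c in contigs:
        lo = np.floor(c.gc_percent / bin_width) * bin_width
        hist[float(lo)] = hist.get(float(lo), 0) + 1
    return dict(sorted(hist.items()))
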
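"""Readers and writers for every external format the pipeline touches.

FASTA assemblies with SPAdes-style headers (``NODE_i_length_L_cov_C``),
GFF3 gene models, the extended tabular HSP dialect (standard outfmt-6-like
columns plus the two aligned strings and an optional per-column subject-codon
field), expression tables, two-column XVG-compatible trajectories and qPCR
Ct tables.

Internal coordinates are 0-based half-open; GFF3 I/O converts from the
1-based inclusive convention at the boundary.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Contig",
    "GeneModel",
    "HSP",
    "CtSet",
    "parse_spades_header",
    "gc_fraction",
    "read_assembly_fasta",
    "write_fasta",
    "read_hsp_table",
    "write_hsp_table",
    "hsps_from_tabular",
    "read_gff3_genes",
    "read_expression_table",
    "write_expression_table",
    "read_trajectory",
    "read_ct_table",
]

_SPADES_RE = re.compile(r"_length_(\d+)_cov_(\d+(?:\.\d+)?)")

HSP_COLUMNS = [
    "query_id", "subject_id", "pct_identity", "evalue", "bitscore",
    "q_start", "q_end", "s_start", "s_end", "frame", "q_aln", "s_aln",
]


def gc_fraction(sequence: str) -> float:
    """G+C over A+C+G+T (N and other ambiguity codes excluded from the
    denominator).  Returns 0.0 for a sequence with no unambiguous base."""
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    denom = gc + at
    return gc / denom if denom else 0.0


@dataclass
class Contig:
    """A contig/nanochromosome with parsed coverage and derived GC/length."""

    id: str
    sequence: str
    coverage: float | None = None
    description: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc_fraction(self) -> float:
        return gc_fraction(self.sequence)

    @property
    def gc_percent(self) -> float:
        return 100.0 * self.gc_fraction


@dataclass
class GeneModel:
    """A predicted gene: ordered CDS segments on a contig.

    ``cds_segments`` are 0-based half-open intervals on the contig, ordered
    5'→3' on the coding strand; their total length is divisible by 3.
    """

    id: str
    contig_id: str
    strand: str
    cds_segments: list[tuple[int, int]]
    protein_length: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        total = sum(e - s for s, e in self.cds_segments)
        if total % 3:
            raise ValueError(
                f"gene {self.id}: CDS length {total} not divisible by 3")

    def cds_sequence(self, contig_seq: str) -> str:
        parts = [contig_seq[s:e] for s, e in self.cds_segments]
        cds = "".join(parts)
        if self.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        return cds.upper()


@dataclass
class HSP:
    """One aligned high-scoring pair with the two aligned strings.

    ``subject_codons``, when present, holds one nucleotide triplet per
    non-gap subject alignment column (translated-search alignments).
    """

    query_id: str
    subject_id: str
    pct_identity: float
    evalue: float
    bitscore: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    frame: int | None
    q_aln: str
    s_aln: str
    subject_codons: list[str] | None = None

    def validate(self) -> None:
        if len(self.q_aln) != len(self.s_aln):
            raise ValueError(
                f"HSP {self.query_id}/{self.subject_id}: aligned strings "
                f"differ in length ({len(self.q_aln)} vs {len(self.s_aln)})")
        if self.evalue < 0:
            raise ValueError("negative e-value")
        if self.subject_codons is not None:
            n_subj = sum(1 for c in self.s_aln if c != "-")
            if len(self.subject_codons) != n_subj:
                raise ValueError(
                    f"HSP {self.query_id}/{self.subject_id}: "
                    f"{len(self.subject_codons)} subject codons for "
                    f"{n_subj} non-gap subject columns")

    @property
    def query_span(self) -> int:
        return abs(self.q_end - self.q_start) + 1

    @property
    def subject_span(self) -> int:
        return abs(self.s_end - self.s_start) + 1


@dataclass
class CtSet:
    """qPCR threshold-cycle replicates for one gene under two conditions."""

    gene: str
    control_cts: list[float]
    sample_cts: list[float]
    role: str = "target"

    def __post_init__(self) -> None:
        for ct in [*self.control_cts, *self.sample_cts]:
            if not np.isfinite(ct) or ct <= 0:
                raise ValueError(f"{self.gene}: Ct values must be finite "
                                 f"and positive, got {ct}")


def parse_spades_header(header: str) -> tuple[str, int | None, float | None]:
    """Parse a SPAdes-style description line (without the leading ``>``).

    Returns ``(id, length, coverage)`` where the id is the full first
    whitespace-delimited token; length/coverage are ``None`` unless the
    ``_length_<int>_cov_<float>`` pattern is present.  Never raises.
    """
    token = str(header).split()[0] if str(header).split() else ""
    m = _SPADES_RE.search(token)
    if m:
        return token, int(m.group(1)), float(m.group(2))
    return token, None, None


def read_assembly_fasta(path: str | Path) -> list[Contig]:
    """Read a FASTA assembly into Contigs, in file order.

    Sequences are uppercased; coverage is taken from the header when the
    SPAdes pattern is parseable.  Duplicate ids are an error.
    """
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        cid, _, cov = parse_spades_header(rec.description or rec.id)
        if cid in seen:
            raise ValueError(f"duplicate contig id {cid!r}")
        seen.add(cid)
        contigs.append(Contig(id=cid, sequence=str(rec.seq),
                              coverage=cov, description=rec.description))
    if not contigs:
        warnings.warn(f"no FASTA records in {path}")
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | Path,
                width: int = 70) -> None:
    recs = [SeqRecord(Seq(c.sequence), id=c.id, description="")
            for c in contigs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def _parse_hsp_row(fields: Sequence[str], lineno: int) -> HSP:
    if len(fields) not in (12, 13):
        raise ValueError(f"line {lineno}: expected 12 or 13 columns, "
                         f"got {len(fields)}")
    try:
        hsp = HSP(
            query_id=fields[0],
            subject_id=fields[1],
            pct_identity=float(fields[2]),
            evalue=float(fields[3]),
            bitscore=float(fields[4]),
            q_start=int(fields[5]),
            q_end=int(fields[6]),
            s_start=int(fields[7]),
            s_end=int(fields[8]),
            frame=None if fields[9] in (".", "", "NA") else int(fields[9]),
            q_aln=fields[10],
            s_aln=fields[11],
            subject_codons=(fields[12].split(",") if len(fields) == 13
                            and fields[12] else None),
        )
    except ValueError as exc:
        raise ValueError(f"line {lineno}: {exc}") from None
    try:
        hsp.validate()
    except ValueError as exc:
        raise ValueError(f"line {lineno}: {exc}") from None
    return hsp


def read_hsp_table(path: str | Path) -> list[HSP]:
    """Read the extended tab-separated HSP dialect.

    Columns: query_id, subject_id, pct_identity, evalue, bitscore, q_start,
    q_end, s_start, s_end, frame, q_aln, s_aln[, subject_codons].  Rows
    failing validation raise with their line number.
    """
    hsps: list[HSP] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            hsps.append(_parse_hsp_row(line.split("\t"), lineno))
    return hsps


def write_hsp_table(hsps: Iterable[HSP], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hsps:
            fields = [
                h.query_id, h.subject_id, f"{h.pct_identity:g}",
                f"{h.evalue:g}", f"{h.bitscore:g}",
                str(h.q_start), str(h.q_end), str(h.s_start), str(h.s_end),
                "." if h.frame is None else str(h.frame),
                h.q_aln, h.s_aln,
            ]
            if h.subject_codons is not None:
                fields.append(",".join(h.subject_codons))
            fh.write("\t".join(fields) + "\n")


def hsps_from_tabular(path: str | Path,
                      query_seqs: Mapping[str, str],
                      subject_seqs: Mapping[str, str]) -> list[HSP]:
    """Convert standard 12-column tabular search output (qseqid sseqid pident
    evalue bitscore qstart qend sstart send frame, or the common variant
    without frame) plus the raw sequences into extended HSPs.

    The aligned strings are reconstructed by cutting the ungapped coordinate
    spans out of the supplied sequences; this is only exact for ungapped
    HSPs and is intended as a bridge for callers who lack alignment strings.
    """
    hsps: list[HSP] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            qid, sid = f[0], f[1]
            if qid not in query_seqs:
                raise KeyError(f"line {lineno}: unknown query {qid!r}")
            if sid not in subject_seqs:
                raise KeyError(f"line {lineno}: unknown subject {sid!r}")
            qs, qe = int(f[5]), int(f[6])
            ss, se = int(f[7]), int(f[8])
            q_aln = query_seqs[qid][qs - 1:qe]
            s_aln = subject_seqs[sid][ss - 1:se]
            if len(q_aln) != len(s_aln):
                raise ValueError(
                    f"line {lineno}: gapped HSP cannot be reconstructed "
                    f"from coordinates alone")
            hsps.append(HSP(qid, sid, float(f[2]), float(f[3]), float(f[4]),
                            qs, qe, ss, se,
                            int(f[9]) if len(f) > 9 and f[9] not in (".", "")
                            else None,
                            q_aln, s_aln))
    return hsps


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (CDS features grouped by Parent/ID).

    Coordinates are converted from GFF3 1-based inclusive to the internal
    0-based half-open convention.
    """
    cds_by_gene: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "CDS":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            gene_id = attrs.get("Parent") or attrs.get("ID")
            if gene_id is None:
                raise ValueError(f"CDS feature without Parent/ID: {line!r}")
            entry = cds_by_gene.setdefault(
                gene_id, {"contig": f[0], "strand": f[6], "segments": []})
            entry["segments"].append((int(f[3]) - 1, int(f[4])))
    genes = []
    for gid, entry in cds_by_gene.items():
        segs = sorted(entry["segments"])
        total = sum(e - s for s, e in segs)
        genes.append(GeneModel(id=gid, contig_id=entry["contig"],
                               strand=entry["strand"], cds_segments=segs,
                               protein_length=total // 3 - 1))
    return genes


def write_gff3_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 CDS features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            for s, e in g.cds_segments:
                fh.write("\t".join([
                    g.contig_id, "nanochrom", "CDS", str(s + 1), str(e),
                    ".", g.strand, "0", f"ID={g.id}.cds;Parent={g.id}",
                ]) + "\n")


def read_expression_table(path: str | Path) -> dict[str, float]:
    """gene_id<TAB>abundance; duplicate ids or non-finite values raise."""
    table: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            gid, value = line.rstrip("\n").split("\t")[:2]
            if gid in table:
                raise ValueError(f"line {lineno}: duplicate gene id {gid!r}")
            x = float(value)
            if not np.isfinite(x) or x < 0:
                raise ValueError(f"line {lineno}: bad abundance {value!r}")
            table[gid] = x
    return table


def write_expression_table(table: Mapping[str, float],
                           path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid, value in table.items():
            fh.write(f"{gid}\t{value:g}\n")


def read_trajectory(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Two-column whitespace-separated (time ns, RMSD nm); '#'/'@' lines are
    ignored (XVG-compatible)."""
    times, rmsds = [], []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s[0] in "#@":
                continue
            t, r = s.split()[:2]
            times.append(float(t))
            rmsds.append(float(r))
    return np.asarray(times), np.asarray(rmsds)


def read_ct_table(path: str | Path) -> dict[str, CtSet]:
    """Tab-separated Ct table: gene, group (control|treated), then replicate
    Ct values.  Returns one CtSet per gene."""
    rows: dict[str, dict[str, list[float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            gene, group = f[0], f[1].lower()
            if group not in ("control", "treated"):
                raise ValueError(f"line {lineno}: unknown group {group!r}")
            rows.setdefault(gene, {})[group] = [float(x) for x in f[2:] if x]
    out = {}
    for gene, groups in rows.items():
        out[gene] = CtSet(gene=gene,
                          control_cts=groups.get("control", []),
                          sample_cts=groups.get("treated", []))
    return out
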
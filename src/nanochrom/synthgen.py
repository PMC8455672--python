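"""Synthetic nanochromosome data with per-record planted truth.

Every analysis stage in this package is validated against data from this
module: telomere-capped single-gene nanochromosomes with a unimodal GC
distribution near 31.5%, high-GC/low-coverage contaminant contigs, short
redundant "chaff" contigs, genes carrying terminal +1-frameshift motifs,
allele pairs (~95% identity) and paralog families (~40% identity),
translated-alignment HSPs with controlled flank identities around stop
codons, saturating RMSD trajectories, and qPCR Ct replicates with a known
expression ratio.  Every generator is a pure function of its parameters and
seed.

Mutation for allele/paralog planting is substitution-only (each mutated
site is replaced by a different base), so the planted identity is exactly
1 − mutation rate in expectation.  Paralog families keep short conserved
anchor blocks intact — as real protein families do around functional
motifs — which is also what makes k-mer screening find diverged relatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, log

import numpy as np

from nanochrom.frameshift import FRAMESHIFT_MOTIFS
from nanochrom.seqio import Contig, CtSet, GeneModel, HSP

__all__ = [
    "GenomeSpec",
    "TruthTable",
    "generate_assembly",
    "generate_frameshift_hsps",
    "generate_expression",
    "generate_readthrough_hsps",
    "generate_trajectory",
    "generate_ct_sets",
]

_BASES = np.array(list("ACGT"))
_AA = "ACDEFGHIKLMNPQRSTVWY"
# one representative (universal-code) codon per amino acid, for building
# subject codon strings in translated alignments
_AA_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class GenomeSpec:
    """Study conditions for a synthetic nanochromosome assembly."""

    n_nanochromosomes: int = 200
    telomere_unit: str = "CCCCAAAA"
    telomere_copies: tuple[int, int] = (3, 6)
    # 2-/1-/0-telomere proportions of a euplotid MAC draft assembly
    # (~77% of contigs carry at least one telomere)
    class_fractions: tuple[float, float, float] = (0.572, 0.197, 0.231)
    target_gc: float = 0.315
    gc_sd: float = 0.02
    insert_length_mean: float = 1900.0   # lognormal-like, bp
    insert_length_sigma: float = 0.45    # sigma of log length
    frameshift_fraction: float = 0.05
    n_allele_pairs: int = 0
    allele_identity: float = 0.95
    n_paralog_families: int = 0
    paralog_family_size: int = 3
    paralog_identity: float = 0.40
    paralog_anchor_frac: float = 0.15
    paralog_len: int = 600
    n_contaminants: int = 0
    contaminant_gc: float = 0.55
    contaminant_cov: float = 3.0
    n_chaff: int = 0
    coverage_mean: float = 45.0
    coverage_sd: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        f2, f1, f0 = self.class_fractions
        if abs(f2 + f1 + f0 - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        for f in (f2, f1, f0, self.target_gc, self.frameshift_fraction):
            if not 0 <= f <= 1:
                raise ValueError(f"fraction {f} out of [0,1]")
        if self.insert_length_mean < 150:
            raise ValueError("insert too short to carry a gene")


@dataclass
class TruthTable:
    """Planted ground truth, one entry per generated record."""

    contig_class: dict[str, int] = field(default_factory=dict)
    contaminants: set[str] = field(default_factory=set)
    chaff: set[str] = field(default_factory=set)
    genes: list[GeneModel] = field(default_factory=list)
    cds_seqs: dict[str, str] = field(default_factory=dict)
    gene_motif: dict[str, str | None] = field(default_factory=dict)
    pair_identity: dict[tuple[str, str], float] = field(default_factory=dict)
    emissions: list[tuple[str, str, float]] = field(default_factory=list)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _mutate(rng: np.random.Generator, seq: str, rate: float,
            protect: np.ndarray | None = None) -> str:
    """Substitute each unprotected site with probability ``rate`` by a
    different base (planted identity is analytically 1-rate)."""
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if protect is not None:
        hit &= ~protect
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def _plant_orf(rng: np.random.Generator, n_codons: int, gc: float,
               motif: str | None) -> str:
    """ATG + biased sense codons + terminal hexamer.

    The terminal hexamer is ``motif`` (sense codon + TAA/TAG) for planted
    frameshift genes, otherwise a random sense codon plus a stop, resampled
    until it is not one of the twelve motifs.  No internal in-frame stops.
    """
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_seq(rng, 3, gc)
        if c not in _STOPS:
            codons.append(c)
    if motif is not None:
        codons.append(motif[:3])
        codons.append(motif[3:])
    else:
        while True:
            sense = _random_seq(rng, 3, gc)
            stop = _STOPS[rng.integers(3)]
            if sense not in _STOPS and sense + stop not in FRAMESHIFT_MOTIFS:
                codons.append(sense)
                codons.append(stop)
                break
    return "".join(codons)


def _class_counts(n: int, fractions: tuple[float, float, float]
                  ) -> tuple[int, int, int]:
    n2 = round(n * fractions[0])
    n1 = round(n * fractions[1])
    n0 = n - n2 - n1
    if n0 < 0:
        raise ValueError("infeasible class fractions")
    return n2, n1, n0


def generate_assembly(spec: GenomeSpec) -> tuple[list[Contig], TruthTable]:
    """Generate a telomere-capped single-gene nanochromosome assembly.

    Deterministic given ``spec.seed``.  Contig ids are SPAdes-style
    (``NODE_i_length_L_cov_C``) with the planted coverage in the header.
    Returns the contigs plus a TruthTable with planted telomere classes,
    contaminant/chaff flags, gene models with CDS sequences and terminal
    motifs, and planted pair identities for alleles and paralogs.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    truth = TruthTable()
    contigs: list[Contig] = []
    unit = spec.telomere_unit.upper()
    rc_unit = unit[::-1].translate(str.maketrans("ACGT", "TGCA"))

    n2, n1, n0 = _class_counts(spec.n_nanochromosomes, spec.class_fractions)
    classes = [2] * n2 + [1] * n1 + [0] * n0
    n_fs = round(spec.n_nanochromosomes * spec.frameshift_fraction)
    fs_flags = [True] * n_fs + [False] * (spec.n_nanochromosomes - n_fs)

    node = 0
    for cls, fs in zip(classes, fs_flags):
        node += 1
        gc = float(np.clip(rng.normal(spec.target_gc, spec.gc_sd), 0.05, 0.95))
        ins_len = int(np.exp(rng.normal(
            log(spec.insert_length_mean) - spec.insert_length_sigma ** 2 / 2,
            spec.insert_length_sigma)))
        ins_len = max(ins_len, 300)
        motif = FRAMESHIFT_MOTIFS[rng.integers(len(FRAMESHIFT_MOTIFS))] \
            if fs else None
        n_codons = max(ins_len // 6, 20)
        orf = _plant_orf(rng, n_codons, gc, motif)
        pad = ins_len - len(orf)
        left = rng.integers(10, max(pad - 10, 11)) if pad > 21 else max(pad // 2, 0)
        # excluding stop codons biases ORF GC slightly upward; compensate in
        # the non-coding flanks so the contig realizes the target GC
        gc_orf = (orf.count("G") + orf.count("C")) / len(orf)
        flank_len = max(pad, 1)
        gc_flank = float(np.clip(
            (gc * (len(orf) + flank_len) - gc_orf * len(orf)) / flank_len,
            0.05, 0.95))
        insert = _random_seq(rng, left, gc_flank) + orf + \
            _random_seq(rng, max(pad - left, 0), gc_flank)

        copies5 = int(rng.integers(*spec.telomere_copies))
        copies3 = int(rng.integers(*spec.telomere_copies))
        if cls == 2:
            has5, has3 = True, True
        elif cls == 1:
            has5 = bool(rng.integers(2))
            has3 = not has5
        else:
            has5 = has3 = False
        seq = (unit * copies5 if has5 else "") + insert + \
              (rc_unit * copies3 if has3 else "")
        cov = float(np.clip(rng.normal(spec.coverage_mean, spec.coverage_sd),
                            15.0, None))
        cid = f"NODE_{node}_length_{len(seq)}_cov_{cov:.4f}"
        contigs.append(Contig(id=cid, sequence=seq, coverage=cov))
        truth.contig_class[cid] = cls

        gene_id = f"gene_{node}"
        orf_start = (len(unit) * copies5 if has5 else 0) + left
        gene = GeneModel(id=gene_id, contig_id=cid, strand="+",
                         cds_segments=[(orf_start, orf_start + len(orf))],
                         protein_length=len(orf) // 3 - 1)
        truth.genes.append(gene)
        truth.cds_seqs[gene_id] = orf
        truth.gene_motif[gene_id] = motif

    # allele pairs: mutate a copy of an existing nanochromosome insert
    for i in range(spec.n_allele_pairs):
        node += 1
        base_len = 800
        a = _random_seq(rng, base_len, spec.target_gc)
        b = _mutate(rng, a, 1.0 - spec.allele_identity)
        pair_ids = []
        for tag, s in (("a", a), ("b", b)):
            cov = float(np.clip(rng.normal(spec.coverage_mean,
                                           spec.coverage_sd), 15.0, None))
            cid = f"NODE_{node}{tag}_length_{len(s)}_cov_{cov:.4f}"
            contigs.append(Contig(id=cid, sequence=s, coverage=cov))
            truth.contig_class[cid] = 0
            pair_ids.append(cid)
        truth.pair_identity[tuple(pair_ids)] = spec.allele_identity

    # paralog families: star topology around a founder, conserved anchors
    for i in range(spec.n_paralog_families):
        node += 1
        founder = _random_seq(rng, spec.paralog_len, spec.target_gc)
        protect = np.zeros(spec.paralog_len, bool)
        n_anchor = int(spec.paralog_anchor_frac * spec.paralog_len)
        block = 30
        starts = rng.choice(spec.paralog_len - block,
                            size=max(n_anchor // block, 1), replace=False)
        for s0 in starts:
            protect[s0:s0 + block] = True
        anchor_frac = protect.mean()
        # overall identity = anchors + (1-rate) elsewhere
        rate = (1.0 - spec.paralog_identity) / (1.0 - anchor_frac)
        rate = min(rate, 1.0)
        members = [founder] + [
            _mutate(rng, founder, rate, protect=protect)
            for _ in range(spec.paralog_family_size - 1)]
        member_ids = []
        for j, s in enumerate(members):
            cov = float(np.clip(rng.normal(spec.coverage_mean,
                                           spec.coverage_sd), 15.0, None))
            cid = f"NODE_{node}f{j}_length_{len(s)}_cov_{cov:.4f}"
            contigs.append(Contig(id=cid, sequence=s, coverage=cov))
            truth.contig_class[cid] = 0
            member_ids.append(cid)
        for mid in member_ids[1:]:
            truth.pair_identity[(member_ids[0], mid)] = spec.paralog_identity

    # high-GC, low-coverage contaminants
    for i in range(spec.n_contaminants):
        node += 1
        s = _random_seq(rng, int(rng.integers(600, 1500)),
                        float(np.clip(rng.normal(spec.contaminant_gc, 0.02),
                                      0.05, 0.95)))
        cov = float(np.clip(rng.normal(spec.contaminant_cov, 1.0), 0.5, 8.0))
        cid = f"NODE_{node}_length_{len(s)}_cov_{cov:.4f}"
        contigs.append(Contig(id=cid, sequence=s, coverage=cov))
        truth.contig_class[cid] = 0
        truth.contaminants.add(cid)

    # chaff: short near-exact copies of segments of real nanochromosomes
    donors = [c for c in contigs if c.id in truth.contig_class
              and c.id not in truth.contaminants and c.length >= 600]
    for i in range(spec.n_chaff):
        node += 1
        donor = donors[rng.integers(len(donors))]
        frag_len = int(rng.integers(250, 450))
        start = int(rng.integers(0, donor.length - frag_len))
        s = _mutate(rng, donor.sequence[start:start + frag_len], 0.01)
        cov = float(np.clip(rng.normal(spec.coverage_mean,
                                       spec.coverage_sd), 15.0, None))
        cid = f"NODE_{node}_length_{len(s)}_cov_{cov:.4f}"
        contigs.append(Contig(id=cid, sequence=s, coverage=cov))
        truth.contig_class[cid] = 0
        truth.chaff.add(cid)

    return contigs, truth


def generate_frameshift_hsps(truth: TruthTable, seed: int = 0,
                             no_hit_fraction: float = 0.0,
                             coverage: float = 0.95,
                             hit_len_factor: float = 1.6,
                             ) -> tuple[list[HSP], dict[str, int]]:
    """Protein-level HSPs wired so the planted frameshift genes, and only
    they, pass the candidate criterion.

    Planted-motif genes get a top hit ``hit_len_factor`` times longer than
    the predicted protein with high query coverage; other genes get a hit of
    their own length (failing the length conjunct).  A ``no_hit_fraction``
    of non-planted genes receive no HSP at all.  Returns the HSPs and the
    subject protein lengths mapping.
    """
    rng = np.random.default_rng(seed)
    hsps: list[HSP] = []
    subject_lengths: dict[str, int] = {}
    for g in truth.genes:
        planted = truth.gene_motif[g.id] is not None
        if not planted and rng.random() < no_hit_fraction:
            continue
        plen = g.protein_length or 0
        subj = f"ref_{g.id}"
        hit_len = int(plen * hit_len_factor) if planted else plen
        subject_lengths[subj] = hit_len
        span = max(int(round(coverage * plen)), 1)
        aln = "".join(rng.choice(list(_AA), size=span))
        hsps.append(HSP(query_id=g.id, subject_id=subj, pct_identity=90.0,
                        evalue=1e-40, bitscore=200.0,
                        q_start=1, q_end=span, s_start=1, s_end=span,
                        frame=None, q_aln=aln, s_aln=aln))
    return hsps, subject_lengths


def generate_expression(gene_ids, candidate_ids, seed: int = 0,
                        log2_effect: float = 0.0,
                        mean_log: float = 4.0,
                        sd_log: float = 1.0) -> dict[str, float]:
    """Lognormal TPM-like abundances with an optional planted log2
    fold-change on the candidate set (0 = null)."""
    rng = np.random.default_rng(seed)
    table = {}
    for gid in gene_ids:
        mu = mean_log + (log2_effect if gid in candidate_ids else 0.0)
        table[gid] = float(2.0 ** rng.normal(mu, sd_log))
    return table


def generate_readthrough_hsps(emission: dict[str, dict[str, float]],
                              flank_identity: float = 1.0,
                              n_hsps: int = 100,
                              seed: int = 0,
                              evalue: float = 1e-30,
                              flank: int = 10,
                              ) -> tuple[list[HSP], TruthTable]:
    """Translated-alignment HSPs, one focal codon per HSP.

    Each HSP is an ungapped (2*flank+1)-column alignment with the focal
    subject codon in the middle, drawn uniformly from the keys of
    ``emission``; the query amino acid at the focal column is drawn from
    that codon's emission distribution, and exactly
    ``round(flank_identity * 2 * flank)`` flanking columns are made
    identical.  Truth records each planted (codon, amino acid, identity).
    """
    rng = np.random.default_rng(seed)
    truth = TruthTable()
    codons = sorted(emission)
    hsps: list[HSP] = []
    n_match = int(round(flank_identity * 2 * flank))
    for i in range(n_hsps):
        codon = codons[rng.integers(len(codons))]
        dist = emission[codon]
        aas, probs = zip(*sorted(dist.items()))
        aa = aas[rng.choice(len(aas), p=np.array(probs) / sum(probs))]
        width = 2 * flank + 1
        s_aa = list("".join(rng.choice(list(_AA), size=width)))
        q_aa = list(s_aa)
        flank_cols = [c for c in range(width) if c != flank]
        mismatch_cols = rng.choice(flank_cols, size=2 * flank - n_match,
                                   replace=False)
        for c in mismatch_cols:
            q_aa[c] = _AA[(_AA.index(s_aa[c]) + 1 + rng.integers(len(_AA) - 1))
                          % len(_AA)]
        q_aa[flank] = aa
        s_aa[flank] = "*" if codon in _STOPS else \
            {v: k for k, v in _AA_CODON.items()}.get(codon, "X")
        subject_codons = [_AA_CODON[c] if c in _AA_CODON else codon
                          for c in s_aa]
        subject_codons[flank] = codon
        hsps.append(HSP(query_id=f"q{i}", subject_id=f"s{i}",
                        pct_identity=100.0 * n_match / (2 * flank),
                        evalue=evalue, bitscore=100.0,
                        q_start=1, q_end=width, s_start=1, s_end=width,
                        frame=1, q_aln="".join(q_aa), s_aln="".join(s_aa),
                        subject_codons=subject_codons))
        truth.emissions.append((codon, aa, n_match / (2 * flank)))
    return hsps, truth


def generate_protein_families(n_families: int, family_size: int,
                              intra_identity: float = 0.45,
                              length: int = 250,
                              seed: int = 0) -> tuple[dict[str, str],
                                                      dict[str, int]]:
    """Synthetic protein families for clustering benchmarks.

    Each family is a star around a founder: members are substitution-only
    mutants of the founder at per-site rate ``1 - intra_identity``.
    Inter-family identity is the random-protein baseline (~5-10%).
    Returns (id -> sequence, id -> family index).
    """
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    labels: dict[str, int] = {}
    aa = np.array(list(_AA))
    for f in range(n_families):
        founder = "".join(aa[rng.integers(len(aa), size=length)])
        for j in range(family_size):
            if j == 0:
                s = founder
            else:
                # exact mutation count: planted identity realized exactly
                chars = np.array(list(founder))
                k = int(round((1 - intra_identity) * length))
                for i in rng.choice(length, size=k, replace=False):
                    choices = [c for c in _AA if c != chars[i]]
                    chars[i] = choices[rng.integers(len(choices))]
                s = "".join(chars)
            # founder kept longest so it is the cluster representative
            sid = f"fam{f}_p{j}"
            seqs[sid] = s if j == 0 else s[:length - 1 - (j % 3)]
            labels[sid] = f
    return seqs, labels


def write_fixture(spec: GenomeSpec, outdir) -> TruthTable:
    """Write a complete pipeline fixture directory with truth TSVs.

    Produces assembly.fasta, genes.gff3, cds.fasta, frameshift_hsps.tsv,
    subject_lengths.tsv, expression.tsv, readthrough_hsps.tsv,
    warm.xvg/cold.xvg trajectories, ct_table.tsv and truth_*.tsv files.
    Deterministic given ``spec`` (all sub-seeds derive from ``spec.seed``).
    """
    from pathlib import Path

    from nanochrom.seqio import (write_expression_table, write_fasta,
                                 write_gff3_genes, write_hsp_table)

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    contigs, truth = generate_assembly(spec)
    write_fasta(contigs, out / "assembly.fasta")
    write_gff3_genes(truth.genes, out / "genes.gff3")
    write_fasta([Contig(id=g.id, sequence=truth.cds_seqs[g.id])
                 for g in truth.genes], out / "cds.fasta")

    hsps, subject_lengths = generate_frameshift_hsps(
        truth, seed=spec.seed + 1, no_hit_fraction=0.47)
    write_hsp_table(hsps, out / "frameshift_hsps.tsv")
    with open(out / "subject_lengths.tsv", "w") as fh:
        for sid, ln in subject_lengths.items():
            fh.write(f"{sid}\t{ln}\n")

    candidate_ids = {g for g, m in truth.gene_motif.items() if m is not None}
    expr = generate_expression([g.id for g in truth.genes], candidate_ids,
                               seed=spec.seed + 2)
    write_expression_table(expr, out / "expression.tsv")

    emission = {"TGA": {"C": 0.8, "W": 0.2},
                "TAA": {"Q": 0.7, "K": 0.3}, "TAG": {"Q": 0.7, "K": 0.3},
                "CAA": {"Q": 1.0}, "CAG": {"Q": 1.0}}
    rt_hsps, rt_truth = generate_readthrough_hsps(
        emission, flank_identity=0.9, n_hsps=400, seed=spec.seed + 3)
    write_hsp_table(rt_hsps, out / "readthrough_hsps.tsv")
    truth.emissions = rt_truth.emissions

    for label, rmax, sub in (("warm", 0.35, 4), ("cold", 0.30, 5)):
        t, y = generate_trajectory(rmax, 1.0, 2.0, 0.01, 200, 50.0,
                                   seed=spec.seed + sub)
        with open(out / f"{label}.xvg", "w") as fh:
            fh.write(f"# synthetic RMSD trajectory ({label}), "
                     f"rmsd_max={rmax}\n@ xaxis label \"time (ns)\"\n")
            for ti, yi in zip(t, y):
                fh.write(f"{ti:.4f} {yi:.6f}\n")

    target, ref = generate_ct_sets(true_ratio=8.0, seed=spec.seed + 6)
    with open(out / "ct_table.tsv", "w") as fh:
        for cs in (target, ref):
            fh.write("\t".join([cs.gene, "control",
                                *[f"{x:.3f}" for x in cs.control_cts]]) + "\n")
            fh.write("\t".join([cs.gene, "treated",
                                *[f"{x:.3f}" for x in cs.sample_cts]]) + "\n")

    with open(out / "truth_contigs.tsv", "w") as fh:
        fh.write("contig_id\ttelomere_class\tcontaminant\tchaff\n")
        for cid, cls in truth.contig_class.items():
            fh.write(f"{cid}\t{cls}\t{int(cid in truth.contaminants)}"
                     f"\t{int(cid in truth.chaff)}\n")
    with open(out / "truth_genes.tsv", "w") as fh:
        fh.write("gene_id\tmotif\n")
        for gid, m in truth.gene_motif.items():
            fh.write(f"{gid}\t{m or '.'}\n")
    return truth


def generate_trajectory(rmsd_max: float, n: float, const: float,
                        noise_sd: float, n_points: int, t_max: float,
                        seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Saturation-model RMSD series with i.i.d. Gaussian noise."""
    if n_points < 4:
        raise ValueError("need at least 4 points")
    rng = np.random.default_rng(seed)
    t = np.linspace(t_max / n_points, t_max, n_points)
    y = t * rmsd_max / (t ** n + const) + rng.normal(0, noise_sd, n_points)
    return t, y


def generate_ct_sets(true_ratio: float, e_target: float = 2.0,
                     e_ref: float = 2.0, noise_sd: float = 0.2,
                     n_reps: int = 4, seed: int = 0,
                     gene: str = "target", ref_gene: str = "reference",
                     ) -> tuple[CtSet, CtSet]:
    """Ct replicates realizing a known expression ratio.

    The reference gene has equal mean Ct in both conditions; the target's
    sample Ct is shifted by −log_E(ratio) relative to control so the Pfaffl
    ratio recovers ``true_ratio`` in expectation.
    """
    rng = np.random.default_rng(seed)
    shift = log(true_ratio) / log(e_target)
    t_ctrl = rng.normal(25.0, noise_sd, n_reps)
    t_smpl = rng.normal(25.0 - shift, noise_sd, n_reps)
    r_ctrl = rng.normal(18.0, noise_sd, n_reps)
    r_smpl = rng.normal(18.0, noise_sd, n_reps)
    target = CtSet(gene=gene, control_cts=list(t_ctrl),
                   sample_cts=list(t_smpl), role="target")
    ref = CtSet(gene=ref_gene, control_cts=list(r_ctrl),
                sample_cts=list(r_smpl), role="reference")
    return target, ref
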
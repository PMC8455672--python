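"""Pipeline configuration and the full-run orchestrator.

All stage thresholds live in one validated schema so the defaults — the
GC/coverage rule (45%, 10x), the chaff rule (500 bp, 0.8 coverage, 0.9
identity), the frameshift coverage floor (0.8), the readthrough window
(e < 1e-20, 10-column flanks, 0.4 identity), the clustering thresholds
(0.95 alleles / 0.40 families) and the completeness criterion (e < 1e-10,
coverage > 0.7) — are auditable in a single place.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

import nanochrom
from nanochrom import decontam, frameshift, homology, readthrough, telostats
from nanochrom.seqio import (read_assembly_fasta, read_expression_table,
                             read_gff3_genes, read_hsp_table, write_fasta)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

_DOMAINS = {
    "gc_threshold": (0.0, 100.0),
    "cov_threshold": (0.0, float("inf")),
    "chaff_min_len": (1, 10**9),
    "chaff_cov_frac": (0.0, 1.0),
    "chaff_min_identity": (0.0, 1.0),
    "foreign_min_identity": (0.0, 1.0),
    "telomere_min_copies": (1.0, float("inf")),
    "telomere_max_offset": (0, 10**6),
    "gc_bin_width": (1e-9, 100.0),
    "frameshift_coverage_min": (0.0, 1.0),
    "readthrough_evalue_max": (0.0, float("inf")),
    "readthrough_flank": (1, 1000),
    "readthrough_identity_min": (0.0, 1.0),
    "allele_threshold": (0.0, 1.0),
    "family_threshold": (0.0, 1.0),
    "ceg_evalue_max": (0.0, float("inf")),
    "ceg_coverage_min": (0.0, 1.0),
}


@dataclass
class PipelineConfig:
    """Per-stage parameter blocks with the module defaults."""

    input_dir: str = "."
    output_dir: str = "pipeline_out"
    seed: int = 0
    log_level: str = "INFO"
    telomere_repeat_unit: str = telostats.DEFAULT_REPEAT_UNIT
    telomere_min_copies: float = 2.0
    telomere_max_offset: int = 5
    gc_bin_width: float = 1.0
    gc_threshold: float = 45.0
    cov_threshold: float = 10.0
    gc_cov_mode: str = "all"
    chaff_min_len: int = 500
    chaff_cov_frac: float = 0.8
    chaff_min_identity: float = 0.9
    foreign_min_identity: float = 0.95
    frameshift_coverage_min: float = 0.8
    readthrough_evalue_max: float = 1e-20
    readthrough_flank: int = 10
    readthrough_identity_min: float = 0.4
    allele_threshold: float = 0.95
    family_threshold: float = 0.40
    ceg_evalue_max: float = 1e-10
    ceg_coverage_min: float = 0.7

    def validate(self) -> None:
        for name, (lo, hi) in _DOMAINS.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(
                    f"config: {name}={v} outside its domain [{lo}, {hi}]")
        if self.gc_cov_mode not in ("all", "any"):
            raise ValueError(f"config: bad gc_cov_mode {self.gc_cov_mode!r}")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config; unknown keys are rejected before execution."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"config: unknown keys {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the staged analysis over a directory of inputs.

    Stages: clean → telomere stats → frameshift → readthrough →
    identity/clusters → completeness.  Each stage writes TSV artifacts
    under ``config.output_dir``; a ``manifest.json`` records version, seed,
    parameters and the per-stage summaries.  Stages whose inputs are absent
    are skipped and noted.  Deterministic given config + seed.
    """
    config.validate()
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}}

    assembly_path = indir / "assembly.fasta"
    if not assembly_path.exists():
        raise FileNotFoundError(f"pipeline: missing {assembly_path}")
    contigs = read_assembly_fasta(assembly_path)

    # --- clean ---
    rep_gc = decontam.filter_gc_coverage(contigs, config.gc_threshold,
                                         config.cov_threshold,
                                         mode=config.gc_cov_mode)
    contigs_clean = rep_gc.apply(contigs)
    rep_chaff = decontam.remove_chaff(contigs_clean, config.chaff_min_len,
                                      config.chaff_cov_frac,
                                      config.chaff_min_identity)
    contigs_clean = rep_chaff.apply(contigs_clean)
    removed = list(rep_gc.removed) + list(rep_chaff.removed)
    cont_path = indir / "contaminants.fasta"
    if cont_path.exists():
        rep_foreign = decontam.flag_foreign(
            contigs_clean, read_assembly_fasta(cont_path),
            config.foreign_min_identity)
        contigs_clean = rep_foreign.apply(contigs_clean)
        removed += list(rep_foreign.removed)
    _write_tsv(outdir / "removed_contigs.tsv",
               ["contig_id", "reason", "evidence"], [list(r) for r in removed])
    write_fasta(contigs_clean, outdir / "assembly.clean.fasta")
    summary["stages"]["clean"] = {
        "n_input": len(contigs), "n_kept": len(contigs_clean),
        "n_removed": len(removed)}

    # --- telomere stats ---
    annotations = [telostats.detect_telomeres(
        c, config.telomere_repeat_unit, config.telomere_min_copies,
        config.telomere_max_offset) for c in contigs_clean]
    stats = telostats.assembly_stats(contigs_clean, annotations)
    _write_tsv(outdir / "telomere_annotations.tsv",
               ["contig_id", "class", "five_copies", "five_offset",
                "three_copies", "three_offset"],
               [[a.contig_id, a.telomere_class,
                 f"{a.five_prime.repeat_copies:.2f}", a.five_prime.offset,
                 f"{a.three_prime.repeat_copies:.2f}", a.three_prime.offset]
                for a in annotations])
    _write_tsv(outdir / "assembly_stats.tsv", ["metric", "value"], [
        ["n_contigs", stats.n_contigs],
        ["total_bp", stats.total_bp],
        ["gc_percent", f"{stats.gc_percent:.2f}"],
        ["n50", stats.n50],
        ["mean_len", f"{stats.mean_len:.1f}"],
        ["max_len", stats.max_len],
        ["n_telomeres", stats.n_telomeres],
        ["contigs_class2", stats.contigs_per_class[2]],
        ["contigs_class1", stats.contigs_per_class[1]],
        ["contigs_class0", stats.contigs_per_class[0]],
        ["pct_with_telomere", f"{stats.pct_with_telomere:.1f}"],
    ])
    hist = telostats.gc_histogram(contigs_clean, config.gc_bin_width)
    _write_tsv(outdir / "gc_histogram.tsv", ["bin_lo", "count"],
               [[lo, n] for lo, n in hist.items()])
    summary["stages"]["stats"] = {
        "n50": stats.n50, "gc_percent": round(stats.gc_percent, 4),
        "pct_with_telomere": round(stats.pct_with_telomere, 4)}

    # --- frameshift ---
    gff = indir / "genes.gff3"
    cds_fa = indir / "cds.fasta"
    fs_hsps_path = indir / "frameshift_hsps.tsv"
    if gff.exists() and cds_fa.exists() and fs_hsps_path.exists():
        genes = read_gff3_genes(gff)
        cds_seqs = {c.id: c.sequence for c in read_assembly_fasta(cds_fa)}
        fs_hsps = read_hsp_table(fs_hsps_path)
        subj_path = indir / "subject_lengths.tsv"
        subject_lengths = None
        if subj_path.exists():
            subject_lengths = {k: int(v) for k, v in
                               (line.split("\t")[:2] for line in
                                subj_path.read_text().splitlines() if line)}
        cands = frameshift.select_candidates(
            genes, cds_seqs, fs_hsps, subject_lengths,
            config.frameshift_coverage_min)
        frac = frameshift.frameshift_fraction(cands, len(genes))
        _write_tsv(outdir / "frameshift_candidates.tsv",
                   ["gene_id", "motif", "protein_len", "top_hit_len",
                    "coverage", "passes", "evaluable"],
                   [[c.gene_id, c.motif or ".", c.predicted_protein_len,
                     c.top_hit_len if c.top_hit_len is not None else ".",
                     f"{c.blast_coverage:.3f}" if c.blast_coverage is not None
                     else ".", int(c.passes), int(c.evaluable)]
                    for c in cands])
        fs_summary = {"n_genes": len(genes),
                      "n_pass": sum(c.passes for c in cands),
                      "fraction_percent": round(frac, 4)}
        expr_path = indir / "expression.tsv"
        if expr_path.exists():
            expr = read_expression_table(expr_path)
            cand_ids = {c.gene_id for c in cands if c.passes}
            t, p, n1, n2 = frameshift.expression_comparison(expr, cand_ids)
            fs_summary.update({"t": round(t, 4), "p_value": round(p, 4)})
        summary["stages"]["frameshift"] = fs_summary
    else:
        summary["stages"]["frameshift"] = "skipped (no gene/HSP inputs)"

    # --- readthrough ---
    rt_path = indir / "readthrough_hsps.tsv"
    if rt_path.exists():
        windows = readthrough.extract_codon_windows(
            read_hsp_table(rt_path), config.readthrough_evalue_max,
            config.readthrough_flank, config.readthrough_identity_min)
        table = readthrough.aa_frequency_table(windows)
        rows = []
        for cls, freqs in table.frequencies.items():
            for aa, f in sorted(freqs.items(), key=lambda kv: -kv[1]):
                rows.append([cls, aa, table.counts[cls][aa], f"{f:.4f}",
                             table.n[cls]])
        _write_tsv(outdir / "readthrough_frequencies.tsv",
                   ["codon_class", "aa", "count", "freq", "n"], rows)
        summary["stages"]["readthrough"] = {
            cls: (max(freqs, key=freqs.get) if freqs else None)
            for cls, freqs in table.frequencies.items()}
    else:
        summary["stages"]["readthrough"] = "skipped (no HSP input)"

    # --- identity / clusters ---
    seqs = {c.id: c.sequence for c in contigs_clean}
    if len(seqs) >= 2:
        pairs = homology.best_nonself_pairs(seqs)
        _write_tsv(outdir / "identity_pairs.tsv",
                   ["a_id", "b_id", "identity_percent"],
                   [[p.a_id, p.b_id or ".",
                     f"{p.identity:.2f}" if p.identity is not None else "."]
                    for p in pairs])
        clusters = homology.greedy_cluster(seqs, config.allele_threshold)
        _write_tsv(outdir / "clusters.tsv",
                   ["representative", "n_members", "members"],
                   [[cl.representative_id, len(cl.member_ids),
                     ",".join(cl.member_ids)] for cl in clusters])
        summary["stages"]["identity"] = {
            "n_pairs": len(pairs), "n_clusters": len(clusters)}
    else:
        summary["stages"]["identity"] = "skipped (<2 contigs)"

    # --- completeness ---
    ceg_hsps_path = indir / "ceg_hsps.tsv"
    ref_len_path = indir / "ceg_lengths.tsv"
    if ceg_hsps_path.exists() and ref_len_path.exists():
        ref_lengths = {k: int(v) for k, v in
                       (line.split("\t")[:2] for line in
                        ref_len_path.read_text().splitlines() if line)}
        report = homology.completeness(
            read_hsp_table(ceg_hsps_path), ref_lengths,
            config.ceg_evalue_max, config.ceg_coverage_min)
        _write_tsv(outdir / "completeness.tsv",
                   ["ref_id", "best_evalue", "best_coverage", "present"],
                   [[rid, e if e is not None else ".",
                     f"{c:.3f}" if c is not None else ".", int(p)]
                    for rid, (e, c, p) in report.per_protein.items()])
        summary["stages"]["completeness"] = {
            "percent_present": round(report.percent_present, 4)}
    else:
        summary["stages"]["completeness"] = "skipped (no CEG inputs)"

    manifest = {
        "package": "nanochrom",
        "version": nanochrom.__version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "summary": summary,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
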
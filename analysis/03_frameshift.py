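"""Scan predicted genes for terminal +1 frameshift motifs.

Applies the three-part candidate criterion (terminal motif, predicted
protein shorter than the top database hit, query coverage above 80%) to
the fixture's genes and HSPs, reports the affected-gene fraction over both
denominators (all genes, and genes with a database hit), and compares
candidate vs non-candidate transcript abundances with a two-sample t-test.
"""

from pathlib import Path

from nanochrom.frameshift import (expression_comparison, frameshift_fraction,
                                  select_candidates)
from nanochrom.seqio import (read_assembly_fasta, read_expression_table,
                             read_gff3_genes, read_hsp_table)

ROOT = Path(__file__).resolve().parent.parent
FIXTURE = ROOT / "results" / "fixture"
OUT = ROOT / "results" / "frameshift_candidates.tsv"


def main() -> None:
    genes = read_gff3_genes(FIXTURE / "genes.gff3")
    cds = {c.id: c.sequence
           for c in read_assembly_fasta(FIXTURE / "cds.fasta")}
    hsps = read_hsp_table(FIXTURE / "frameshift_hsps.tsv")
    subj = {k: int(v) for k, v in
            (line.split("\t")[:2] for line in
             (FIXTURE / "subject_lengths.tsv").read_text().splitlines()
             if line)}
    cands = select_candidates(genes, cds, hsps, subj)

    with open(OUT, "w") as fh:
        fh.write("gene_id\tmotif\tprotein_len\ttop_hit_len\tcoverage"
                 "\tpasses\tevaluable\n")
        for c in cands:
            cov = f"{c.blast_coverage:.3f}" if c.blast_coverage is not None \
                else "."
            hit = c.top_hit_len if c.top_hit_len is not None else "."
            fh.write(f"{c.gene_id}\t{c.motif or '.'}"
                     f"\t{c.predicted_protein_len}\t{hit}\t{cov}"
                     f"\t{int(c.passes)}\t{int(c.evaluable)}\n")

    n_pass = sum(c.passes for c in cands)
    n_eval = sum(c.evaluable for c in cands)
    frac_all = frameshift_fraction(cands, len(genes))
    frac_eval = frameshift_fraction(cands, n_eval) if n_eval else 0.0
    print(f"candidates passing: {n_pass} of {len(genes)} genes")
    print(f"  fraction over all genes:        {frac_all:.2f}%")
    print(f"  fraction over evaluable genes:  {frac_eval:.2f}%"
          f"  ({len(genes) - n_eval} genes had no database hit)")

    expr = read_expression_table(FIXTURE / "expression.tsv")
    t, p, n1, n2 = expression_comparison(
        expr, {c.gene_id for c in cands if c.passes})
    verdict = "significant" if p < 0.05 else "not significant"
    print(f"expression, candidates vs others: t={t:.3f} p={p:.3f} "
          f"(n={n1} vs {n2}) -> {verdict} at alpha=0.05")
    print(f"table: {OUT}")


if __name__ == "__main__":
    main()
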
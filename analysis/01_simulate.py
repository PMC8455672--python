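"""Generate the synthetic nanochromosome study set.

Writes a complete fixture directory (assembly, gene models, CDSs, HSP
tables, expression table, RMSD trajectories, qPCR Ct table, truth TSVs)
under results/fixture/.  Every downstream analysis script reads from it.
The conditions: 200 telomere-capped single-gene nanochromosomes at the
class proportions of a euplotid MAC draft (57/20/23% for 2/1/0 telomeres),
GC centred on 31.5%, a 5% planted frameshift-candidate rate, 20 high-GC
low-coverage contaminants and 20 redundant chaff fragments.
"""

import sys
from pathlib import Path

from nanochrom.synthgen import GenomeSpec, write_fixture

OUT = Path(__file__).resolve().parent.parent / "results" / "fixture"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7


def main() -> None:
    spec = GenomeSpec(n_nanochromosomes=200, n_contaminants=20, n_chaff=20,
                      frameshift_fraction=0.05, seed=SEED)
    truth = write_fixture(spec, OUT)
    n_tel = sum(1 for v in truth.contig_class.values() if v > 0)
    print(f"wrote fixture to {OUT}")
    print(f"  contigs: {len(truth.contig_class)} "
          f"({len(truth.contaminants)} contaminants, "
          f"{len(truth.chaff)} chaff)")
    print(f"  genes: {len(truth.genes)}, planted frameshift candidates: "
          f"{sum(1 for m in truth.gene_motif.values() if m is not None)}")
    print(f"  telomere-bearing contigs (incl. planted extras): {n_tel}")


if __name__ == "__main__":
    main()
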
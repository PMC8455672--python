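"""Amino acids aligned to stop codons in conserved translated alignments.

Extracts 21-codon windows around subject TGA, TAA/TAG and CAA/CAG codons
from the fixture's translated-search HSPs (e < 1e-20, gap-free flanks,
>= 40% flank identity) and tabulates the aligned amino-acid frequencies per
codon class.  TGA is expected to read as cysteine, TAA/TAG and the CAA/CAG
glutamine controls as glutamine.
"""

from pathlib import Path

from nanochrom.readthrough import aa_frequency_table, extract_codon_windows
from nanochrom.seqio import read_hsp_table

ROOT = Path(__file__).resolve().parent.parent
FIXTURE = ROOT / "results" / "fixture"
OUT = ROOT / "results" / "readthrough_frequencies.tsv"


def main() -> None:
    hsps = read_hsp_table(FIXTURE / "readthrough_hsps.tsv")
    windows = extract_codon_windows(hsps)
    table = aa_frequency_table(windows)
    n_acc = sum(w.accepted for w in windows)
    print(f"windows: {len(windows)} emitted, {n_acc} accepted")
    with open(OUT, "w") as fh:
        fh.write("codon_class\taa\tcount\tfreq\tn\n")
        for cls, freqs in table.frequencies.items():
            for aa, f in sorted(freqs.items(), key=lambda kv: -kv[1]):
                fh.write(f"{cls}\t{aa}\t{table.counts[cls][aa]}"
                         f"\t{f:.4f}\t{table.n[cls]}\n")
    for cls, freqs in table.frequencies.items():
        if freqs:
            top = max(freqs, key=freqs.get)
            print(f"  {cls:8s} n={table.n[cls]:4d}  modal aa: {top} "
                  f"({freqs[top]:.2f})")
    print(f"table: {OUT}")


if __name__ == "__main__":
    main()
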
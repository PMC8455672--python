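# Methods

This note records the models, conventions and design choices behind each
stage, what the synthetic generator does and does not emulate, and the
numerical details a maintainer would need.

## Telomere detection and assembly statistics

Euplotid MAC telomeres are short exact tandem repeats; the default unit is
5′-C₄A₄-3′ (reverse complement G₄T₄ at the 3′ end), exposed as a parameter
because the unit differs across ciliate lineages.  An end is telomeric when
a tandem run of at least `min_copies` (default 2.0) copies begins within
`max_offset` (default 5) nt of the contig end; matching is exact, and a
partial terminal unit counts pro rata (2 full copies plus 4 of 8 bases →
2.5 copies).  Exact matching is conservative: on real assemblies with
degenerate or sequencing-error-bearing caps it will undercount relative to
a fuzzy matcher.  Detection is implemented symmetrically — the 3′ scan is
the 5′ scan on the reverse complement — which makes the strand-mirroring
property hold by construction.

N50 is the largest length L such that contigs of length ≥ L sum to at least
half the assembly, computed by descending cumulative sum and property-tested
against an exhaustive candidate scan.  %GC is assembly-wide over A+C+G+T
(N excluded from the denominator, counted in lengths) and includes telomeric
runs; a telomere-trimmed variant is available through `trim_telomeres`.

## Clean-up filters

The contaminant rule removes contigs with GC above 45 % **and** coverage
below 10×, reading the rule as a conjunction; a disjunctive mode is a
config option because the sentence-level reading is genuinely ambiguous.
Contigs without coverage in their headers are kept.  Chaff removal deletes
contigs shorter than 500 bp for which another contig contains a local
alignment covering ≥ 80 % of the short contig at ≥ 90 % identity
(identities / aligned columns).  Candidate pairs are screened by shared
11-mers before alignment; the screen is an efficiency device and is
property-tested to leave results unchanged.  Chaff evaluation is
single-pass against the full input set, so a chaff contig may be supported
by another chaff contig; a recursive re-evaluation mode is not the default.
Foreign-sequence flagging aligns contigs to a user-supplied contaminant
genome and flags matches at ≥ 0.95 identity over the shorter sequence (the
cd-hit-2d convention); telomere-bearing short contigs are not special-cased.

## Frameshift candidates

The twelve motifs are hexamers of a sense codon followed by TAA or TAG.
The motif is evaluated at the annotated CDS terminus only (final sense
codon + stop): predictions trained without frameshifting end exactly at the
stop a +1 shift would read through, so internal occurrences are
uninformative for this criterion.  "Top hit length" is the subject's full
protein length, supplied as an explicit mapping (when absent, the maximum
observed subject-alignment end per subject is used, a lower bound that is
exact for full-length hits); "coverage" is the top HSP's query span over
the predicted protein length.  Genes with no hit are counted separately and
fractions are reported over both denominators (all genes, evaluable genes),
since roughly half of predicted genes in a novel genome may lack database
hits.  The expression comparison is a two-sided two-sample t-test,
pooled-variance by default (Welch optional), on untransformed abundances
(log2(x+1) optional); identical constant groups are rejected as degenerate.

## Readthrough windows

A window is one (HSP, subject codon) pair for codons in {TGA, TAA, TAG,
CAA, CAG}.  The "21 amino acids centered on the codon" criterion is read as
a 21-codon window — focal column plus 10 alignment columns per side — and
the ≥ 40 % flank identity is computed jointly over the 20 flanking columns;
a per-side mode exists because the criterion could also be read per flank.
Windows with any gap in the flanks (either sequence) or a gap at the focal
query column are rejected rather than identity-penalized, and the focal
column is excluded from the identity to avoid counting a codon as conserved
because of its own match.  Each accepted (HSP, column) pair counts once;
overlapping HSPs covering the same subject position are not deduplicated by
default.  Rejections are monotone in both thresholds, and extraction is
tested against an exhaustive column-scan oracle.

## Identity, clustering, completeness

Two identity conventions coexist deliberately.  Distribution-style identity
(best-nonself histograms) is identical columns over alignment length from a
global affine-gap alignment; clustering identity is identical columns over
the shorter sequence (CD-HIT).  The nucleotide aligner uses stiff gap
penalties (match 1, mismatch −2, open −8, extend −4): with the permissive
blastn-like scheme the optimal global alignment of substitution-diverged
sequences recruits gap columns and inflates counted identity well above the
per-site identity, which would distort the allele/paralog peaks this
analysis is about.  Under the stiff scheme the measured identity of
sequences diverged by substitution at rate r sits within a few points of
1 − r, and the random-DNA baseline is ≈ 40 % — which is also why paralog
peaks in nucleotide identity distributions bottom out near that value.
Proteins use BLOSUM62 with gap open −11 / extend −2.

Best-partner choice is screened by shared k-mer counts (k = 8 nucleotide,
k = 4 protein; ties to the longer partner, then lexicographic id) and the
reported identity comes from the affine alignment of the chosen pair; the
screen is tested against exhaustive all-pairs alignment on small sets.
Greedy clustering sorts by length descending (ties by id), joining the
first representative at or above threshold, which makes membership
invariant under input shuffling.  A unit-cost edit-distance prefilter
(edlib) plus a shared-k-mer gate at thresholds ≥ 0.75 skips hopeless
representative comparisons; both are over-approximations of the affine
match count, so they can only skip pairs the affine aligner would also
reject, and the fast and exhaustive paths are asserted equal in tests.

Completeness follows the core-gene criterion: a reference protein is
present when its best hit has e-value < 1e−10 and its best hit coverage
(matched reference span / reference length) exceeds 70 %; the score is the
percentage of reference proteins present.

## RMSD saturation fit

The model is RMSD(t) = t·RMSD_max/(tⁿ + const), implemented exactly in this
form even though it is non-saturating for n ≠ 1; a Hill-style variant
tⁿ·RMSD_max/(tⁿ + const) is available behind a flag for users who want a
strictly saturating curve.  Fitting is trust-region nonlinear least squares
with positivity bounds, initialization (max(rmsds), 1, median(times)), and
5 seeded log-normal-jittered restarts keeping the lowest-RSS solution, so
results are bit-reproducible given seed and inputs.  The first start is the
initialization point itself, which guarantees the fitted RSS never exceeds
the initialization RSS.  Units are ns and nm at the interface.  A flat
zero trajectory is rejected (RMSD_max at the 0 boundary).  ΔRMSD is the
plain difference RMSD_max(warm) − RMSD_max(cold) with its sign preserved.

## qPCR

Efficiency comes from the standard-curve slope, E = 10^(−1/slope) (E = 2 at
slope −3.3219); the Pfaffl ratio uses condition-mean Cts.  The
randomization test reallocates condition labels with group sizes fixed;
the default is *paired* reallocation — the i-th target and reference
replicates move together, matching the common case where both genes are
measured from the same cDNA sample — with an independent-reallocation
variant available, since the published description of the reference
implementation leaves the pairing ambiguous.  The statistic is |log ratio|;
with sampling, p = (1 + #{≥ obs}) / (1 + N) to avoid p = 0; when the number
of distinct reallocations is ≤ N the test enumerates them exhaustively and
p is the exact tail fraction.

## Synthetic data: what it emulates, and what it does not

The generator produces telomere-capped single-gene nanochromosomes with
per-contig GC drawn from N(0.315, 0.02), lognormal insert lengths
(mean ≈ 1.9 kb), SPAdes-style headers carrying planted coverage
(N(45, 8), floored at 15×), and 2/1/0-telomere class counts realized
exactly from the class fractions (default 57.2/19.7/23.1 %, the class
proportions of a euplotid MAC draft, ≈ 77 % telomere-bearing).  Each insert
carries one ATG…stop ORF with no internal in-frame stops; planted
frameshift genes have the terminal hexamer forced to one of the twelve
motifs, all others to a non-motif terminus.  Because excluding stop codons
biases ORF base composition slightly GC-richer, the non-coding flanks
compensate so the contig realizes the target GC; telomeric runs are fixed
sequence outside GC control.  Contaminants are GC ≈ 0.55, coverage ≈ 3×;
chaff contigs are 250–450 bp copies of nanochromosome segments mutated at
1 %.  Alleles are substitution-only mutants at rate 1 − identity (planted
identity analytic); paralog families are stars around a founder with ~15 %
of positions held in conserved 30-bp anchor blocks — as real protein
families conserve functional motifs — and the remainder mutated so overall
founder identity is the planted 0.40; the anchors are also what makes
k-mer screening able to find diverged relatives.  Protein families for
clustering use exact mutation counts so planted identity is realized
exactly.  Readthrough HSPs are ungapped 21-column windows with the focal
codon emitted from a configurable per-codon amino-acid distribution and
flank identity realized exactly.  Ct tables shift the target's sample Ct
by −log_E(ratio) against a stable reference.

Not emulated: sequencing error, indels (an alignment-recomputed indel mode
exists for mutation but is not the default), multi-gene nanochromosomes,
introns, biased codon usage, expression-coverage correlation, or MIC→MAC
rearrangement.  Passing closed-loop tests therefore demonstrates the
correctness of the analysis logic under the stated generative conditions,
not robustness to the full messiness of real assemblies — in particular the
exact-match telomere detector and the substitution-only identity truths are
cleaner than real data.

## Problem sizes

The default test and analysis runs use 100–1,000 nanochromosomes,
30–80-contig pipeline fixtures, 2,000 readthrough windows, 12 paralog
families of 3 × 600 bp, 1,000-gene frameshift sets, 500-point
trajectories, 4 qPCR replicates, and 1,000-replicate null simulations for
the type-I error checks; these sizes put every oracle comparison and
closed-loop recovery in minutes on one CPU while keeping binomial error
bands tight enough for the stated tolerances.
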
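"""Pairwise identity, best-nonself distributions, greedy clustering,
completeness scoring."""

import numpy as np
import pytest

from nanochrom.homology import (best_nonself_pairs, completeness,
                                greedy_cluster, pairwise_identity)
from nanochrom.seqio import HSP
from nanochrom.synthgen import (GenomeSpec, generate_assembly,
                                generate_protein_families)


def _mutate_exact(rng, s, k):
    arr = list(s)
    for i in rng.choice(len(s), size=k, replace=False):
        arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
    return "".join(arr)


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("ACGTACGT", "ACGTACGT") == 100.0

    def test_single_substitution(self):
        # one substitution in 8 columns: exhaustive DP has no better
        # gapped alternative under the scoring, so identity is 7/8
        assert pairwise_identity("ACGTACGT", "ACGAACGT") == pytest.approx(87.5)

    def test_all_mismatch(self):
        assert pairwise_identity("AAAA", "GGGG") == 0.0

    def test_alphabet_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("ACGT", "MKLV")

    def test_symmetry(self, rng):
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(50, 150)))
            b = _mutate_exact(rng, a, 20)
            assert pairwise_identity(a, b) == pytest.approx(
                pairwise_identity(b, a), abs=0.1)


class TestBestNonself:
    def test_two_identical(self):
        pairs = best_nonself_pairs({"a": "ACGTACGTACGT", "b": "ACGTACGTACGT"})
        assert {(p.a_id, p.b_id) for p in pairs} == {("a", "b"), ("b", "a")}
        assert all(p.identity == 100.0 for p in pairs)

    def test_constructed_triple(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=400))
        b = _mutate_exact(rng, a, 20)  # 95%
        c = "".join(rng.choice(list("ACGT"), size=400))
        pairs = {p.a_id: p for p in
                 best_nonself_pairs({"A": a, "B": b, "C": c})}
        assert pairs["A"].b_id == "B"
        assert pairs["B"].b_id == "A"
        assert pairs["A"].identity == pytest.approx(95.0, abs=2.0)
        assert pairs["C"].identity is None or pairs["C"].identity < 60.0

    def test_matches_exhaustive_oracle(self, rng):
        """Screened best-partner choice agrees with exhaustive all-pairs
        global alignment on small sets."""
        seqs = {}
        for fam in range(4):
            base = "".join(rng.choice(list("ACGT"), size=200))
            for j in range(3):
                seqs[f"f{fam}m{j}"] = _mutate_exact(rng, base, 10 * (j + 1))
        pairs = {p.a_id: p for p in best_nonself_pairs(seqs)}
        for sid, s in seqs.items():
            oracle_best = max(
                ((oid, pairwise_identity(s, os))
                 for oid, os in seqs.items() if oid != sid),
                key=lambda kv: kv[1])
            got = pairs[sid]
            assert got.identity == pytest.approx(oracle_best[1], abs=1.0)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            best_nonself_pairs({"a": "ACGT"})

    def test_identity_histogram_modes(self):
        """Paralog-only assemblies give a single identity mode near 40%;
        adding allele pairs creates a second mode above 90%."""
        spec = GenomeSpec(n_nanochromosomes=0, n_paralog_families=10, seed=5)
        contigs, _ = generate_assembly(spec)
        idents = [p.identity for p in
                  best_nonself_pairs({c.id: c.sequence for c in contigs})
                  if p.identity is not None]
        hist, edges = np.histogram(idents, bins=np.arange(0, 101, 10))
        assert edges[np.argmax(hist)] == 40.0
        assert not any(i > 90 for i in idents)

        spec2 = GenomeSpec(n_nanochromosomes=0, n_paralog_families=10,
                           n_allele_pairs=8, seed=5)
        contigs2, _ = generate_assembly(spec2)
        idents2 = [p.identity for p in
                   best_nonself_pairs({c.id: c.sequence for c in contigs2})
                   if p.identity is not None]
        hist2, _ = np.histogram(idents2, bins=np.arange(0, 101, 10))
        assert hist2[9] >= 8  # second mode: the 16 allele contigs


class TestGreedyCluster:
    def test_pair_above_threshold_merges(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=500))
        b = _mutate_exact(rng, a, 20)  # 96%
        assert len(greedy_cluster({"a": a, "b": b}, 0.95)) == 1
        assert len(greedy_cluster({"a": a, "b": b}, 0.97)) == 2

    def test_representative_is_longest(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=500))
        b = a[:450]
        clusters = greedy_cluster({"short": b, "long": a}, 0.9)
        assert len(clusters) == 1
        assert clusters[0].representative_id == "long"

    def test_protein_families_recovered(self):
        seqs, labels = generate_protein_families(10, 10, intra_identity=0.45,
                                                 seed=3)
        clusters = greedy_cluster(seqs, 0.4)
        assert len(clusters) == 10
        assert all(len(c.member_ids) >= 2 for c in clusters)
        for c in clusters:
            assert len({labels[m] for m in c.member_ids}) == 1

    def test_invariant_under_shuffling(self, rng):
        seqs, _ = generate_protein_families(4, 5, seed=6)
        items = list(seqs.items())
        ref = [(c.representative_id, tuple(sorted(c.member_ids)))
               for c in greedy_cluster(dict(items), 0.4)]
        for _ in range(3):
            rng.shuffle(items)
            got = [(c.representative_id, tuple(sorted(c.member_ids)))
                   for c in greedy_cluster(dict(items), 0.4)]
            assert got == ref

    def test_cluster_count_monotone_in_threshold(self):
        seqs, _ = generate_protein_families(5, 4, seed=7)
        counts = [len(greedy_cluster(seqs, t))
                  for t in (0.2, 0.4, 0.6, 0.8, 0.95)]
        assert counts == sorted(counts)

    def test_fast_prescreen_matches_exhaustive(self, rng):
        """The edlib/k-mer screen never changes the clustering relative to
        exhaustive affine alignment."""
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"),
                                            size=rng.integers(80, 250)))
                for i in range(12)}
        base = "".join(rng.choice(list("ACGT"), size=200))
        seqs["d1"] = base
        seqs["d2"] = _mutate_exact(rng, base, 4)
        for t in (0.4, 0.8, 0.95):
            fast = [(c.representative_id, tuple(c.member_ids))
                    for c in greedy_cluster(seqs, t, fast=True)]
            slow = [(c.representative_id, tuple(c.member_ids))
                    for c in greedy_cluster(seqs, t, fast=False)]
            assert fast == slow


def _ceg_hsp(subj, evalue, s_span):
    return HSP("pred", subj, 90.0, evalue, 100.0, 1, s_span, 1, s_span,
               None, "A" * s_span, "A" * s_span)


class TestCompleteness:
    def test_criterion_application(self):
        ref = {"p1": 100, "p2": 100, "p3": 100, "p4": 100}
        hsps = [_ceg_hsp("p1", 1e-12, 80), _ceg_hsp("p2", 1e-12, 80),
                _ceg_hsp("p3", 1e-12, 80), _ceg_hsp("p4", 1e-8, 90)]
        report = completeness(hsps, ref)
        assert report.percent_present == 75.0
        assert report.per_protein["p4"][2] is False  # e-value too high

    def test_no_hits(self):
        assert completeness([], {"p": 100}).percent_present == 0.0

    def test_unknown_subject_rejected(self):
        with pytest.raises(KeyError):
            completeness([_ceg_hsp("x", 1e-12, 50)], {"p": 100})

    def test_planted_231_of_248(self):
        """A 248-protein reference with 231 passing hits scores 93.1%."""
        ref = {f"ceg{i}": 200 for i in range(248)}
        hsps = [_ceg_hsp(f"ceg{i}", 1e-12, 180) for i in range(231)]
        hsps += [_ceg_hsp(f"ceg{i}", 1e-12, 100) for i in range(231, 248)]
        report = completeness(hsps, ref)
        assert report.percent_present == pytest.approx(100 * 231 / 248,
                                                       abs=0.01)
        assert round(report.percent_present, 1) == 93.1
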
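"""+1 frameshift motif scanning, candidate selection and expression test."""

import numpy as np
import pytest

from nanochrom.frameshift import (FRAMESHIFT_MOTIFS, expression_comparison,
                                  frameshift_fraction, select_candidates,
                                  terminal_motif)
from nanochrom.seqio import HSP, GeneModel
from nanochrom.synthgen import (GenomeSpec, generate_assembly,
                                generate_expression, generate_frameshift_hsps)


def test_motif_list_structure():
    assert len(FRAMESHIFT_MOTIFS) == 12
    assert len(set(FRAMESHIFT_MOTIFS)) == 12
    for m in FRAMESHIFT_MOTIFS:
        assert len(m) == 6
        assert m[3:] in ("TAA", "TAG")


class TestTerminalMotif:
    def test_first_ranked_motif(self):
        assert terminal_motif("ATGGGCAAATAA") == "AAATAA"

    def test_last_ranked_motif(self):
        assert terminal_motif("ATGGGCTCCTAA") == "TCCTAA"

    def test_tga_hexamers_absent(self):
        assert terminal_motif("ATGGGCGGCTGA") is None

    def test_non_stop_end_warns(self):
        with pytest.warns(UserWarning):
            assert terminal_motif("ATGGGCAAAGGG") is None

    def test_short_or_unframed(self):
        assert terminal_motif("TAA") is None
        assert terminal_motif("ATGAAATAAX") is None  # length not /3

    def test_agrees_with_brute_force_on_random_cds(self, rng):
        """Membership of the final hexamer in the motif list, checked
        independently."""
        for _ in range(300):
            n = int(rng.integers(2, 40)) * 3
            cds = "".join(rng.choice(list("ACGT"), size=n - 3))
            cds += ["TAA", "TAG", "TGA"][rng.integers(3)]
            expect = cds[-6:] if len(cds) >= 6 and \
                cds[-6:] in FRAMESHIFT_MOTIFS else None
            assert terminal_motif(cds) == expect


def _gene(gid, n_aa):
    return GeneModel(gid, gid, "+", [(0, (n_aa + 1) * 3)],
                     protein_length=n_aa)


def _hsp(gid, subj, span, evalue=1e-40, bitscore=100.0):
    return HSP(gid, subj, 90.0, evalue, bitscore, 1, span, 1, span, None,
               "A" * span, "A" * span)


class TestSelectCandidates:
    def test_all_conjuncts_hold(self):
        genes = [_gene("g", 200)]
        cds = {"g": "ATG" + "GGC" * 199 + "AAATAA"}
        hsps = [_hsp("g", "ref", 190)]
        out = select_candidates(genes, cds, hsps, {"ref": 350})
        assert out[0].passes
        assert out[0].blast_coverage == pytest.approx(0.95)

    def test_low_coverage_fails(self):
        genes = [_gene("g", 200)]
        cds = {"g": "ATG" + "GGC" * 199 + "AAATAA"}
        hsps = [_hsp("g", "ref", 120)]  # coverage 0.6
        out = select_candidates(genes, cds, hsps, {"ref": 350})
        assert not out[0].passes

    def test_not_shorter_than_hit_fails(self):
        genes = [_gene("g", 200)]
        cds = {"g": "ATG" + "GGC" * 199 + "AAATAA"}
        hsps = [_hsp("g", "ref", 190)]
        out = select_candidates(genes, cds, hsps, {"ref": 200})
        assert not out[0].passes

    def test_top_hit_by_evalue_then_bitscore(self):
        genes = [_gene("g", 100)]
        cds = {"g": "ATG" + "GGC" * 99 + "AAATAA"}
        hsps = [_hsp("g", "worse", 95, evalue=1e-10),
                _hsp("g", "better", 95, evalue=1e-30)]
        out = select_candidates(genes, cds, hsps,
                                {"worse": 500, "better": 90})
        # top hit is 'better' (length 90, not longer than 100) -> fails
        assert out[0].top_hit_len == 90
        assert not out[0].passes

    def test_no_hit_gene_unevaluable(self):
        genes = [_gene("g", 100)]
        cds = {"g": "ATG" + "GGC" * 99 + "AAATAA"}
        out = select_candidates(genes, cds, [], {})
        assert not out[0].passes
        assert not out[0].evaluable
        assert out[0].motif == "AAATAA"

    def test_unknown_gene_id_rejected(self):
        with pytest.raises(KeyError):
            select_candidates([_gene("g", 10)], {"g": "ATG" * 10 + "TAA"},
                              [_hsp("other", "ref", 5)], {"ref": 100})

    def test_planted_truth_recovered_exactly(self):
        spec = GenomeSpec(n_nanochromosomes=200, frameshift_fraction=0.05,
                          seed=21)
        _, truth = generate_assembly(spec)
        hsps, subj = generate_frameshift_hsps(truth, seed=22,
                                              no_hit_fraction=0.3)
        cands = select_candidates(truth.genes, truth.cds_seqs, hsps, subj)
        planted = {g for g, m in truth.gene_motif.items() if m is not None}
        assert {c.gene_id for c in cands if c.passes} == planted

    def test_passing_set_monotone_in_coverage_min(self):
        spec = GenomeSpec(n_nanochromosomes=100, seed=23)
        _, truth = generate_assembly(spec)
        hsps, subj = generate_frameshift_hsps(truth, seed=24)
        sets = []
        for cov_min in (0.5, 0.8, 0.95, 0.99):
            cands = select_candidates(truth.genes, truth.cds_seqs, hsps,
                                      subj, coverage_min=cov_min)
            sets.append({c.gene_id for c in cands if c.passes})
        for a, b in zip(sets, sets[1:]):
            assert b <= a


class TestFraction:
    def test_headline_arithmetic(self):
        cands = [type("C", (), {"passes": i < 42})() for i in range(1000)]
        assert frameshift_fraction(cands, 1000) == pytest.approx(4.2)

    def test_zero(self):
        assert frameshift_fraction([], 10) == 0.0

    def test_planted_fraction_exact(self):
        spec = GenomeSpec(n_nanochromosomes=200, frameshift_fraction=0.05,
                          seed=25)
        _, truth = generate_assembly(spec)
        hsps, subj = generate_frameshift_hsps(truth, seed=26)
        cands = select_candidates(truth.genes, truth.cds_seqs, hsps, subj)
        assert frameshift_fraction(cands, 200) == pytest.approx(5.0)


class TestExpressionComparison:
    def test_null_gives_insignificant_p(self):
        expr = generate_expression([f"g{i}" for i in range(1000)],
                                   {f"g{i}" for i in range(50)}, seed=1)
        t, p, n1, n2 = expression_comparison(expr,
                                             {f"g{i}" for i in range(50)})
        assert (n1, n2) == (50, 950)
        assert p > 0.05  # no planted difference

    def test_planted_shift_detected(self):
        cand = {f"g{i}" for i in range(100)}
        expr = generate_expression([f"g{i}" for i in range(1000)], cand,
                                   seed=2, log2_effect=2.0)
        t, p, _, _ = expression_comparison(expr, cand)
        assert p < 1e-4
        assert t > 0

    def test_degenerate_constant_groups_rejected(self):
        expr = {f"a{i}": 1.0 for i in range(5)}
        expr.update({f"b{i}": 1.0 for i in range(5)})
        with pytest.raises(ValueError):
            expression_comparison(expr, {f"a{i}" for i in range(5)})

    def test_small_group_rejected(self):
        expr = {"a": 1.0, "b": 2.0, "c": 3.0}
        with pytest.raises(ValueError):
            expression_comparison(expr, {"a"})

    def test_welch_variant_runs(self):
        expr = generate_expression([f"g{i}" for i in range(100)],
                                   set(), seed=3)
        t, p, _, _ = expression_comparison(expr,
                                           {f"g{i}" for i in range(20)},
                                           variant="welch")
        assert 0 <= p <= 1
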
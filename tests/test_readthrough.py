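"""Stop-codon readthrough window extraction and amino-acid frequencies."""

import numpy as np
import pytest

from nanochrom.readthrough import (CODON_CLASSES, FOCAL_CODONS,
                                   aa_frequency_table, extract_codon_windows)
from nanochrom.seqio import HSP
from nanochrom.synthgen import generate_readthrough_hsps

AA = "ACDEFGHIKLMNPQRSTVWY"


def _hsp(q_aln, s_aln, subject_codons, evalue=1e-30):
    return HSP("q", "s", 50.0, evalue, 80.0, 1, len(q_aln.replace("-", "")),
               1, len(s_aln.replace("-", "")), 1, q_aln, s_aln,
               subject_codons)


def _window_hsp(focal_codon, aligned_aa, n_match=20, evalue=1e-30):
    """21-column ungapped alignment with the focal codon at column 10."""
    s = list("ACDEFGHIKLMNPQRSTVWYA")
    q = list(s)
    for i in range(20 - n_match):
        col = i if i < 10 else i + 1
        q[col] = "X"
    q[10] = aligned_aa
    s[10] = "*"
    codons = ["GCT"] * 21
    codons[10] = focal_codon
    return _hsp("".join(q), "".join(s), codons, evalue)


class TestExtract:
    def test_constructed_pass(self):
        wins = extract_codon_windows([_window_hsp("TAA", "Q")])
        assert len(wins) == 1
        w = wins[0]
        assert w.accepted and w.aligned_aa == "Q"
        assert w.subject_codon == "TAA"
        assert w.flank_identity == 1.0

    def test_low_flank_identity_rejected(self):
        wins = extract_codon_windows([_window_hsp("TAA", "Q", n_match=6)])
        assert not wins[0].accepted
        assert wins[0].flank_identity == pytest.approx(0.3)

    def test_evalue_gate(self):
        wins = extract_codon_windows([_window_hsp("TAA", "Q", evalue=1e-10)])
        assert not wins[0].accepted
        assert wins[0].reject_reason == "evalue"

    def test_window_near_edge_rejected(self):
        # focal codon 5 columns from the end: flank does not fit
        s = list("ACDEFGHIKLMNPQR")
        q = list(s)
        codons = ["GCT"] * 15
        codons[9] = "TAA"
        s[9] = "*"
        wins = extract_codon_windows([_hsp("".join(q), "".join(s), codons)])
        assert len(wins) == 1 and not wins[0].accepted
        assert wins[0].reject_reason == "flank"

    def test_gap_in_flank_rejected(self):
        h = _window_hsp("TAA", "Q")
        q = list(h.q_aln)
        q[4] = "-"
        h2 = _hsp("".join(q), h.s_aln, h.subject_codons)
        wins = extract_codon_windows([h2])
        assert not wins[0].accepted

    def test_missing_codons_skipped_with_warning(self):
        h = _window_hsp("TAA", "Q")
        h.subject_codons = None
        with pytest.warns(UserWarning):
            assert extract_codon_windows([h]) == []

    def test_monotone_in_identity_and_evalue(self, rng):
        hsps, _ = generate_readthrough_hsps(
            {"TAA": {"Q": 0.5, "K": 0.5}}, flank_identity=0.5,
            n_hsps=100, seed=1)
        base = sum(w.accepted for w in
                   extract_codon_windows(hsps, identity_min=0.4))
        stricter = sum(w.accepted for w in
                       extract_codon_windows(hsps, identity_min=0.6))
        tighter_e = sum(w.accepted for w in
                        extract_codon_windows(hsps, evalue_max=1e-40))
        assert stricter <= base
        assert tighter_e <= base

    def test_agrees_with_exhaustive_column_scan(self, rng):
        """Window extraction equals an independent brute-force scan over
        all alignment columns on randomized HSPs."""
        def brute_force(hsps, evalue_max=1e-20, flank=10, identity_min=0.4):
            out = []
            for h in hsps:
                if h.subject_codons is None:
                    continue
                codons = list(h.subject_codons)
                subject_cols = [i for i, ch in enumerate(h.s_aln)
                                if ch != "-"]
                for pos, col in enumerate(subject_cols):
                    codon = codons[pos].upper()
                    if codon not in FOCAL_CODONS:
                        continue
                    ok = h.evalue < evalue_max
                    cols = list(range(col - flank, col + flank + 1))
                    if cols[0] < 0 or cols[-1] >= len(h.q_aln):
                        ok = False
                    else:
                        flank_cols = [c for c in cols if c != col]
                        if any(h.q_aln[c] == "-" or h.s_aln[c] == "-"
                               for c in flank_cols):
                            ok = False
                        elif h.q_aln[col] == "-":
                            ok = False
                        else:
                            ident = np.mean([h.q_aln[c] == h.s_aln[c]
                                             for c in flank_cols])
                            ok = ok and ident >= identity_min
                    out.append((h.query_id, col, codon, ok))
            return out

        for seed in range(5):
            r = np.random.default_rng(seed)
            hsps = []
            for i in range(30):
                n = int(r.integers(5, 40))
                q = "".join(r.choice(list(AA + "-"), size=n,
                                     p=[0.045] * 20 + [0.1]))
                s_chars = list(r.choice(list(AA), size=n))
                codon_pool = list(FOCAL_CODONS) + ["GCT", "AAA", "CTT"]
                codons = [str(r.choice(codon_pool)) for _ in range(n)]
                hsps.append(HSP(f"q{i}", f"s{i}", 50.0,
                                float(r.choice([1e-30, 1e-10])), 80.0,
                                1, n, 1, n, 1, q, "".join(s_chars), codons))
            got = [(w.query_id, w.column, w.subject_codon, w.accepted)
                   for w in extract_codon_windows(hsps)]
            assert got == brute_force(hsps)


class TestFrequencies:
    def test_pure_class(self):
        wins = extract_codon_windows([_window_hsp("TAA", "Q")
                                      for _ in range(10)])
        table = aa_frequency_table(wins)
        assert table.n["TAA/TAG"] == 10
        assert table.frequencies["TAA/TAG"] == {"Q": 1.0}

    def test_all_rejected_gives_zero_n(self):
        hsps, _ = generate_readthrough_hsps({"TAA": {"Q": 1.0}},
                                            flank_identity=0.2, n_hsps=50,
                                            seed=2)
        table = aa_frequency_table(extract_codon_windows(hsps))
        assert all(n == 0 for n in table.n.values())

    def test_frequencies_sum_to_one(self):
        hsps, _ = generate_readthrough_hsps(
            {"TGA": {"C": 0.8, "W": 0.2}, "CAA": {"Q": 1.0}},
            flank_identity=0.9, n_hsps=500, seed=3)
        table = aa_frequency_table(extract_codon_windows(hsps))
        for cls, freqs in table.frequencies.items():
            if table.n[cls]:
                assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_emission_recovery_within_binomial_error(self):
        """Planted per-codon emission distributions are recovered at
        n = 2,000 within +-0.03."""
        emission = {"TGA": {"C": 0.8, "W": 0.2},
                    "TAA": {"Q": 0.7, "K": 0.3},
                    "TAG": {"Q": 0.7, "K": 0.3},
                    "CAA": {"Q": 1.0}, "CAG": {"Q": 1.0}}
        hsps, _ = generate_readthrough_hsps(emission, flank_identity=0.9,
                                            n_hsps=2000, seed=4)
        table = aa_frequency_table(extract_codon_windows(hsps))
        assert table.frequencies["TGA"]["C"] == pytest.approx(0.8, abs=0.03)
        assert table.frequencies["TAA/TAG"]["Q"] == pytest.approx(0.7,
                                                                  abs=0.03)
        assert table.frequencies["CAA/CAG"] == {"Q": 1.0}

    def test_caa_cag_mode_is_glutamine(self):
        """Positive control: canonical glutamine codons recover Q as the
        modal aligned amino acid."""
        hsps, _ = generate_readthrough_hsps(
            {"CAA": {"Q": 0.9, "E": 0.1}, "CAG": {"Q": 0.9, "E": 0.1}},
            flank_identity=0.8, n_hsps=400, seed=5)
        table = aa_frequency_table(extract_codon_windows(hsps))
        freqs = table.frequencies["CAA/CAG"]
        assert max(freqs, key=freqs.get) == "Q"
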
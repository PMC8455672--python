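"""Pfaffl relative-expression qPCR quantification and the fixed-reallocation
randomization test.

The Pfaffl method corrects the classic ΔΔCt quantification for per-gene
amplification efficiency: ratio = E_target^ΔCt_target / E_ref^ΔCt_ref with
ΔCt = mean(control Ct) − mean(sample Ct), and E = 10^(−1/slope) from a
standard-curve fit of Ct against log10 input.  Significance is assessed by
reallocating condition labels over the replicates with group sizes fixed
(REST-style), comparing |log ratio| of each reallocation to the observed
one.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, log

import numpy as np

from nanochrom.seqio import CtSet

__all__ = ["EfficiencyModel", "ExpressionRatio", "efficiency_from_slope",
           "efficiency_from_standard_curve", "pfaffl_ratio",
           "randomization_test"]


@dataclass
class EfficiencyModel:
    slope: float
    efficiency: float


@dataclass
class ExpressionRatio:
    gene: str
    ratio: float
    p_value: float | None = None


def efficiency_from_slope(slope: float) -> EfficiencyModel:
    """E = 10^(−1/slope) for a negative standard-curve slope.

    A perfectly efficient reaction doubles product each cycle: E = 2 at
    slope = −1/log10(2) ≈ −3.3219.
    """
    if slope >= 0:
        raise ValueError(f"standard-curve slope must be negative, got {slope}")
    return EfficiencyModel(slope=slope, efficiency=10.0 ** (-1.0 / slope))


def efficiency_from_standard_curve(log10_inputs, cts) -> EfficiencyModel:
    """Fit Ct vs log10(input) by least squares and invert the slope."""
    slope, _ = np.polyfit(np.asarray(log10_inputs, float),
                          np.asarray(cts, float), 1)
    return efficiency_from_slope(float(slope))


def _delta_ct(ctset: CtSet) -> float:
    if not ctset.control_cts or not ctset.sample_cts:
        raise ValueError(f"{ctset.gene}: empty replicate list")
    return float(np.mean(ctset.control_cts) - np.mean(ctset.sample_cts))


def _log_ratio(tc, ts, rc, rs, e_target: float, e_ref: float) -> float:
    dct_t = float(np.mean(tc) - np.mean(ts))
    dct_r = float(np.mean(rc) - np.mean(rs))
    return dct_t * log(e_target) - dct_r * log(e_ref)


def pfaffl_ratio(target: CtSet, reference: CtSet,
                 e_target: float, e_ref: float) -> ExpressionRatio:
    """Efficiency-corrected relative expression of the target gene,
    normalized to the reference gene."""
    if e_target <= 1 or e_ref <= 1:
        raise ValueError("efficiencies must exceed 1")
    ratio = (e_target ** _delta_ct(target)) / (e_ref ** _delta_ct(reference))
    return ExpressionRatio(gene=target.gene, ratio=ratio)


def randomization_test(target: CtSet, reference: CtSet,
                       e_target: float, e_ref: float,
                       n_iter: int = 2000, seed: int = 0,
                       paired: bool = True) -> float:
    """Fixed-reallocation randomization p-value for the Pfaffl ratio.

    Condition labels are reallocated over replicates with group sizes
    fixed.  In the default paired variant the i-th target and reference
    replicates swap together (they come from the same cDNA sample); the
    independent variant reallocates the two genes separately.  Two-sided:
    p = (1 + #{|log ratio_perm| >= |log ratio_obs|}) / (1 + N).  When the
    number of distinct reallocations is at most ``n_iter`` they are
    enumerated exhaustively and p = #{>=} / total.
    """
    tc, ts = list(target.control_cts), list(target.sample_cts)
    rc, rs = list(reference.control_cts), list(reference.sample_cts)
    n1, n2 = len(tc), len(ts)
    if paired and (len(rc) != n1 or len(rs) != n2):
        raise ValueError("paired reallocation needs matching replicate "
                         "counts between target and reference")
    if comb(n1 + n2, n1) < 2:
        raise ValueError("insufficient replicates for a randomization test")
    obs = abs(_log_ratio(tc, ts, rc, rs, e_target, e_ref))
    eps = 1e-12

    if paired:
        pairs = [(t, r) for t, r in zip(tc, rc)] + \
                [(t, r) for t, r in zip(ts, rs)]

        def stat(control_idx: tuple[int, ...]) -> float:
            cset = set(control_idx)
            ctl = [pairs[i] for i in range(len(pairs)) if i in cset]
            smp = [pairs[i] for i in range(len(pairs)) if i not in cset]
            return abs(_log_ratio([p[0] for p in ctl], [p[0] for p in smp],
                                  [p[1] for p in ctl], [p[1] for p in smp],
                                  e_target, e_ref))

        total = comb(n1 + n2, n1)
        if total <= n_iter:
            count = sum(stat(idx) >= obs - eps
                        for idx in combinations(range(n1 + n2), n1))
            return count / total
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_iter):
            perm = rng.permutation(n1 + n2)
            count += stat(tuple(perm[:n1])) >= obs - eps
        return (1 + count) / (1 + n_iter)

    # independent reallocation of the two genes
    t_all, r_all = tc + ts, rc + rs
    m1 = len(rc)
    rng = np.random.default_rng(seed)
    total = comb(n1 + n2, n1) * comb(len(r_all), m1)
    if total <= n_iter:
        count = tries = 0
        for tidx in combinations(range(n1 + n2), n1):
            for ridx in combinations(range(len(r_all)), m1):
                tset, rset = set(tidx), set(ridx)
                s = abs(_log_ratio(
                    [t_all[i] for i in tset],
                    [t_all[i] for i in range(n1 + n2) if i not in tset],
                    [r_all[i] for i in rset],
                    [r_all[i] for i in range(len(r_all)) if i not in rset],
                    e_target, e_ref))
                count += s >= obs - eps
                tries += 1
        return count / tries
    count = 0
    for _ in range(n_iter):
        tperm = rng.permutation(n1 + n2)
        rperm = rng.permutation(len(r_all))
        s = abs(_log_ratio([t_all[i] for i in tperm[:n1]],
                           [t_all[i] for i in tperm[n1:]],
                           [r_all[i] for i in rperm[:m1]],
                           [r_all[i] for i in rperm[m1:]],
                           e_target, e_ref))
        count += s >= obs - eps
    return (1 + count) / (1 + n_iter)
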
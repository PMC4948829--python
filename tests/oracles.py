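"""Independent brute-force oracles used by the tests.

These deliberately re-derive results by the most transparent method
available (exhaustive recursion/enumeration), independent of the package's
implementation paths.
"""

from __future__ import annotations

import functools
from math import comb

import numpy as np

from telodiverge.caller import AlignmentScoring


def alignment_score_oracle(ref: str, clone: str, sc: AlignmentScoring | None = None) -> float:
    """Exhaustive DP over explicit alignment states: left-anchored, may stop
    anywhere (both distal remainders free), affine gaps that may open from
    any state."""
    sc = sc or AlignmentScoring()

    @functools.lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        if i == len(ref) or j == len(clone):
            return 0.0
        s = sc.match if ref[i] == clone[j] else sc.mismatch
        return max(
            0.0,  # stop here; the rest of both sequences is a free tail
            s + best(i + 1, j + 1, "M"),
            (sc.gap_extend if state == "X" else sc.gap_open) + best(i + 1, j, "X"),
            (sc.gap_extend if state == "Y" else sc.gap_open) + best(i, j + 1, "Y"),
        )

    out = best(0, 0, "M")
    best.cache_clear()
    return out


def fisher_exact_oracle(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher's exact p by full hypergeometric enumeration:
    sum of the probabilities of all tables (with the observed margins) at
    most as probable as the observed one."""
    K, N = k1 + k2, n1 + n2

    def prob(k: int) -> float:
        return comb(n1, k) * comb(n2, K - k) / comb(N, K)

    p_obs = prob(k1)
    lo, hi = max(0, K - n2), min(n1, K)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-12))


def permutation_test_oracle(a, b, n_shuffles: int, rng: np.random.Generator) -> float:
    """Two-sided permutation test on the difference of group means."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    obs = abs(a.mean() - b.mean())
    mat = np.tile(pooled, (n_shuffles, 1))
    mat = rng.permuted(mat, axis=1)
    diffs = np.abs(mat[:, : len(a)].mean(axis=1) - mat[:, len(a):].mean(axis=1))
    return float((np.sum(diffs >= obs - 1e-12) + 1) / (n_shuffles + 1))
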
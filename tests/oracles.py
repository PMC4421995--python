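"""Independent brute-force oracles used to validate the package's algorithms.

Every function here recomputes a quantity by enumeration, closed form or
direct linear algebra, sharing no code with the implementation it checks.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np

from decaydet.folding import MIN_HAIRPIN, PAIR_ENERGY, STACK_BONUS


def brute_force_mfe(seq: str) -> float:
    """Minimum energy over explicit enumeration of all nested structures."""
    seq = seq.upper().replace("T", "U")
    n = len(seq)

    def pair_ok(i, j):
        return (seq[i], seq[j]) in PAIR_ENERGY and j - i - 1 >= MIN_HAIRPIN

    def enum(i, j):
        if j - i + 1 < MIN_HAIRPIN + 2:
            yield frozenset()
            return
        yield from enum(i + 1, j)
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            if pair_ok(i, k):
                inners = list(enum(i + 1, k - 1))
                outers = list(enum(k + 1, j)) if k < j else [frozenset()]
                for inner in inners:
                    for outer in outers:
                        yield frozenset({(i, k)}) | inner | outer

    best = 0.0
    for struct in enum(0, n - 1):
        e = 0.0
        for (i, j) in struct:
            e += PAIR_ENERGY[(seq[i], seq[j])]
            if (i + 1, j - 1) in struct:
                e += STACK_BONUS
        best = min(best, e)
    return best


def dimer_counts(s: str) -> Counter:
    return Counter(s[i:i + 2] for i in range(len(s) - 1))


def valid_shuffles(seq: str) -> set[str]:
    """All permutations with identical dinucleotide counts and fixed ends."""
    ref = dimer_counts(seq)
    return {
        "".join(p) for p in set(itertools.permutations(seq))
        if p[0] == seq[0] and p[-1] == seq[-1]
        and dimer_counts("".join(p)) == ref
    }


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Coefficients via the explicit (X'X)^-1 X'y solution."""
    return np.linalg.solve(X.T @ X, X.T @ y)


def exhaustive_best_subset(design, scope) -> tuple[list[str], float]:
    """Minimize n*ln(RSS/n) + 2N over all 2^k term subsets."""
    n = len(design.y)
    best_terms, best_crit = None, math.inf
    for r in range(len(scope) + 1):
        for combo in itertools.combinations(sorted(scope), r):
            X = design.X[design.columns_for(list(combo))].to_numpy()
            coef, res, rank, _ = np.linalg.lstsq(X, design.y, rcond=None)
            rss = float(res[0]) if res.size else float(
                np.sum((design.y - X @ coef) ** 2))
            crit = -math.inf if rss <= 0 else n * math.log(rss / n) + 2 * X.shape[1]
            # same tie-breaking as the stepwise search: smaller model first
            if crit < best_crit - 1e-10:
                best_terms, best_crit = list(combo), crit
    return sorted(best_terms), best_crit


def geometric_mean_cai(orf: str, w: dict[str, float],
                       informative) -> float:
    """Spreadsheet-style CAI: exp(mean(ln w)) over informative codons."""
    logs = [math.log(w[orf[i:i + 3]]) for i in range(0, len(orf), 3)
            if informative(orf[i:i + 3])]
    return math.exp(sum(logs) / len(logs))


def simulate_m1(P: np.ndarray, mu: np.ndarray, length: int, n_chains: int,
                rng: np.random.Generator) -> np.ndarray:
    """Vectorized sampling of first-order Markov chains (integer states)."""
    cum = P.cumsum(axis=1)
    states = np.empty((n_chains, length), dtype=np.int8)
    states[:, 0] = rng.choice(4, size=n_chains, p=mu)
    u = rng.random((n_chains, length))
    for t in range(1, length):
        states[:, t] = (cum[states[:, t - 1]] < u[:, [t]]).sum(axis=1)
    return states


def count_word_in_chains(states: np.ndarray, word_idx) -> np.ndarray:
    """Overlapping occurrence count of an index-encoded word per chain."""
    L = states.shape[1]
    k = len(word_idx)
    m = np.ones((states.shape[0], L - k + 1), dtype=bool)
    for off, i in enumerate(word_idx):
        m &= states[:, off:L - k + 1 + off] == i
    return m.sum(axis=1)
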
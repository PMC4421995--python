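"""5'UTR word exceptionality under a first-order Markov null.

All 1024 five-nucleotide words are scored in a set of 5'UTR sequences
(each truncated to its last 100 nt before the start codon): the observed
overlapping count is compared with the count expected under a first-order
Markov (M1) chain fitted to the set's pooled dinucleotide composition,

    E(w) = sum_seq (L_seq - 4) * mu(w1) * prod_i p(w_i | w_{i-1}).

The Gaussian approximation gives the p-value: the statistic
``N(w) - E_hat(w)`` (observed minus plug-in expected) is asymptotically
normal, with a variance that accounts for word self-overlap and for the
fact that the M1 parameters are estimated from the same sequences (delta
method over the joint word-count covariances of the stationary chain).
Scores are the probit transform of the p-value, so overrepresented words
get high positive scores and the score of a null word is ~N(0, 1).

An optional empirical null -- dinucleotide-preserving shuffling of every
sequence in the set -- samples the exact conditional distribution given
the dinucleotide composition and overrides the analytic p-value when
enabled; it serves as the in-repo oracle for the Gaussian approximation.

Quartile comparison: genes with a mapped 5'UTR and a half-life at the
growth rate of interest are ranked by half-life; the top and bottom
``ceil(0.25 n)`` form the stable and unstable sets, words are scored in
each, and words much more exceptional in the stable set are reported as
candidate stabilizing motifs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from .features import effective_utr5
from .folding import dinucleotide_shuffle
from .io_core import GeneRecord

BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(BASES)}

#: motif search window: at most this many nt immediately upstream of the start
SEARCH_WINDOW = 100
WORD_LENGTH = 5

ALL_WORDS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product(BASES, repeat=WORD_LENGTH))


@dataclass
class MotifScore:
    """Observed vs expected statistics of one word in one sequence set."""

    word: str
    observed: int
    expected: float
    variance: float
    pvalue: float
    score: float
    set_label: str = ""
    scorable: bool = True


@dataclass
class QuartileSplit:
    """Most- and least-stable gene quartiles at one growth rate."""

    growth_rate: str
    stable_ids: list[str]
    unstable_ids: list[str]

    @property
    def set_size(self) -> int:
        return len(self.stable_ids)


def truncate_utr(seq: str) -> str:
    """Restrict a 5'UTR to the search window next to the start codon."""
    return seq[-SEARCH_WINDOW:]


def count_word(word: str, sequences: Sequence[str]) -> int:
    """Total overlapping occurrences over truncated sequences.

    Counting never crosses a sequence boundary.
    """
    word = _norm_word(word)
    total = 0
    for seq in sequences:
        seq = truncate_utr(str(seq).upper().replace("U", "T"))
        for i in range(len(seq) - len(word) + 1):
            if seq[i:i + len(word)] == word:
                total += 1
    return total


def _norm_word(word: str) -> str:
    return str(word).upper().replace("U", "T")


def _count_all_words(sequences: Sequence[str], k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for seq in sequences:
        for i in range(len(seq) - k + 1):
            w = seq[i:i + k]
            counts[w] = counts.get(w, 0) + 1
    return counts


class M1Null:
    """Word-count moments under a stationary first-order Markov chain.

    Parametrized by the 4x4 transition matrix ``P`` and its stationary
    distribution; exposes the expected count, and the asymptotic variance
    of ``N(w) - E_hat(w)`` when the chain is estimated from the scored
    sequences themselves (plug-in of dinucleotide and interior-letter
    counts).
    """

    def __init__(self, P: np.ndarray, lengths: Sequence[int],
                 word_length: int = WORD_LENGTH):
        self.P = np.asarray(P, dtype=float)
        if self.P.shape != (4, 4):
            raise ValueError("P must be 4x4")
        self.lengths = [int(x) for x in lengths]
        self.k = word_length
        self.mu = self._stationary(self.P)
        # fundamental-matrix tail sum: M = sum_{m>=1} (P^m - 1 mu) = Z - I
        Z = np.linalg.inv(np.eye(4) - self.P + np.outer(np.ones(4), self.mu))
        self.M = Z - np.eye(4)
        self.n_letters = sum(self.lengths)
        self.n_pairs = sum(max(L - 1, 0) for L in self.lengths)
        self.n_positions = sum(max(L - self.k + 1, 0) for L in self.lengths)
        self._cov_cache: dict[tuple[str, str], float] = {}

    @staticmethod
    def _stationary(P: np.ndarray) -> np.ndarray:
        vals, vecs = np.linalg.eig(P.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        mu = np.real(vecs[:, i])
        mu = np.abs(mu)
        return mu / mu.sum()

    @classmethod
    def from_sequences(cls, sequences: Sequence[str],
                       word_length: int = WORD_LENGTH) -> "M1Null":
        pairs = np.zeros((4, 4))
        lengths = []
        for seq in sequences:
            lengths.append(len(seq))
            for a, b in zip(seq, seq[1:]):
                pairs[_IDX[a], _IDX[b]] += 1
        rows = pairs.sum(axis=1, keepdims=True)
        P = np.divide(pairs, rows, out=np.full((4, 4), 0.25), where=rows > 0)
        return cls(P, lengths, word_length)

    # -- first moments -----------------------------------------------------

    def pi(self, word: str) -> float:
        """Stationary occurrence probability of ``word`` at a fixed position."""
        p = self.mu[_IDX[word[0]]]
        for a, b in zip(word, word[1:]):
            p *= self.P[_IDX[a], _IDX[b]]
        return float(p)

    def expected(self, word: str) -> float:
        n_pos = sum(max(L - len(word) + 1, 0) for L in self.lengths)
        return n_pos * self.pi(word)

    # -- covariances -------------------------------------------------------

    def _merge(self, u: str, v: str, t: int) -> str | None:
        """Overlay ``v`` starting at offset ``t`` of ``u``; None on clash."""
        lo = min(0, t)
        hi = max(len(u), t + len(v))
        out = []
        for pos in range(lo, hi):
            a = u[pos] if 0 <= pos < len(u) else None
            b = v[pos - t] if 0 <= pos - t < len(v) else None
            if a is not None and b is not None and a != b:
                return None
            out.append(a if a is not None else b)
        return "".join(out)

    def cov_rate(self, u: str, v: str) -> float:
        """Asymptotic per-letter covariance of the counts of ``u`` and ``v``."""
        key = (u, v) if u <= v else (v, u)
        if key in self._cov_cache:
            return self._cov_cache[key]
        u, v = key
        pu, pv = self.pi(u), self.pi(v)
        s = 0.0
        for t in range(-(len(v) - 1), len(u)):
            merged = self._merge(u, v, t)
            s += (self.pi(merged) if merged is not None else 0.0) - pu * pv
        mu = self.mu
        s += pu * pv * (self.M[_IDX[u[-1]], _IDX[v[0]]] / mu[_IDX[v[0]]]
                        + self.M[_IDX[v[-1]], _IDX[u[0]]] / mu[_IDX[u[0]]])
        self._cov_cache[key] = s
        return s

    def variance(self, word: str) -> float:
        """Asymptotic variance of ``N(w) - E_hat(w)`` with estimated M1.

        The plug-in expectation uses the counts of the word's 4 dinucleotide
        steps and 3 interior letters; linearizing it and applying the joint
        Gaussian limit of word counts yields
        ``Var = n * c' Sigma c`` over the involved words.
        """
        E_w = self.expected(word)
        items: list[tuple[str, float]] = [(word, 1.0)]
        steps: dict[str, int] = {}
        for a, b in zip(word, word[1:]):
            steps[a + b] = steps.get(a + b, 0) + 1
        for d, mult in steps.items():
            E_d = self.n_pairs * self.pi(d)
            items.append((d, -E_w * mult / E_d))
        interior: dict[str, int] = {}
        for a in word[1:-1]:
            interior[a] = interior.get(a, 0) + 1
        for a, mult in interior.items():
            E_a = self.n_pairs * self.mu[_IDX[a]]
            items.append((a, E_w * mult / E_a))
        var = 0.0
        for (w1, c1), (w2, c2) in itertools.product(items, repeat=2):
            var += c1 * c2 * self.cov_rate(w1, w2)
        return var * self.n_letters


def score_exceptionality(
    sequences: Sequence[str],
    word_length: int = WORD_LENGTH,
    set_label: str = "",
    empirical_null: int = 0,
    rng: np.random.Generator | None = None,
) -> dict[str, MotifScore]:
    """Score every word of ``word_length`` in a sequence set.

    With ``empirical_null = B > 0`` the p-value comes from ``B``
    dinucleotide-preserving shuffles of every sequence (add-one rank
    p-value) instead of the Gaussian approximation; the score remains the
    probit of the p-value in both cases.  Words containing a dinucleotide
    never observed in the set are flagged unscorable.
    """
    seqs = [truncate_utr(_norm_word(s)) for s in sequences if len(s) > 0]
    pooled = sum(len(s) for s in seqs)
    if pooled < 1000:
        import warnings
        warnings.warn(f"pooled sequence length {pooled} < 1000 nt; "
                      "exceptionality scores will be noisy")
    null = M1Null.from_sequences(seqs, word_length)
    counts = _count_all_words(seqs, word_length)
    words = ["".join(p) for p in itertools.product(BASES, repeat=word_length)]

    shuffle_counts: dict[str, np.ndarray] | None = None
    if empirical_null > 0:
        rng = rng if rng is not None else np.random.default_rng()
        shuffle_counts = {w: np.zeros(empirical_null) for w in words}
        for b in range(empirical_null):
            shuffled = [dinucleotide_shuffle(s, rng) for s in seqs]
            for w, c in _count_all_words(shuffled, word_length).items():
                shuffle_counts[w][b] = c

    out: dict[str, MotifScore] = {}
    for w in words:
        obs = counts.get(w, 0)
        exp = null.expected(w)
        if exp <= 0:
            out[w] = MotifScore(w, obs, exp, math.nan, math.nan, math.nan,
                                set_label, scorable=False)
            continue
        if shuffle_counts is not None:
            sims = shuffle_counts[w]
            var = float(np.var(sims, ddof=1))
            B = len(sims)
            p_over = (1 + np.sum(sims >= obs)) / (B + 1)
            p_under = (1 + np.sum(sims <= obs)) / (B + 1)
            # mid-offset keeps the probit finite and sign-consistent
            score = float(stats.norm.ppf(1 - p_over)) if obs >= np.median(sims) \
                else float(stats.norm.ppf(p_under))
            pval = p_over if obs >= np.median(sims) else p_under
        else:
            var = null.variance(w)
            if var <= 0:
                if abs(obs - exp) < 1e-6:
                    # deterministic count (e.g. homopolymer set): no deviation
                    out[w] = MotifScore(w, obs, exp, var, 0.5, 0.0, set_label)
                else:
                    out[w] = MotifScore(w, obs, exp, var, math.nan, math.nan,
                                        set_label, scorable=False)
                continue
            z = (obs - exp) / math.sqrt(var)
            pval = float(stats.norm.sf(z)) if z >= 0 else float(stats.norm.cdf(z))
            score = z
        out[w] = MotifScore(w, obs, exp, var, float(pval), score, set_label)
    return out


# ---------------------------------------------------------------------------
# quartile comparison


def eligible_records(records: Sequence[GeneRecord],
                     growth_rate: str) -> list[tuple[GeneRecord, str]]:
    """Genes with a nonempty truncated 5'UTR and a half-life at this rate."""
    out = []
    for rec in records:
        utr = truncate_utr(effective_utr5(rec))
        if utr and growth_rate in rec.half_life:
            out.append((rec, utr))
    return out


def quartile_split(records: Sequence[GeneRecord],
                   growth_rate: str) -> QuartileSplit:
    """Top/bottom ``ceil(0.25 n)`` of eligible genes ranked by half-life."""
    elig = eligible_records(records, growth_rate)
    n = len(elig)
    size = quartile_size(n)
    ranked = sorted(elig, key=lambda e: (-e[0].half_life[growth_rate],
                                         e[0].gene_id))
    stable = [r.gene_id for r, _ in ranked[:size]]
    unstable = [r.gene_id for r, _ in ranked[-size:]]
    return QuartileSplit(growth_rate, stable, unstable)


def quartile_size(n_eligible: int) -> int:
    """``ceil(0.25 n)``: 1937 eligible 5'UTRs give sets of 485."""
    return math.ceil(0.25 * n_eligible)


def compare_quartiles(
    records: Sequence[GeneRecord],
    growth_rate: str,
    score_diff_threshold: float = 3.0,
    stable_score_threshold: float = 3.0,
    empirical_null: int = 0,
    rng: np.random.Generator | None = None,
) -> dict:
    """Score words in the stable and unstable quartiles and call differences.

    Differential words are exceptional in the stable set (score above
    ``stable_score_threshold``) and clearly more so than in the unstable
    set (score difference above ``score_diff_threshold``).
    """
    elig = eligible_records(records, growth_rate)
    if len(elig) < 40:
        raise ValueError(f"only {len(elig)} eligible genes at mu={growth_rate}; "
                         "need at least 40")
    split = quartile_split(records, growth_rate)
    utr_by_id = {rec.gene_id: utr for rec, utr in elig}
    stable_seqs = [utr_by_id[g] for g in split.stable_ids]
    unstable_seqs = [utr_by_id[g] for g in split.unstable_ids]
    scores_stable = score_exceptionality(
        stable_seqs, set_label="stable", empirical_null=empirical_null, rng=rng)
    scores_unstable = score_exceptionality(
        unstable_seqs, set_label="unstable", empirical_null=empirical_null, rng=rng)
    differential = []
    for w in scores_stable:
        s, u = scores_stable[w], scores_unstable[w]
        if not (s.scorable and u.scorable):
            continue
        if (s.score >= stable_score_threshold
                and s.score - u.score >= score_diff_threshold):
            differential.append(w)
    differential.sort(
        key=lambda w: scores_unstable[w].score - scores_stable[w].score)
    return {
        "split": split,
        "stable": scores_stable,
        "unstable": scores_unstable,
        "differential": differential,
    }


# ---------------------------------------------------------------------------
# motif placement and effect on half-life


@dataclass
class PositionProfile:
    """Distances from each motif occurrence to the start codon.

    Distance counts the nucleotides between the word's 3' end and the first
    base of the start codon: a word ending immediately before the ATG is at
    distance 0.
    """

    word: str
    distances: list[int]

    def fraction_in_window(self, a: int, b: int) -> float:
        if not self.distances:
            return math.nan
        hits = sum(1 for d in self.distances if a <= d <= b)
        return hits / len(self.distances)


def motif_position_profile(word: str,
                           records: Sequence[GeneRecord]) -> PositionProfile:
    """All occurrence distances of ``word`` over the truncated 5'UTRs."""
    word = _norm_word(word)
    distances = []
    for rec in records:
        utr = truncate_utr(effective_utr5(rec))
        for i in range(len(utr) - len(word) + 1):
            if utr[i:i + len(word)] == word:
                distances.append(len(utr) - (i + len(word)))
    return PositionProfile(word, distances)


def motif_halflife_shift(records: Sequence[GeneRecord], word: str,
                         growth_rate: str) -> dict:
    """Half-life distribution of motif-bearing mRNAs vs the whole population.

    Returns notched five-number summaries for both groups plus whether the
    two notch intervals are disjoint (in which case the medians differ with
    ~95% confidence).
    """
    from .decay_structure import summarize_distribution

    word = _norm_word(word)
    elig = eligible_records(records, growth_rate)
    if not elig:
        raise ValueError(f"no eligible genes at mu={growth_rate}")
    all_vals = [rec.half_life[growth_rate] for rec, _ in elig]
    with_vals = [rec.half_life[growth_rate] for rec, utr in elig if word in utr]
    if not with_vals:
        raise ValueError(f"motif {word} absent from all eligible 5'UTRs")
    all_summary = summarize_distribution(all_vals)
    sub_summary = summarize_distribution(with_vals)
    nonoverlap = (sub_summary.notch_low > all_summary.notch_high
                  or sub_summary.notch_high < all_summary.notch_low)
    return {"all": all_summary, "with_motif": sub_summary,
            "nonoverlap": bool(nonoverlap)}
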
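"""Thermodynamic-stability Z score of the start-codon region.

For each transcript the region from 30 nt upstream to 24 nt downstream of
the start codon (positions -30..-1 and +1..+24; there is no position 0) is
folded, and its minimum free energy (MFE) is compared with the MFE of
dinucleotide-preserving shuffles of the same region:

    Z = (native MFE - mean shuffled MFE) / SD of shuffled MFEs.

A negative Z marks a region folding more stably than expected from its
dinucleotide composition.  Shuffling preserves the exact dinucleotide count
multiset (Euler-path construction, first and last bases fixed), which is
the sufficient statistic of a first-order Markov chain.

Folding engines
---------------
``bundled``
    A nested-structure dynamic program over {GC, AU, GU} base pairs with a
    per-pair energy, a stacking bonus for directly stacked pairs and a
    minimum hairpin loop of 3 nt.  The energy constants are deliberately
    simple (documented below); Z scores are engine-relative, so only the
    *ranking* of native vs shuffled energies matters.
``vienna``
    Adapter invoking the external ``RNAfold`` command-line folder
    (nearest-neighbor model) when a full thermodynamic model is wanted.
"""

from __future__ import annotations

import math
import subprocess
from dataclasses import dataclass, field

import numpy as np

from .features import effective_utr5
from .io_core import GeneRecord

#: kcal/mol per closing pair, bundled engine.
PAIR_ENERGY = {("G", "C"): -3.0, ("C", "G"): -3.0,
               ("A", "U"): -2.0, ("U", "A"): -2.0,
               ("G", "U"): -1.0, ("U", "G"): -1.0}
#: bonus when a pair is directly stacked on the enclosed pair.
STACK_BONUS = -1.0
#: minimum number of unpaired bases in a hairpin loop.
MIN_HAIRPIN = 3

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}
_ENERGY4 = np.full((4, 4), np.inf)
for (_a, _b), _e in PAIR_ENERGY.items():
    _ENERGY4[_BASE_INDEX[_a], _BASE_INDEX[_b]] = _e


@dataclass
class ZScoreResult:
    """Native and shuffled MFEs plus the resulting Z score for one region."""

    gene_id: str
    region: str
    native_mfe: float
    shuffle_mfes: np.ndarray
    zscore: float | None
    truncated: bool
    engine: str = "bundled"


def _to_rna(seq: str) -> str:
    return str(seq).upper().replace("T", "U")


def _encode(seqs: list[str]) -> np.ndarray:
    arr = np.empty((len(seqs), len(seqs[0])), dtype=np.int8)
    for i, s in enumerate(seqs):
        arr[i] = [_BASE_INDEX[c] for c in s]
    return arr


def fold_mfe_batch(seqs: list[str]) -> np.ndarray:
    """Bundled-engine MFE for equal-length sequences, vectorized over the batch.

    ``W[i, j]`` is the minimum energy of any nested structure on ``i..j`` and
    ``V[i, j]`` the minimum given that ``(i, j)`` is paired; the stacking
    bonus applies when ``(i+1, j-1)`` is also paired.  The empty structure
    (energy 0) is always admissible, so the result is <= 0.
    """
    if not seqs:
        return np.zeros(0)
    n = len(seqs[0])
    if any(len(s) != n for s in seqs):
        raise ValueError("fold_mfe_batch requires equal-length sequences")
    B = len(seqs)
    if n < MIN_HAIRPIN + 2:
        return np.zeros(B)
    s = _encode([_to_rna(x) for x in seqs])
    V = np.full((B, n, n), np.inf)
    W = np.zeros((B, n, n))
    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(n - span):
            j = i + span
            e = _ENERGY4[s[:, i], s[:, j]]
            inner = W[:, i + 1, j - 1]
            if span >= MIN_HAIRPIN + 3:
                inner = np.minimum(inner, V[:, i + 1, j - 1] + STACK_BONUS)
            V[:, i, j] = e + inner
            best = W[:, i, j - 1].copy()
            # j paired with k, for k in i..j-(MIN_HAIRPIN+1)
            ks_hi = j - MIN_HAIRPIN - 1
            if ks_hi >= i:
                vk = V[:, i:ks_hi + 1, j]
                left = np.concatenate(
                    [np.zeros((B, 1)), W[:, i, i:ks_hi]], axis=1)
                best = np.minimum(best, (left + vk).min(axis=1))
            W[:, i, j] = best
    return W[:, 0, n - 1]


def fold_mfe(seq: str, engine: str = "bundled") -> float:
    """Minimum free folding energy (kcal/mol) of one sequence."""
    if engine == "bundled":
        if len(seq) == 0:
            raise ValueError("cannot fold an empty sequence")
        return float(fold_mfe_batch([seq])[0])
    if engine == "vienna":
        return _fold_vienna(seq)
    raise ValueError(f"unknown folding engine {engine!r}")


def _fold_vienna(seq: str) -> float:
    """External-engine adapter: parse the MFE printed by ``RNAfold --noPS``."""
    out = subprocess.run(
        ["RNAfold", "--noPS"], input=_to_rna(seq) + "\n",
        capture_output=True, text=True, check=True,
    ).stdout
    last = out.strip().splitlines()[-1]
    return float(last[last.rindex("(") + 1:last.rindex(")")])


# ---------------------------------------------------------------------------
# dinucleotide-preserving shuffle


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Random shuffle preserving the exact dinucleotide count multiset.

    Altschul-Erickson Euler-path construction: the sequence is a walk on the
    graph whose edges are its dinucleotides.  For every vertex other than
    the final base a random "last exit" edge is drawn (redrawn until the
    last-exit edges form an arborescence into the final base), the remaining
    edges are permuted uniformly, and the walk is replayed.  First and last
    bases are preserved; every valid shuffle has positive probability.
    """
    seq = str(seq)
    if len(seq) < 2 or len(set(seq)) == 1:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    first, last = seq[0], seq[-1]
    vertices = [v for v in edges if v != last]

    while True:
        last_exit = {v: edges[v][rng.integers(len(edges[v]))] for v in vertices}
        if all(_reaches(v, last, last_exit) for v in vertices):
            break

    pools: dict[str, list[str]] = {}
    for v, out in edges.items():
        rest = list(out)
        if v != last:
            rest.remove(last_exit[v])
        perm = rng.permutation(len(rest))
        rest = [rest[i] for i in perm]
        if v != last:
            rest.append(last_exit[v])
        else:
            pass
        pools[v] = rest
    if last in pools:
        perm = rng.permutation(len(pools[last]))
        pools[last] = [pools[last][i] for i in perm]

    out_chars = [first]
    cursor = {v: 0 for v in pools}
    cur = first
    for _ in range(len(seq) - 1):
        nxt = pools[cur][cursor[cur]]
        cursor[cur] += 1
        out_chars.append(nxt)
        cur = nxt
    return "".join(out_chars)


def _reaches(v: str, last: str, last_exit: dict[str, str]) -> bool:
    seen = set()
    while v != last:
        if v in seen or v not in last_exit:
            return False
        seen.add(v)
        v = last_exit[v]
    return True


# ---------------------------------------------------------------------------
# Z score

#: region extent around the start codon (paper-standard -30/+24 window).
UPSTREAM_NT = 30
DOWNSTREAM_NT = 24


def region_around_start(record: GeneRecord) -> tuple[str, bool]:
    """The -30/+24 region: last <=30 5'UTR nt plus first <=24 ORF nt."""
    utr = effective_utr5(record)
    up = utr[-UPSTREAM_NT:]
    down = record.orf_seq[:DOWNSTREAM_NT]
    truncated = len(up) < UPSTREAM_NT or len(down) < DOWNSTREAM_NT
    return up + down, truncated


def compute_zscore(
    record: GeneRecord,
    n_shuffles: int = 100,
    rng: np.random.Generator | None = None,
    engine: str = "bundled",
    require_utr: bool = True,
) -> ZScoreResult:
    """Folding Z score of a gene's start-codon region.

    Genes with no mapped 5'UTR get a missing Z score unless ``require_utr``
    is disabled (in which case the ORF-only window is used and flagged as
    truncated).  A degenerate shuffle set (SD below tolerance, e.g. for
    homopolymeric regions) also yields a missing Z score.
    """
    rng = rng if rng is not None else np.random.default_rng()
    utr = effective_utr5(record)
    if not utr and require_utr:
        region, _ = region_around_start(record)
        return ZScoreResult(record.gene_id, region, math.nan,
                            np.empty(0), None, True, engine)
    region, truncated = region_around_start(record)
    if not region:
        raise ValueError(f"{record.gene_id}: empty folding region")
    shuffles = [dinucleotide_shuffle(region, rng) for _ in range(n_shuffles)]
    if engine == "bundled":
        energies = fold_mfe_batch([region] + shuffles)
    else:
        energies = np.array([fold_mfe(s, engine) for s in [region] + shuffles])
    native, shuffled = float(energies[0]), energies[1:]
    sd = float(np.std(shuffled, ddof=1)) if len(shuffled) > 1 else 0.0
    z = (native - float(np.mean(shuffled))) / sd if sd > 1e-9 else None
    return ZScoreResult(record.gene_id, region, native, shuffled, z,
                        truncated, engine)


def zscores_for_records(
    records, n_shuffles: int = 100, seed: int = 0, engine: str = "bundled",
) -> dict[str, float | None]:
    """Z scores for a record set, one child RNG per gene from a master seed."""
    out: dict[str, float | None] = {}
    children = np.random.SeedSequence(seed).spawn(len(records))
    for rec, child in zip(records, children):
        rng = np.random.default_rng(child)
        try:
            res = compute_zscore(rec, n_shuffles=n_shuffles, rng=rng,
                                 engine=engine)
            out[rec.gene_id] = res.zscore
        except ValueError:
            out[rec.gene_id] = None
    return out
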
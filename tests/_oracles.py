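"""Independent brute-force oracles used to validate the vectorized encoders.

Everything here is written as literal loops over the defining formulas,
deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import math
from collections import Counter
from itertools import product

import numpy as np

DINUCS = ["".join(p) for p in product("ACGT", repeat=2)]


def prop_value(table, u: int, dinuc: str) -> float:
    return table.values[u, DINUCS.index(dinuc)]


def brute_kmer(seq: str, k: int = 3) -> dict[str, float]:
    counts = Counter(
        seq[i : i + k] for i in range(len(seq) - k + 1) if "N" not in seq[i : i + k]
    )
    return {kmer: counts[kmer] / len(seq) for kmer in map("".join, product("ACGT", repeat=k))}


def brute_dac(seq: str, table, u: int, lag: int) -> float:
    L = len(seq)
    P = [prop_value(table, u, seq[i : i + 2]) for i in range(L - 1)]
    mean = sum(P) / (L - 1)
    total = 0.0
    for i in range(L - lag - 1):
        total += (P[i] - mean) * (P[i + lag] - mean) / (L - lag - 1)
    return total


def brute_dcc(seq: str, table, u1: int, u2: int, lag: int) -> float:
    L = len(seq)
    P1 = [prop_value(table, u1, seq[i : i + 2]) for i in range(L - 1)]
    P2 = [prop_value(table, u2, seq[i : i + 2]) for i in range(L - 1)]
    m1, m2 = sum(P1) / (L - 1), sum(P2) / (L - 1)
    total = 0.0
    for i in range(L - lag - 1):
        total += (P1[i] - m1) * (P2[i + lag] - m2) / (L - lag - 1)
    return total


def brute_dacc(seq: str, table, lag_max: int) -> list[float]:
    nprops = table.n_properties
    out = [
        brute_dac(seq, table, u, lag)
        for u in range(nprops)
        for lag in range(1, lag_max + 1)
    ]
    out += [
        brute_dcc(seq, table, u1, u2, lag)
        for u1 in range(nprops)
        for u2 in range(nprops)
        if u1 != u2
        for lag in range(1, lag_max + 1)
    ]
    return out


def brute_scpsednc(seq: str, table, lam: int, w: float) -> list[float]:
    L = len(seq)
    counts = Counter(seq[i : i + 2] for i in range(L - 1))
    freqs = [counts[d] / (L - 1) for d in DINUCS]
    nprops = table.n_properties
    thetas = []
    for m in range(1, lam + 1):
        for xi in range(nprops):
            terms = [
                prop_value(table, xi, seq[i : i + 2])
                * prop_value(table, xi, seq[i + m : i + m + 2])
                for i in range(L - m - 2)
            ]
            thetas.append(sum(terms) / (L - m - 2))
    denom = sum(freqs) + w * sum(thetas)
    return [f / denom for f in freqs] + [w * t / denom for t in thetas]


def mi_bits(x, y) -> float:
    """Plug-in mutual information in bits via explicit probability tables."""
    n = len(x)
    joint = Counter(zip(x, y))
    px = Counter(x)
    py = Counter(y)
    total = 0.0
    for (a, b), c in joint.items():
        pxy = c / n
        total += pxy * math.log2(pxy / (px[a] / n * py[b] / n))
    return total


def brute_mrmr_order(disc: np.ndarray, y: np.ndarray, m: int, criterion: str = "MID"):
    """Recompute the greedy mRMR selection from scratch at every step."""
    p = disc.shape[1]
    selected: list[int] = []
    while len(selected) < m:
        best, best_score = None, None
        for j in range(p):
            if j in selected:
                continue
            rel = mi_bits(disc[:, j].tolist(), y.tolist())
            if not selected:
                score = rel
            else:
                red = sum(
                    mi_bits(disc[:, j].tolist(), disc[:, s].tolist()) for s in selected
                ) / len(selected)
                score = rel - red if criterion == "MID" else rel / (red + 1e-12)
            if best_score is None or score > best_score + 1e-12:
                best, best_score = j, score
        selected.append(best)
    return selected


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
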
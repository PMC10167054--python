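"""Independent brute-force oracles used by the tests.

These deliberately re-derive each quantity from its definition with the
most literal possible code (explicit loops, exhaustive enumeration) and
share nothing with the package implementations they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# fuzzy approximate entropy


def naive_fapen_scalar(x: np.ndarray, m: int, r: float, n: float) -> float:
    """Fully scalar quadruple-loop transcription of the fApEn definition.

    Usable only for tiny records; exists to anchor the vectorized oracle.
    """
    x = np.asarray(x, dtype=float)
    N = x.size
    z = (x - x.mean()) / x.std()
    nvec = N - m

    def phi(mlen: int) -> float:
        total = 0.0
        for i in range(nvec):
            mu_i = sum(z[i + k] for k in range(mlen)) / mlen
            acc = 0.0
            for j in range(nvec):
                if j == i:
                    continue
                mu_j = sum(z[j + k] for k in range(mlen)) / mlen
                d = 0.0
                for k in range(mlen):
                    diff = abs((z[i + k] - mu_i) - (z[j + k] - mu_j))
                    if diff > d:
                        d = diff
                acc += math.exp(-(d**n) / r)
            total += math.log(acc / (nvec - 1))
        return total / nvec

    return phi(m) - phi(m + 1)


def naive_fapen(x: np.ndarray, m: int, r: float, n: float) -> float:
    """Direct transcription of the fApEn definition, vectorized over the
    comparison index only (one explicit loop per vector)."""
    x = np.asarray(x, dtype=float)
    N = x.size
    z = (x - x.mean()) / x.std()
    nvec = N - m

    def phi(mlen: int) -> float:
        V = np.stack([z[i : i + mlen] for i in range(nvec)])
        V = V - V.mean(axis=1)[:, None]
        total = 0.0
        for i in range(nvec):
            d = np.abs(V[i][None, :] - V).max(axis=1)
            sim = np.exp(-(d**n) / r)
            sim[i] = 0.0  # j != i
            total += np.log(sim.sum() / (nvec - 1))
        return total / nvec

    return phi(m) - phi(m + 1)


# ---------------------------------------------------------------------------
# weighted graph metrics (exhaustive enumeration, <= 8 nodes)


def brute_clustering(W: np.ndarray) -> np.ndarray:
    """Onnela weighted clustering by explicit triangle enumeration on the
    max-normalized weight matrix."""
    W = np.asarray(W, dtype=float).copy()
    np.fill_diagonal(W, 0.0)
    W[W < 0] = 0.0
    Wn = W / W.max()
    k = W.shape[0]
    out = np.zeros(k)
    for i in range(k):
        nbrs = [j for j in range(k) if Wn[i, j] > 0]
        deg = len(nbrs)
        if deg < 2:
            continue
        s = 0.0
        for j, h in itertools.permutations(nbrs, 2):
            s += (Wn[i, j] * Wn[i, h] * Wn[j, h]) ** (1.0 / 3.0)
        out[i] = s / (deg * (deg - 1))
    return out


def _brute_shortest(D: np.ndarray, src: int, dst: int) -> float:
    """Shortest path by enumerating every simple path."""
    k = D.shape[0]
    best = D[src, dst] if np.isfinite(D[src, dst]) else np.inf
    others = [v for v in range(k) if v not in (src, dst)]
    for length in range(1, len(others) + 1):
        for mid in itertools.permutations(others, length):
            path = [src, *mid, dst]
            cost = 0.0
            for a, b in zip(path[:-1], path[1:]):
                cost += D[a, b]
                if cost >= best:
                    break
            best = min(best, cost)
    return best


def brute_efficiency(W: np.ndarray) -> float:
    """Mean inverse shortest-path length on distance = 1/weight."""
    W = np.asarray(W, dtype=float)
    k = W.shape[0]
    if k < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        D = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    np.fill_diagonal(D, 0.0)
    vals = []
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            d = _brute_shortest(D, i, j)
            vals.append(1.0 / d if np.isfinite(d) and d > 0 else 0.0)
    return float(np.mean(vals))


def brute_graph_metrics(W: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """(clustering, local efficiency, global efficiency) by enumeration."""
    W = np.asarray(W, dtype=float).copy()
    np.fill_diagonal(W, 0.0)
    W[W < 0] = 0.0
    Wn = W / W.max()
    k = W.shape[0]
    clustering = brute_clustering(W)
    local = np.zeros(k)
    for i in range(k):
        nbrs = [j for j in range(k) if Wn[i, j] > 0]
        if len(nbrs) >= 2:
            local[i] = brute_efficiency(Wn[np.ix_(nbrs, nbrs)])
    return clustering, local, brute_efficiency(Wn)
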
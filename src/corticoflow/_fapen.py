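"""Low-level fuzzy approximate entropy kernels.

The statistic is O(N^2) in the window length; the default path is a
numba-compiled double loop (O(N) memory). A chunked numpy fallback with
identical semantics is used when numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    import numba

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _phi_numpy(z: np.ndarray, mlen: int, n: float, r: float, nvec: int) -> float:
    """phi^mlen over the first ``nvec`` baseline-removed vectors of length ``mlen``.

    Chunked over rows to bound memory at O(chunk * nvec).
    """
    # baseline-removed embedding rows: V[i, k] = z[i+k] - mean(z[i:i+mlen])
    idx = np.arange(mlen)[None, :] + np.arange(nvec)[:, None]
    V = z[idx]
    V = V - V.mean(axis=1, keepdims=True)
    total = 0.0
    chunk = max(1, int(2e6 // max(nvec, 1)))
    for lo in range(0, nvec, chunk):
        hi = min(lo + chunk, nvec)
        # Chebyshev distance between every row pair in the chunk and all rows
        d = np.abs(V[lo:hi, None, :] - V[None, :, :]).max(axis=2)
        sim = np.exp(-(d**n) / r)
        # exclude self-matches
        rows = np.arange(lo, hi)
        sim[rows - lo, rows] = 0.0
        total += float(np.sum(np.log(np.maximum(sim.sum(axis=1) / (nvec - 1), 1e-300))))
    return total / nvec


if _HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=False)
    def _phi_numba(z, mlen, n, r, nvec):  # pragma: no cover - compiled
        # window means for baseline removal
        mu = np.empty(nvec)
        for i in range(nvec):
            s = 0.0
            for k in range(mlen):
                s += z[i + k]
            mu[i] = s / mlen
        # Kahan-compensated sums keep the serial accumulation within the
        # 1e-10 agreement bound against pairwise-summing references
        total = 0.0
        tc = 0.0
        for i in range(nvec):
            acc = 0.0
            ac = 0.0
            for j in range(nvec):
                if j == i:
                    continue
                d = 0.0
                for k in range(mlen):
                    diff = abs((z[i + k] - mu[i]) - (z[j + k] - mu[j]))
                    if diff > d:
                        d = diff
                if n == 2.0:
                    e = d * d
                elif n == 1.0:
                    e = d
                else:
                    e = d**n
                term = np.exp(-e / r) - ac
                tmp = acc + term
                ac = (tmp - acc) - term
                acc = tmp
            m = acc / (nvec - 1)
            if m < 1e-300:
                m = 1e-300
            lterm = np.log(m) - tc
            ttmp = total + lterm
            tc = (ttmp - total) - lterm
            total = ttmp
        return total / nvec


def phi(z: np.ndarray, mlen: int, n: float, r: float, nvec: int) -> float:
    """Average log mean fuzzy similarity of the embedding at length ``mlen``."""
    z = np.ascontiguousarray(z, dtype=np.float64)
    if _HAVE_NUMBA:
        return float(_phi_numba(z, mlen, float(n), float(r), nvec))
    return _phi_numpy(z, mlen, float(n), float(r), nvec)
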
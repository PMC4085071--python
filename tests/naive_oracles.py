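"""Independent brute-force oracles: every quantity recomputed with plain
Python loops straight from the defining sums, with no reuse of the package's
vectorized kernels."""

import math

import numpy as np


def naive_hill(p, q):
    p = [x / sum(p) for x in p if x > 0]
    if q == 1:
        return math.exp(-sum(x * math.log(x) for x in p))
    return sum(x**q for x in p) ** (1.0 / (1.0 - q))


def naive_Q(p, d):
    p = [x / sum(p) for x in p]
    S = len(p)
    return sum(d[i][j] * p[i] * p[j] for i in range(S) for j in range(S))


def naive_fad(d):
    S = len(d)
    return sum(d[i][j] for i in range(S) for j in range(S))


def naive_functional_D(p, d, q):
    """Functional Hill number by direct double summation."""
    p = [x / sum(p) for x in p]
    S = len(p)
    Q = naive_Q(p, d)
    pairs = [
        (d[i][j], p[i] * p[j])
        for i in range(S)
        for j in range(S)
        if p[i] * p[j] > 0
    ]
    if q == 1:
        ent = sum((dij / Q) * pp * math.log(pp) for dij, pp in pairs)
        return math.exp(-0.5 * ent)
    s = sum((dij / Q) * pp**q for dij, pp in pairs)
    return s ** (1.0 / (2.0 * (1.0 - q)))


def naive_fd(p, d, q):
    p = [x / sum(p) for x in p]
    Q = naive_Q(p, d)
    D = naive_functional_D(p, d, q)
    return Q * D * D


def _rel_z(z, scheme):
    z = np.asarray(z, dtype=float)
    if scheme == "relative":
        z = z / z.sum(axis=0, keepdims=True)
    return z


def naive_fd_gamma(z, d, q, scheme="relative"):
    z = _rel_z(z, scheme)
    pooled = z.sum(axis=1)
    return naive_fd(list(pooled), d, q)


def naive_fd_alpha(z, d, q, scheme="relative"):
    """Functional alpha diversity by quadruple summation over species pairs
    (i, j) and assemblage pairs (k, m)."""
    z = _rel_z(z, scheme)
    S, N = z.shape
    zpp = z.sum()
    a = z / zpp
    pooled = z.sum(axis=1) / zpp
    Q = sum(d[i][j] * pooled[i] * pooled[j] for i in range(S) for j in range(S))
    terms = [
        (d[i][j], a[i, k] * a[j, m])
        for i in range(S)
        for j in range(S)
        for k in range(N)
        for m in range(N)
        if a[i, k] * a[j, m] > 0
    ]
    if q == 1:
        ent = sum((dij / Q) * pp * math.log(pp) for dij, pp in terms)
        return (Q / N**2) * math.exp(-ent)
    s = sum((dij / Q) * pp**q for dij, pp in terms)
    return (Q / N**2) * s ** (1.0 / (1.0 - q))


def naive_hill_alpha(z, q, scheme="relative"):
    z = _rel_z(z, scheme)
    S, N = z.shape
    a = (z / z.sum()).ravel()
    a = a[a > 0]
    if q == 1:
        return math.exp(-sum(x * math.log(x) for x in a)) / N
    return sum(x**q for x in a) ** (1.0 / (1.0 - q)) / N
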
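"""Independent oracle implementations used to cross-check the library.

Everything here is deliberately written from the definitions with explicit
loops (or an njit-compiled copy of the same loops for large sweeps), sharing
no code with the implementation under test.
"""

from __future__ import annotations

import numpy as np

STATIONARY_BURN = 64  # canonical burn-in + Cesaro lengths of the definition
STATIONARY_ITERS = 64


def phi_oracle(tpm: np.ndarray) -> float:
    """Brute-force whole-vs-factorized divergence for a 4x4 two-node TPM.

    States are s = 2*a + b.  Stationary weights from Cesaro-averaged power
    iteration (uniform start); the factorized model conditions each node on
    its own state only, with the partner marginalized under the stationary
    conditional (uniform fallback for zero-mass margins).  All sums are
    explicit loops.
    """
    # stationary distribution: burn-in then Cesaro average
    pi = [0.25, 0.25, 0.25, 0.25]
    acc = [0.0, 0.0, 0.0, 0.0]
    for it in range(STATIONARY_BURN + STATIONARY_ITERS):
        new = [0.0] * 4
        for s in range(4):
            for s2 in range(4):
                new[s2] += pi[s] * tpm[s, s2]
        pi = new
        if it >= STATIONARY_BURN:
            for s in range(4):
                acc[s] += pi[s]
    pi = [v / STATIONARY_ITERS for v in acc]

    # node marginal transition probabilities given the joint state
    def p_a_next(s: int, a2: int) -> float:
        return sum(tpm[s, 2 * a2 + b2] for b2 in (0, 1))

    def p_b_next(s: int, b2: int) -> float:
        return sum(tpm[s, 2 * a2 + b2] for a2 in (0, 1))

    # stationary conditionals of the partner
    pa_marg = [pi[2 * a + 0] + pi[2 * a + 1] for a in (0, 1)]
    pb_marg = [pi[0 + b] + pi[2 + b] for b in (0, 1)]

    def w_b_given_a(a: int, b: int) -> float:
        return pi[2 * a + b] / pa_marg[a] if pa_marg[a] > 0 else 0.5

    def w_a_given_b(a: int, b: int) -> float:
        return pi[2 * a + b] / pb_marg[b] if pb_marg[b] > 0 else 0.5

    def qa(a: int, a2: int) -> float:
        return sum(w_b_given_a(a, b) * p_a_next(2 * a + b, a2) for b in (0, 1))

    def qb(b: int, b2: int) -> float:
        return sum(w_a_given_b(a, b) * p_b_next(2 * a + b, b2) for a in (0, 1))

    total = 0.0
    for s in range(4):
        if pi[s] <= 0:
            continue
        a, b = s >> 1, s & 1
        kl = 0.0
        for s2 in range(4):
            p = tpm[s, s2]
            if p <= 0:
                continue
            a2, b2 = s2 >> 1, s2 & 1
            q = qa(a, a2) * qb(b, b2)
            kl += p * np.log2(p / q)
        total += pi[s] * kl
    return max(total, 0.0)


def make_phi_oracle_njit():
    """njit-compiled copy of :func:`phi_oracle` plus a grid sweep driver.

    The compiled oracle repeats the same explicit-loop derivation so the
    full coarse-grid enumeration stays affordable.
    """
    import numba

    @numba.njit(cache=False)
    def phi_one(tpm):
        pi = np.full(4, 0.25)
        acc = np.zeros(4)
        for it in range(STATIONARY_BURN + STATIONARY_ITERS):
            new = np.zeros(4)
            for s in range(4):
                for s2 in range(4):
                    new[s2] += pi[s] * tpm[s, s2]
            pi = new
            if it >= STATIONARY_BURN:
                for s in range(4):
                    acc[s] += pi[s]
        pi = acc / STATIONARY_ITERS

        pa_marg = np.zeros(2)
        pb_marg = np.zeros(2)
        for a in range(2):
            for b in range(2):
                pa_marg[a] += pi[2 * a + b]
                pb_marg[b] += pi[2 * a + b]

        qa = np.zeros((2, 2))  # qa[a, a2]
        qb = np.zeros((2, 2))
        for a in range(2):
            for a2 in range(2):
                v = 0.0
                for b in range(2):
                    w = pi[2 * a + b] / pa_marg[a] if pa_marg[a] > 0 else 0.5
                    pa_next = tpm[2 * a + b, 2 * a2 + 0] + tpm[2 * a + b, 2 * a2 + 1]
                    v += w * pa_next
                qa[a, a2] = v
        for b in range(2):
            for b2 in range(2):
                v = 0.0
                for a in range(2):
                    w = pi[2 * a + b] / pb_marg[b] if pb_marg[b] > 0 else 0.5
                    pb_next = tpm[2 * a + b, 0 + b2] + tpm[2 * a + b, 2 + b2]
                    v += w * pb_next
                qb[b, b2] = v

        total = 0.0
        for s in range(4):
            if pi[s] <= 0:
                continue
            a = s >> 1
            b = s & 1
            kl = 0.0
            for s2 in range(4):
                p = tpm[s, s2]
                if p <= 0:
                    continue
                a2 = s2 >> 1
                b2 = s2 & 1
                q = qa[a, a2] * qb[b, b2]
                kl += p * np.log2(p / q)
            total += pi[s] * kl
        return max(total, 0.0)

    @numba.njit(cache=False)
    def phi_grid(rows, idx):
        out = np.empty(idx.shape[0])
        tpm = np.empty((4, 4))
        for n in range(idx.shape[0]):
            for r in range(4):
                for c in range(4):
                    tpm[r, c] = rows[idx[n, r], c]
            out[n] = phi_one(tpm)
        return out

    return phi_one, phi_grid


def complete_linkage_labels(points: np.ndarray, k: int) -> np.ndarray:
    """Brute-force agglomerative complete linkage down to k clusters.

    Starts from singletons and repeatedly merges the pair of clusters with
    the smallest maximum inter-point distance.  Returns integer labels.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    clusters: list[list[int]] = [[i] for i in range(n)]
    dist = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))

    def cluster_distance(ci, cj):
        return max(dist[a, b] for a in ci for b in cj)

    while len(clusters) > k:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = cluster_distance(clusters[i], clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        _, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    labels = np.empty(n, dtype=int)
    for ci, members in enumerate(clusters):
        for m in members:
            labels[m] = ci
    return labels


def superpose_template(
    n: int, template: np.ndarray, onsets_samples: list[int], gain: float
) -> np.ndarray:
    """Direct summation of shifted templates (evoked-response injection oracle)."""
    out = np.zeros(n)
    for s in onsets_samples:
        for i, v in enumerate(template):
            if 0 <= s + i < n:
                out[s + i] += gain * v
    return out


def friedman_chi2_textbook(values: np.ndarray) -> float:
    """Tie-free Friedman chi-square: 12/(n k (k+1)) * sum Rj^2 - 3 n (k+1)."""
    from scipy.stats import rankdata

    n, k = values.shape
    ranks = np.vstack([rankdata(row) for row in values])
    rj = ranks.sum(axis=0)
    return float(12.0 / (n * k * (k + 1)) * (rj**2).sum() - 3.0 * n * (k + 1))


def spearman_textbook(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of the ranks (hand-ranked formula)."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))
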
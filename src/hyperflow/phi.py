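"""Pairwise integrated information over binarized region activity.

Each pair of region-group series (within or between brains) is reduced to a
two-node binary system: after down-sampling (factors 5/10/15/20 at 256 Hz
give the 51.2/25.6/17.1/12.8 Hz step rates), a step maps to "on" when the
activity is increasing across consecutive down-sampled samples.  Joint-state
transitions, pooled over every down-sampling shift and over trials, form a
4x4 transition probability matrix (TPM) on states (00, 01, 10, 11).

Integrated information phi compares the whole TPM with its independence
factorization across the unique bipartition of the pair: both cross
connections are cut, leaving each node's next state conditioned on its own
past only (the partner marginalized under the stationary conditional).  phi
is the Kullback-Leibler divergence (bits) between the joint and factorized
next-state distributions, weighted by a canonical stationary distribution
(Cesaro-averaged power iteration from a uniform start, which exists for
every row-stochastic matrix).  phi >= 0, with equality exactly when the
nodes evolve independently.

This is the operational whole-vs-minimally-reducible construction; equality
with IIT-3.0 toolbox big-Phi is not claimed — the contract is zero iff
factorizable and monotone growth with cross-coupling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from hyperflow.config import CONDITIONS, DOWNSAMPLE_FACTORS

#: Joint states in index order: s = 2*a + b for node states (a, b).
STATES = ("00", "01", "10", "11")

#: Burn-in and averaging lengths for the canonical stationary distribution.
STATIONARY_BURN_IN = 64
STATIONARY_ITERATIONS = 64


@dataclass
class TransitionModel:
    """Row-stochastic 4x4 TPM with its raw transition counts."""

    tpm: np.ndarray
    counts: np.ndarray
    down_factor: int
    n_shifts: int
    unvisited: np.ndarray = field(default_factory=lambda: np.zeros(4, dtype=bool))

    def __post_init__(self) -> None:
        rs = self.tpm.sum(axis=1)
        if not np.allclose(rs, 1.0, atol=1e-9):
            raise ValueError(f"TPM rows must sum to 1, got {rs}")
        if np.any(self.counts < 0):
            raise ValueError("negative transition counts")


@dataclass
class PhiValue:
    phi: float
    low_confidence: bool = False
    connection: tuple | None = None
    scope: str | None = None


def binarize_ramp(series: np.ndarray, down_factor: int = 1) -> np.ndarray:
    """Binary "rising" indicator of the down-sampled series.

    After taking every ``down_factor``-th sample, step t is 1 iff
    ``x[t+1] > x[t]`` (strict: ties and decreases give 0).  Output length is
    the down-sampled length minus one.
    """
    series = np.asarray(series, dtype=float)
    if down_factor < 1:
        raise ValueError("down_factor must be >= 1")
    if series.shape[-1] < 2 * down_factor:
        raise ValueError(
            f"series of {series.shape[-1]} samples too short for factor {down_factor}"
        )
    ds = series[..., ::down_factor]
    return (np.diff(ds, axis=-1) > 0).astype(np.int8)


def build_tpm(
    series_a: np.ndarray | list[np.ndarray],
    series_b: np.ndarray | list[np.ndarray],
    down_factor: int = 1,
) -> TransitionModel:
    """Shift-pooled TPM of the binarized pair, optionally pooled over trials.

    For every shift 0..down_factor-1 the pair is binarized on the shifted
    down-sampled grid and joint-state transitions are counted; counts pool
    across shifts and across trials (pass lists of per-trial series).  Rows
    of never-visited states get a uniform placeholder and are flagged.
    """
    if isinstance(series_a, np.ndarray) and series_a.ndim == 1:
        series_a, series_b = [series_a], [series_b]
    counts = np.zeros((4, 4))
    for xa, xb in zip(series_a, series_b, strict=True):
        xa = np.asarray(xa, dtype=float)
        xb = np.asarray(xb, dtype=float)
        if xa.shape != xb.shape:
            raise ValueError("paired series must have equal length")
        for shift in range(down_factor):
            a = binarize_ramp(xa[shift:], down_factor)
            b = binarize_ramp(xb[shift:], down_factor)
            joint = 2 * a + b
            idx = 4 * joint[:-1] + joint[1:]
            counts += np.bincount(idx, minlength=16).reshape(4, 4)
    row_sums = counts.sum(axis=1)
    unvisited = row_sums == 0
    if unvisited.any():
        warnings.warn(
            f"states never visited: {[STATES[i] for i in np.flatnonzero(unvisited)]}"
        )
    tpm = np.where(
        unvisited[:, None], 0.25, counts / np.maximum(row_sums, 1.0)[:, None]
    )
    return TransitionModel(
        tpm=tpm,
        counts=counts,
        down_factor=down_factor,
        n_shifts=down_factor,
        unvisited=unvisited,
    )


def stationary_distribution(tpm: np.ndarray) -> np.ndarray:
    """Canonical stationary distribution: Cesaro-averaged power iteration.

    A geometric burn-in removes the transient of the uniform start, then
    the orbit is Cesaro-averaged over a fixed window, which yields an
    invariant distribution for every row-stochastic matrix (including
    periodic and reducible ones) and makes the weighting deterministic.
    """
    tpm = np.asarray(tpm, dtype=float)
    pi = np.full(tpm.shape[0], 1.0 / tpm.shape[0])
    for _ in range(STATIONARY_BURN_IN):
        pi = pi @ tpm
    acc = np.zeros_like(pi)
    for _ in range(STATIONARY_ITERATIONS):
        pi = pi @ tpm
        acc += pi
    return acc / STATIONARY_ITERATIONS


def factorized_tpm(tpm: np.ndarray, pi: np.ndarray | None = None) -> np.ndarray:
    """Independence factorization across the unique 2-node bipartition.

    The bipartition cuts both cross connections, leaving each node
    conditioned on its own past only: ``qA(a'|a) = sum_b pi(b|a) pA(a'|a,b)``
    with ``pA`` the node's marginal next-state distribution and ``pi(b|a)``
    the stationary conditional of the partner (uniform where ``pi(a) = 0``).
    The factorized TPM is ``q(s'|s) = qA(a'|a) qB(b'|b)``, the minimally
    reducible model of the pair.
    """
    tpm = np.asarray(tpm, dtype=float)
    if pi is None:
        pi = stationary_distribution(tpm)
    p4 = tpm.reshape(2, 2, 2, 2)  # (a, b, a', b')
    pi4 = pi.reshape(2, 2)  # (a, b)
    pa_joint = p4.sum(axis=3)  # pA(a'| a, b)
    pb_joint = p4.sum(axis=2)  # pB(b'| a, b)
    # stationary conditionals of the partner, uniform for unvisited margins
    pa_marg = pi4.sum(axis=1)  # pi(a)
    pb_marg = pi4.sum(axis=0)  # pi(b)
    w_b_given_a = np.where(
        pa_marg[:, None] > 0, pi4 / np.maximum(pa_marg[:, None], 1e-300), 0.5
    )
    w_a_given_b = np.where(
        pb_marg[None, :] > 0, pi4 / np.maximum(pb_marg[None, :], 1e-300), 0.5
    )
    qa = np.einsum("ab,abx->ax", w_b_given_a, pa_joint)  # qA(a'|a)
    qb = np.einsum("ab,aby->by", w_a_given_b, pb_joint)  # qB(b'|b)
    # q((a',b') | (a,b)) = qA(a'|a) qB(b'|b)
    q = np.einsum("ax,by->abxy", qa, qb).reshape(4, 4)
    return q


def phi(model: TransitionModel | np.ndarray) -> PhiValue:
    """Integrated information of a 2-node TPM, in bits.

    Stationary-weighted KL divergence between the whole and the
    independence-factorized conditional transition distributions.  The
    factorized marginals dominate the joint (q > 0 wherever p > 0), so the
    divergence is always finite, nonnegative, and exactly zero for product
    TPMs.
    """
    if isinstance(model, TransitionModel):
        tpm = model.tpm
        low_conf = bool(model.unvisited.any())
    else:
        tpm = np.asarray(model, dtype=float)
        if tpm.shape != (4, 4) or not np.allclose(tpm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("phi needs a row-stochastic 4x4 TPM")
        low_conf = False
    pi = stationary_distribution(tpm)
    q = factorized_tpm(tpm, pi)
    with np.errstate(divide="ignore", invalid="ignore"):
        logterm = np.where(tpm > 0, np.log2(np.maximum(tpm, 1e-300) / np.maximum(q, 1e-300)), 0.0)
    kl_rows = (tpm * logterm).sum(axis=1)
    # rows with zero stationary weight contribute nothing (0 * inf guard)
    value = float(np.maximum((pi * np.where(pi > 0, kl_rows, 0.0)).sum(), 0.0))
    return PhiValue(phi=value, low_confidence=low_conf)


def phi_batch(tpms: np.ndarray) -> np.ndarray:
    """Vectorized phi over a batch of row-stochastic TPMs (n, 4, 4) -> (n,)."""
    tpms = np.asarray(tpms, dtype=float)
    n = tpms.shape[0]
    pi = np.full((n, 4), 0.25)
    for _ in range(STATIONARY_BURN_IN):
        pi = np.einsum("ni,nij->nj", pi, tpms)
    acc = np.zeros_like(pi)
    for _ in range(STATIONARY_ITERATIONS):
        pi = np.einsum("ni,nij->nj", pi, tpms)
        acc += pi
    pi = acc / STATIONARY_ITERATIONS
    p4 = tpms.reshape(n, 2, 2, 2, 2)  # (n, a, b, a', b')
    pi4 = pi.reshape(n, 2, 2)
    pa_joint = p4.sum(axis=4)
    pb_joint = p4.sum(axis=3)
    pa_marg = pi4.sum(axis=2)  # (n, a)
    pb_marg = pi4.sum(axis=1)  # (n, b)
    w_b_given_a = np.where(
        pa_marg[:, :, None] > 0, pi4 / np.maximum(pa_marg[:, :, None], 1e-300), 0.5
    )
    w_a_given_b = np.where(
        pb_marg[:, None, :] > 0, pi4 / np.maximum(pb_marg[:, None, :], 1e-300), 0.5
    )
    qa = np.einsum("nab,nabx->nax", w_b_given_a, pa_joint)
    qb = np.einsum("nab,naby->nby", w_a_given_b, pb_joint)
    q = np.einsum("nax,nby->nabxy", qa, qb).reshape(n, 4, 4)
    with np.errstate(divide="ignore", invalid="ignore"):
        logterm = np.where(
            tpms > 0,
            np.log2(np.maximum(tpms, 1e-300) / np.maximum(q, 1e-300)),
            0.0,
        )
    kl_rows = (tpms * logterm).sum(axis=2)
    kl_rows = np.where(pi > 0, kl_rows, 0.0)
    return np.maximum((pi * kl_rows).sum(axis=1), 0.0)


def cross_coupling_tpm(c: float) -> np.ndarray:
    """Parametric two-node family: each node copies the *other* node's
    current state with probability ``(1 + c) / 2``, acts as a fair coin at
    ``c = 0``.  phi grows monotonically with ``c`` in [0, 1)."""
    if not 0.0 <= c <= 1.0:
        raise ValueError("coupling must be in [0, 1]")
    p_copy = (1.0 + c) / 2.0
    tpm = np.zeros((4, 4))
    for s in range(4):
        a, b = s >> 1, s & 1
        for s2 in range(4):
            a2, b2 = s2 >> 1, s2 & 1
            pa = p_copy if a2 == b else 1.0 - p_copy
            pb = p_copy if b2 == a else 1.0 - p_copy
            tpm[s, s2] = pa * pb
    return tpm


# --------------------------------------------------------------------------
# Condition normalization (shared with the phase-synchrony stage)
# --------------------------------------------------------------------------


def normalize_conditions(
    raw: dict[tuple, dict[str, float]]
) -> dict[tuple, dict[str, float]]:
    """Per connection: value minus the mean over the three conditions.

    Connections missing a condition are excluded (logged), not imputed.
    The sign convention keeps larger raw values larger after normalization.
    """
    out = {}
    for conn, values in raw.items():
        if any(c not in values for c in CONDITIONS):
            warnings.warn(f"connection {conn} missing a condition; excluded")
            continue
        mean = np.mean([values[c] for c in CONDITIONS])
        out[conn] = {c: values[c] - mean for c in CONDITIONS}
    return out


def global_mean(
    normalized: dict[tuple, dict[str, float]],
    connection_filter=None,
) -> dict[str, float]:
    """Unweighted mean over (retained) connections, per condition."""
    keys = [k for k in normalized if connection_filter is None or connection_filter(k)]
    if not keys:
        raise ValueError("no connections retained by the filter")
    return {
        c: float(np.mean([normalized[k][c] for k in keys])) for c in CONDITIONS
    }


def trial_pair_phi(
    series_a: list[np.ndarray],
    series_b: list[np.ndarray],
    factors: tuple[int, ...] = DOWNSAMPLE_FACTORS,
) -> float:
    """phi for one connection: computed per down-sampling factor from the
    trial-pooled TPM, then averaged over the four factors."""
    vals = []
    for f in factors:
        model = build_tpm(series_a, series_b, down_factor=f)
        vals.append(phi(model).phi)
    return float(np.mean(vals))
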
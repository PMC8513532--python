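"""Sliding-window MVAR modelling and frequency-domain directed causality.

Region-group series are modelled with short-window multivariate
autoregressions fitted by the Vieira-Morf lattice (multichannel Burg with
geometric-mean normalization of the reflection coefficients, which keeps
every fitted model stable).  Window length is 500 ms with a 25 ms step
(rounded down to 6 samples at 256 Hz); same-condition epochs are pooled per
window position (ensemble fitting), and model order minimises AIC.

From the fitted coefficients ``A_1..A_p`` and residual covariance ``S``,
with ``Abar(f) = I - sum_k A_k e^{-i 2 pi f k / fs}`` and ``H = Abar^{-1}``:

* nPDC: squared modulus of the column-normalized ``Abar`` entries
  (``sum_targets nPDC(source->target) = 1`` at every frequency);
* dDTF: full-frequency DTF times squared partial coherence;
* GGC:  ``ln(S_ii / (S_ii - (S_jj - S_ij^2/S_ii) |H_ij|^2))``.

Per-region sender/receiver roles are summarised by the to/from ratio: the
mean over partners of outgoing over incoming band-averaged causality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats

MEASURES = ("GGC", "dDTF", "nPDC")

#: Band and grid used for all causality summaries (Hz).
CAUSALITY_BAND = (13.0, 50.0)


@dataclass
class MVARModel:
    """One window's fitted VAR: x_t = sum_k A_k x_{t-k} + e_t."""

    window_start: float
    order: int
    coeffs: np.ndarray  # (p, d, d)
    resid_cov: np.ndarray  # (d, d)
    aic: float
    sampling_rate: float
    stable: bool = True
    fitted_by: str = "vieira-morf"

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    def spectral_radius(self) -> float:
        p, d, _ = self.coeffs.shape
        comp = np.zeros((d * p, d * p))
        comp[:d] = self.coeffs.transpose(1, 0, 2).reshape(d, d * p)
        if p > 1:
            comp[d:, : d * (p - 1)] = np.eye(d * (p - 1))
        return float(np.max(np.abs(np.linalg.eigvals(comp))))


@dataclass
class ValidationReport:
    consistency: float  # percent
    stable: bool
    spectral_radius: float
    whiteness_p: float


# --------------------------------------------------------------------------
# Vieira-Morf lattice fit
# --------------------------------------------------------------------------


def _vieira_morf(x: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Fit VAR(p) by the Vieira-Morf lattice recursion.

    ``x`` is (n_epochs, d, n); prediction-error covariances are pooled over
    epochs.  Returns ``(coeffs (p, d, d), resid_cov (d, d))``.
    """
    e, d, n = x.shape
    if p >= n:
        raise ValueError(f"order {p} >= window length {n}")
    f = x.astype(float).copy()  # forward errors
    b = x.astype(float).copy()  # backward errors
    af: list[np.ndarray] = []  # forward coefficients A_1..A_m
    ab: list[np.ndarray] = []  # backward coefficients
    for m in range(1, p + 1):
        fm = f[:, :, m:]  # (e, d, n-m)
        bm = b[:, :, m - 1 : -1]  # backward errors lagged one step
        nobs = fm.shape[0] * fm.shape[2]
        dmat = np.einsum("eit,ejt->ij", fm, bm) / nobs
        vf = np.einsum("eit,ejt->ij", fm, fm) / nobs
        vb = np.einsum("eit,ejt->ij", bm, bm) / nobs
        if not (np.all(np.isfinite(vf)) and np.linalg.matrix_rank(vf) == d):
            raise ValueError("singular covariance: input has zero-variance content")
        sf = np.linalg.cholesky(vf + 1e-12 * np.eye(d) * np.trace(vf) / d)
        sb = np.linalg.cholesky(vb + 1e-12 * np.eye(d) * np.trace(vb) / d)
        k = np.linalg.solve(sf, dmat) @ np.linalg.inv(sb).T
        a_m = sf @ k @ np.linalg.inv(sb)  # forward reflection matrix
        c_m = sb @ k.T @ np.linalg.inv(sf)  # backward reflection matrix
        # Levinson-Whittle update of the full coefficient sets
        af_old = [a.copy() for a in af]
        ab_old = [a.copy() for a in ab]
        af = [af_old[i] - a_m @ ab_old[m - 2 - i] for i in range(m - 1)] + [a_m]
        ab = [ab_old[i] - c_m @ af_old[m - 2 - i] for i in range(m - 1)] + [c_m]
        # lattice error update (order matters: use pre-update errors)
        f_new = f[:, :, m:] - np.einsum("ij,ejt->eit", a_m, b[:, :, m - 1 : -1])
        b_new = b[:, :, m - 1 : -1] - np.einsum("ij,ejt->eit", c_m, f[:, :, m:])
        f[:, :, m:] = f_new
        b[:, :, m:] = b_new
    resid = f[:, :, p:]
    nobs = resid.shape[0] * resid.shape[2]
    cov = np.einsum("eit,ejt->ij", resid, resid) / max(nobs - 1, 1)
    return np.stack(af) if p else np.empty((0, d, d)), cov


def fit_mvar(
    x: np.ndarray,
    max_order: int = 8,
    sampling_rate: float = 256.0,
    window_start: float = 0.0,
    order: int | None = None,
) -> MVARModel:
    """Fit one window, selecting the order 1..max_order minimising AIC.

    ``x`` is (n_epochs, d, n) or (d, n).  AIC = N ln|cov| + 2 p d^2 with N
    the pooled residual count.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:
        x = x[None]
    e, d, n = x.shape
    if np.any(np.ptp(x, axis=-1) == 0):
        raise ValueError("singular covariance: constant (zero-variance) channel")
    best: tuple[float, int, np.ndarray, np.ndarray] | None = None
    orders = [order] if order is not None else range(1, max_order + 1)
    for p in orders:
        coeffs, cov = _vieira_morf(x, p)
        nobs = e * (n - p)
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            continue
        aic = nobs * logdet + 2 * p * d * d
        if best is None or aic < best[0]:
            best = (aic, p, coeffs, cov)
    if best is None:
        raise ValueError("no admissible model order (degenerate covariance)")
    aic, p, coeffs, cov = best
    model = MVARModel(
        window_start=window_start,
        order=p,
        coeffs=coeffs,
        resid_cov=cov,
        aic=aic,
        sampling_rate=sampling_rate,
    )
    model.stable = model.spectral_radius() < 1.0
    if not model.stable:
        warnings.warn(f"window at {window_start:.3f}s: unstable model rejected")
    return model


def sliding_window_positions(
    n_samples: int, sampling_rate: float, window: float = 0.5, step: float = 0.025
) -> tuple[int, int, list[int]]:
    """(window_samples, step_samples, start_indices) for the sliding grid.

    The 25 ms step is 6.4 samples at 256 Hz; rounded down to 6 samples.
    """
    win = int(round(window * sampling_rate))
    stp = max(int(step * sampling_rate), 1)
    if n_samples < win:
        raise ValueError(f"epoch of {n_samples} samples shorter than window {win}")
    starts = list(range(0, n_samples - win + 1, stp))
    return win, stp, starts


def fit_mvar_sliding(
    epochs: np.ndarray,
    sampling_rate: float = 256.0,
    window: float = 0.5,
    step: float = 0.025,
    max_order: int = 8,
) -> list[MVARModel]:
    """Ensemble-fit every window position over pooled epochs.

    ``epochs`` is (n_epochs, d, n); each window pools the same time slice of
    all epochs, the adaptive-MVAR convention for short windows.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim == 2:
        epochs = epochs[None]
    n = epochs.shape[-1]
    win, _, starts = sliding_window_positions(n, sampling_rate, window, step)
    models = []
    for s in starts:
        models.append(
            fit_mvar(
                epochs[:, :, s : s + win],
                max_order=max_order,
                sampling_rate=sampling_rate,
                window_start=s / sampling_rate,
            )
        )
    return models


# --------------------------------------------------------------------------
# Model validation
# --------------------------------------------------------------------------


def simulate_var(model: MVARModel, n: int, n_epochs: int = 1, seed=0) -> np.ndarray:
    """Simulate epochs from a fitted model with its correlated innovations."""
    rng_seeds = np.random.SeedSequence(seed).spawn(n_epochs)
    p = model.order
    burn = 256
    out = []
    for ss in rng_seeds:
        rng = np.random.default_rng(ss)
        e = rng.multivariate_normal(
            np.zeros(model.n_channels), model.resid_cov, size=n + burn
        ).T
        x = np.zeros_like(e)
        for t in range(p, e.shape[1]):
            acc = e[:, t].copy()
            for k in range(p):
                acc += model.coeffs[k] @ x[:, t - 1 - k]
            x[:, t] = acc
        out.append(x[:, burn:])
    return np.stack(out)


def _correlation_vector(x: np.ndarray, max_lag: int) -> np.ndarray:
    """All auto/cross-covariances at lags 0..max_lag, pooled over epochs."""
    e, d, n = x.shape
    xc = x - x.mean(axis=-1, keepdims=True)
    vecs = []
    for lag in range(max_lag + 1):
        c = np.einsum("eit,ejt->ij", xc[:, :, lag:], xc[:, :, : n - lag if lag else None])
        vecs.append(c.ravel() / (e * (n - lag)))
    return np.concatenate(vecs)


def validate_model(model: MVARModel, data: np.ndarray, seed=0) -> ValidationReport:
    """Stability, percent consistency, and residual-whiteness report.

    Consistency compares the auto/cross-covariance structure of the data with
    that of data simulated from the model:
    ``100 * (1 - ||R_data - R_sim|| / ||R_data||)``.  Whiteness is a
    multivariate Ljung-Box portmanteau test on residual autocorrelations.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[None]
    e, d, n = data.shape
    rho = model.spectral_radius()
    stable = rho < 1.0

    consistency = 0.0
    if stable:
        sim = simulate_var(model, n, n_epochs=max(e, 4), seed=seed)
        r_data = _correlation_vector(data, model.order)
        r_sim = _correlation_vector(sim, model.order)
        consistency = 100.0 * (1.0 - np.linalg.norm(r_data - r_sim) / np.linalg.norm(r_data))
    consistency = float(np.clip(consistency, 0.0, 100.0))

    resid = _residuals(model, data)
    whiteness_p = _portmanteau_p(resid, model.order)
    return ValidationReport(
        consistency=consistency,
        stable=stable,
        spectral_radius=rho,
        whiteness_p=whiteness_p,
    )


def _residuals(model: MVARModel, data: np.ndarray) -> np.ndarray:
    p = model.order
    e, d, n = data.shape
    pred = np.zeros((e, d, n - p))
    for k in range(p):
        pred += np.einsum("ij,ejt->eit", model.coeffs[k], data[:, :, p - 1 - k : n - 1 - k])
    return data[:, :, p:] - pred


def _portmanteau_p(resid: np.ndarray, p: int, h: int = 12) -> float:
    """Multivariate Ljung-Box p-value on residual autocorrelations to lag h."""
    e, d, n = resid.shape
    h = min(h, n // 2 - 1)
    rc = resid - resid.mean(axis=-1, keepdims=True)
    c0 = np.einsum("eit,ejt->ij", rc, rc) / (e * n)
    c0inv = np.linalg.inv(c0 + 1e-12 * np.eye(d) * np.trace(c0) / d)
    q = 0.0
    for lag in range(1, h + 1):
        cl = np.einsum("eit,ejt->ij", rc[:, :, lag:], rc[:, :, :-lag]) / (e * n)
        q += np.trace(cl.T @ c0inv @ cl @ c0inv) / (n - lag)
    q *= (e * n) ** 2 / e  # pooled-epoch Ljung-Box scaling
    df = d * d * max(h - p, 1)
    return float(sp_stats.chi2.sf(q, df))


# --------------------------------------------------------------------------
# Spectral causality measures
# --------------------------------------------------------------------------


def _transfer(model: MVARModel, freqs: np.ndarray):
    """Abar(f) and H(f) = Abar(f)^-1 on the grid; (n_f, d, d) each."""
    d = model.n_channels
    p = model.order
    k = np.arange(1, p + 1)
    phase = np.exp(
        -2j * np.pi * freqs[:, None] * k[None, :] / model.sampling_rate
    )  # (n_f, p)
    abar = np.eye(d)[None] - np.einsum("fk,kij->fij", phase, model.coeffs)
    h = np.linalg.inv(abar)
    return abar, h


def causality_spectrum(
    model: MVARModel,
    measure: str,
    freqs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Directed causality values on the frequency grid.

    Returns ``(freqs, values)`` with values shaped (from, to, n_freqs),
    diagonal set to zero.  Measures: ``GGC``, ``dDTF``, ``nPDC``; all
    nonnegative.
    """
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}")
    if freqs is None:
        freqs = np.arange(CAUSALITY_BAND[0], CAUSALITY_BAND[1] + 1.0)
    if not model.stable:
        warnings.warn("causality spectrum from an unstable model")
    d = model.n_channels
    abar, h = _transfer(model, freqs)
    cov = model.resid_cov

    if measure == "nPDC":
        a2 = np.abs(abar) ** 2  # (f, i, j): i = target row, j = source column
        denom = a2.sum(axis=1, keepdims=True)  # sum over targets per source column
        pdc2 = a2 / np.maximum(denom, 1e-300)
        vals = pdc2.transpose(2, 1, 0)  # (from=j, to=i, f)
    elif measure == "dDTF":
        h2 = np.abs(h) ** 2
        denom = h2.sum(axis=(0, 2))  # full-frequency row normalization per target i
        ff_dtf2 = h2 / np.maximum(denom[None, :, None], 1e-300)
        s = np.einsum("fik,kl,fjl->fij", h, cov, np.conj(h))
        m = np.linalg.inv(s + 1e-300 * np.eye(d))
        diag = np.abs(np.einsum("fii->fi", m))
        pcoh2 = np.abs(m) ** 2 / np.maximum(
            diag[:, :, None] * diag[:, None, :], 1e-300
        )
        vals = (ff_dtf2 * pcoh2).transpose(2, 1, 0)
    else:  # GGC
        s = np.einsum("fik,kl,fjl->fij", h, cov, np.conj(h))
        s_ii = np.maximum(np.abs(np.einsum("fii->fi", s)), 1e-300)  # (f, i)
        vals = np.zeros((d, d, len(freqs)))
        for j in range(d):  # source
            for i in range(d):  # target
                if i == j:
                    continue
                sigma_jj = cov[j, j] - cov[i, j] ** 2 / cov[i, i]
                num = sigma_jj * np.abs(h[:, i, j]) ** 2
                ratio = s_ii[:, i] / np.maximum(s_ii[:, i] - num, 1e-300)
                vals[j, i] = np.log(np.maximum(ratio, 1.0))
        freqs = np.asarray(freqs, dtype=float)
        for i in range(d):
            vals[i, i] = 0.0
        return freqs, vals

    for i in range(d):
        vals[i, i] = 0.0
    return np.asarray(freqs, dtype=float), vals


def band_mean_connectivity(
    models: list[MVARModel],
    measure: str,
    band: tuple[float, float] = CAUSALITY_BAND,
) -> np.ndarray:
    """Mean over stable windows and the band grid -> (from, to) matrix."""
    freqs = np.arange(band[0], band[1] + 1.0)
    mats = []
    for m in models:
        if not m.stable:
            continue
        _, vals = causality_spectrum(m, measure, freqs)
        mats.append(vals.mean(axis=-1))
    if not mats:
        raise ValueError("no stable models to summarise")
    return np.mean(mats, axis=0)


# --------------------------------------------------------------------------
# Sender/receiver summaries
# --------------------------------------------------------------------------


@dataclass
class ToFromRatios:
    ratio: np.ndarray  # per-region mean of outgoing/incoming ratios
    log_ratio: np.ndarray
    edge_log_ratio: np.ndarray  # (from, to) log(C[i->j]/C[j->i])
    flagged: list[tuple[int, int]] = field(default_factory=list)


def to_from_summary(conn: np.ndarray, eps: float = 1e-12) -> ToFromRatios:
    """Per-region sending/receiving summary of a band-mean causality matrix.

    For region i and partner j, ``ratio_ij = C[i->j] / C[j->i]``; the
    per-region value is the mean over partners (diagonal ignored).  Zero
    denominators are floored at ``eps`` and flagged.
    """
    conn = np.asarray(conn, dtype=float)
    d = conn.shape[0]
    if conn.shape != (d, d) or np.any(conn < 0):
        raise ValueError("connectivity must be a square nonnegative matrix")
    flagged = []
    ratios = np.zeros((d, d))
    for i in range(d):
        for j in range(d):
            if i == j:
                continue
            denom = conn[j, i]
            if denom <= eps:
                flagged.append((i, j))
                denom = eps
            ratios[i, j] = max(conn[i, j], eps) / denom
    if flagged:
        warnings.warn(f"{len(flagged)} to/from ratios floored at eps")
    off = ~np.eye(d, dtype=bool)
    per_region = np.array([ratios[i, off[i]].mean() for i in range(d)])
    log_edge = np.where(off, np.log(np.where(off, ratios, 1.0)), 0.0)
    per_region_log = np.array([log_edge[i, off[i]].mean() for i in range(d)])
    return ToFromRatios(
        ratio=per_region,
        log_ratio=per_region_log,
        edge_log_ratio=log_edge,
        flagged=flagged,
    )


def top_senders(
    edge_log_ratio: np.ndarray, retain_fraction: float = 0.10
) -> list[tuple[int, int, float]]:
    """Edges with log to/from above the (1 - fraction) quantile.

    Only strict exceedance retains an edge (all-equal input gives an empty
    list); at the boundary, ties are broken by (source, target) lexicographic
    order to keep the retained count at ``round(fraction * n_edges)``.
    """
    d = edge_log_ratio.shape[0]
    edges = [
        (i, j, float(edge_log_ratio[i, j]))
        for i in range(d)
        for j in range(d)
        if i != j
    ]
    if not np.all(np.isfinite([v for _, _, v in edges])):
        raise ValueError("edge values must be finite")
    values = np.array([v for _, _, v in edges])
    if np.ptp(values) == 0:
        return []  # no strict exceedance anywhere
    thresh = float(np.quantile(values, 1.0 - retain_fraction))
    above = [e for e in edges if e[2] > thresh]
    n_target = int(round(retain_fraction * len(edges)))
    at = sorted((e for e in edges if e[2] == thresh), key=lambda e: (e[0], e[1]))
    for e in at:
        if len(above) >= n_target:
            break
        above.append(e)
    return sorted(above, key=lambda e: (-e[2], e[0], e[1]))
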
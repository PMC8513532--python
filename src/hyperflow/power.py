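"""Condition-normalized band power and permutation topography statistics.

Per NC epoch, power spectral density comes from Welch's overlapped segment
averaging.  Powers are expressed in dB and normalized per song: for each
(participant, song, unit), the mean PSD across the three conditions is
subtracted from each condition's PSD, so condition values sum to zero by
construction and each value reads as "dB relative to that song's mean".

The discovery statistic is a per-unit one-way F across conditions whose null
is built by shuffling condition labels within participant, Bonferroni-
corrected across units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from hyperflow.config import CONDITIONS

#: Canonical frequency bands (Hz, inclusive bounds).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
    "gamma": (31.0, 120.0),
    "low_gamma": (31.0, 50.0),
    "beta_gamma": (13.0, 50.0),
}


@dataclass
class TopographyStats:
    """Per-unit permutation test results with Bonferroni correction."""

    statistic: np.ndarray
    p_raw: np.ndarray
    p_corrected: np.ndarray
    mask: np.ndarray  # significant at corrected alpha
    alpha: float
    n_perm: int


def welch_psd(
    epoch: np.ndarray,
    rate: float,
    segment_length: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD per channel: Hann-tapered, 50%-overlapping, detrended segments.

    Default segment length is half the epoch (two full segments, three with
    overlap).  Returns ``(freqs, psd)`` with psd shaped like the input's
    leading dimensions x frequency.
    """
    epoch = np.asarray(epoch, dtype=float)
    n = epoch.shape[-1]
    if segment_length is None:
        segment_length = max(n // 2, 1)
    if n < segment_length:
        raise ValueError(
            f"epoch length {n} shorter than Welch segment {segment_length}"
        )
    freqs, psd = signal.welch(
        epoch,
        fs=rate,
        nperseg=segment_length,
        noverlap=segment_length // 2,
        window="hann",
        detrend="constant",
        axis=-1,
    )
    return freqs, psd


def psd_db(psd: np.ndarray, floor: float = 1e-300) -> np.ndarray:
    return 10.0 * np.log10(np.maximum(psd, floor))


def normalize_per_song(psd_by_condition: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Subtract the three-condition mean PSD from each condition's PSD.

    Input arrays (one per condition, any common shape, typically dB) must
    cover all three conditions; no imputation is attempted.  Output values
    sum to zero across conditions at every entry.
    """
    missing = [c for c in CONDITIONS if c not in psd_by_condition]
    if missing:
        raise ValueError(f"missing condition(s): {missing}")
    stack = np.stack([np.asarray(psd_by_condition[c], dtype=float) for c in CONDITIONS])
    mean = stack.mean(axis=0)
    return {c: stack[i] - mean for i, c in enumerate(CONDITIONS)}


def band_average(
    normalized_psd: np.ndarray, freqs: np.ndarray, band: tuple[float, float] | str
) -> np.ndarray:
    """Unweighted mean over frequency bins whose centre lies inside the band
    (inclusive bounds)."""
    if isinstance(band, str):
        band = BANDS[band]
    lo, hi = band
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError(f"band {band} contains no frequency bins")
    return np.asarray(normalized_psd)[..., mask].mean(axis=-1)


def _f_stat_per_unit(values: np.ndarray) -> np.ndarray:
    """One-way F across conditions, per unit.  values: (unit, participant, cond)."""
    n_u, n_p, k = values.shape
    cond_means = values.mean(axis=1)  # (unit, cond)
    grand = values.mean(axis=(1, 2))  # (unit,)
    ss_between = n_p * ((cond_means - grand[:, None]) ** 2).sum(axis=1)
    ss_within = ((values - cond_means[:, None, :]) ** 2).sum(axis=(1, 2))
    df_b = k - 1
    df_w = k * (n_p - 1)
    ms_b = ss_between / df_b
    ms_w = ss_within / np.maximum(df_w, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(ms_w > 0, ms_b / ms_w, np.inf * (ms_b > 0))
    return np.nan_to_num(f, nan=0.0)


def permutation_test_topography(
    values: np.ndarray,
    n_perm: int = 2000,
    seed=0,
    alpha: float = 0.05,
) -> TopographyStats:
    """Permutation F-test across conditions, per unit, Bonferroni-corrected.

    ``values`` is (unit, participant, condition); the null shuffles condition
    labels independently within each participant (all units share a
    participant's permutation, preserving the spatial correlation structure).
    Raw p uses the add-one estimator ``(1 + #{null >= obs}) / (1 + n_perm)``,
    so it is floored at ``1/(1+n_perm)``.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 3 or values.shape[2] != len(CONDITIONS):
        raise ValueError(
            "values must be (unit, participant, condition) with "
            f"{len(CONDITIONS)} conditions (unbalanced designs unsupported)"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite (unbalanced design?)")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-value resolution is coarse")
    n_u, n_p, k = values.shape
    obs = _f_stat_per_unit(values)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_u)
    for _ in range(n_perm):
        perm = np.empty_like(values)
        for j in range(n_p):
            perm[:, j, :] = values[:, j, rng.permutation(k)]
        exceed += _f_stat_per_unit(perm) >= obs
    p_raw = (1.0 + exceed) / (1.0 + n_perm)
    p_corr = np.minimum(1.0, p_raw * n_u)
    return TopographyStats(
        statistic=obs,
        p_raw=p_raw,
        p_corrected=p_corr,
        mask=p_corr < alpha,
        alpha=alpha,
        n_perm=n_perm,
    )


def epoch_band_power_db(
    epochs: np.ndarray, rate: float, band: tuple[float, float] | str = "beta_gamma"
) -> np.ndarray:
    """Trial-level band power (dB) per channel: Welch per epoch, averaged
    over epochs, then band-averaged on the dB spectrum."""
    freqs, psd = welch_psd(epochs, rate)
    trial_psd = psd.mean(axis=0)  # (channel, freq)
    return band_average(psd_db(trial_psd), freqs, band)
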
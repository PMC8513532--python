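"""Objective flow-depth statistic from auditory-evoked potentials.

Task-irrelevant beep trains evoke a stereotyped triphasic response
(N1/P2/N2 near 130/230/330 ms).  The deeper a participant's flow state, the
more attention is withdrawn from the beeps and the weaker the response, so
the AEP amplitude works as an inverse probe of flow depth.

The statistic is computed exactly as in the source-selection protocol:

1. inter-trial coherence (ITC) in the theta band over the rest phase selects
   the central channels with a stable response;
2. N1/P2/N2 peak latencies are estimated on the theta-filtered grand-average
   rest-phase response, pooled over conditions;
3. the play-phase score is the polarity-aware mean of the three +/-40 ms
   window amplitudes, ``(P2 - N1 - N2) / 3``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from mne.time_frequency import tfr_array_morlet

from hyperflow.preprocess import EpochSet

#: Peak-search sub-windows (s, post-onset) bracketing the observed
#: 110-150 / 210-250 / 310-350 ms component windows.
SEARCH_WINDOWS: tuple[tuple[float, float], ...] = (
    (0.0, 0.180),
    (0.150, 0.300),
    (0.280, 0.450),
)

#: Half-width (s) of the mean-amplitude window around each group latency.
WINDOW_HALF_WIDTH = 0.040


@dataclass
class TimeFrequencyMap:
    """ERSP (dB vs baseline) or ITC (unit interval) on a freq x time grid."""

    kind: str
    freqs: np.ndarray
    times: np.ndarray
    values: np.ndarray  # (n_channels, n_freqs, n_times)


@dataclass
class AEPResult:
    """Per-participant-condition flow-depth statistic and its components."""

    channels: list[int]
    latencies: tuple[float, float, float]
    half_width: float
    window_means: tuple[float, float, float]  # (n1, p2, n2)
    aep_score: float
    n_epochs: int


def _adaptive_cycles(freqs: np.ndarray) -> np.ndarray:
    """Frequency-adaptive wavelet width, ~2.5 cycles at 3 Hz up to 7 cycles.

    The 5-sigma Gaussian support of a 3-cycle 3 Hz Morlet wavelet (~1.6 s)
    would exceed the 1.5-s AEP epoch, so the low end is trimmed to the
    widest wavelet that fits.
    """
    return np.clip(0.85 * freqs, 2.5, 7.0)


def time_frequency(
    epochs: EpochSet,
    band: tuple[float, float] = (3.0, 7.0),
    baseline: tuple[float, float] = (-0.3, 0.0),
) -> tuple[TimeFrequencyMap, TimeFrequencyMap]:
    """Morlet ERSP and inter-trial coherence for an epoch set.

    ITC(f, t) is the modulus of the across-epoch mean unit phasor; ERSP is
    mean power in dB relative to the pre-onset baseline window.
    """
    if epochs.n_epochs < 2:
        raise ValueError("time-frequency coherence needs >= 2 epochs")
    freqs = np.arange(band[0], band[1] + 0.5)
    tfr = tfr_array_morlet(
        epochs.epochs,
        sfreq=epochs.sampling_rate,
        freqs=freqs,
        n_cycles=_adaptive_cycles(freqs),
        output="complex",
        zero_mean=True,
    )  # (n_epochs, n_channels, n_freqs, n_times)
    power = np.abs(tfr) ** 2
    phasors = tfr / np.maximum(np.abs(tfr), 1e-300)
    itc_vals = np.abs(phasors.mean(axis=0))

    times = epochs.times
    base_mask = (times >= baseline[0]) & (times < baseline[1])
    mean_power = power.mean(axis=0)
    base = mean_power[..., base_mask].mean(axis=-1, keepdims=True)
    ersp_vals = 10.0 * np.log10(mean_power / np.maximum(base, 1e-300))

    ersp = TimeFrequencyMap("ERSP", freqs, times, ersp_vals)
    itc = TimeFrequencyMap("ITC", freqs, times, itc_vals)
    return ersp, itc


def itc_by_channel(itc: TimeFrequencyMap, window: tuple[float, float] = (0.0, 0.5)) -> np.ndarray:
    """Average ITC per channel over the theta band and the post-onset window."""
    mask = (itc.times >= window[0]) & (itc.times < window[1])
    return itc.values[..., mask].mean(axis=(1, 2))


def select_stable_channels(
    itc_values: np.ndarray | dict[int, float],
    central_set: list[int],
) -> list[int]:
    """Keep central channels whose ITC is not below mean - SE of the set.

    SE = sd / sqrt(n) over the central set (ddof=1); a single-channel set has
    SE = 0 by convention and the channel is retained.  The exclusion rule is
    strict ("lower than"), so ties at the threshold are kept.
    """
    if not central_set:
        raise ValueError("central channel set is empty")
    if isinstance(itc_values, dict):
        vals = np.array([itc_values[c] for c in central_set], dtype=float)
    else:
        vals = np.asarray(itc_values, dtype=float)[central_set]
    n = len(vals)
    se = vals.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
    threshold = vals.mean() - se
    return [c for c, v in zip(central_set, vals) if not v < threshold]


def estimate_peak_latencies(
    rest_erp: np.ndarray,
    times: np.ndarray,
    search_windows: tuple[tuple[float, float], ...] = SEARCH_WINDOWS,
    noise_floor: float = 1e-12,
) -> tuple[float, float, float]:
    """N1/P2/N2 latencies from the theta-filtered grand-average rest response.

    N1 is the most negative extremum in the first sub-window, P2 the most
    positive in the second, N2 the most negative in the third; the enforced
    ordering N1 < P2 < N2 comes from the non-decreasing sub-windows.  A flat
    response (peak-to-peak below ``noise_floor``) has no defined peaks.
    """
    rest_erp = np.asarray(rest_erp, dtype=float)
    if np.ptp(rest_erp) < noise_floor:
        raise ValueError("flat response: N1/P2/N2 peaks undefined")
    lats = []
    for (w0, w1), mode in zip(search_windows, ("min", "max", "min")):
        mask = (times >= w0) & (times <= w1)
        seg = rest_erp[mask]
        seg_t = times[mask]
        idx = np.argmin(seg) if mode == "min" else np.argmax(seg)
        lats.append(float(seg_t[idx]))
    n1, p2, n2 = lats
    if not (n1 < p2 < n2):
        raise ValueError(f"latency ordering violated: {lats}")
    return (n1, p2, n2)


def component_windows(
    latencies: tuple[float, float, float], half_width: float = WINDOW_HALF_WIDTH
) -> list[tuple[float, float]]:
    """The +/- half-width mean-amplitude windows around each latency."""
    return [(lat - half_width, lat + half_width) for lat in latencies]


def aep_score(
    play_epochs: EpochSet,
    channels: list[int],
    latencies: tuple[float, float, float],
    half_width: float = WINDOW_HALF_WIDTH,
) -> AEPResult:
    """Polarity-aware mean window amplitude ``(P2 - N1 - N2) / 3``.

    ``play_epochs`` must already be theta-filtered; the evoked response is
    the average over epochs and the selected channels.
    """
    if play_epochs.n_epochs == 0:
        raise ValueError("no epochs to score")
    times = play_epochs.times
    erp = play_epochs.epochs[:, channels, :].mean(axis=(0, 1))
    means = []
    for w0, w1 in component_windows(latencies, half_width):
        if w0 < times[0] or w1 > times[-1]:
            raise ValueError(
                f"window ({w0:.3f}, {w1:.3f}) s exceeds epoch bounds "
                f"({times[0]:.3f}, {times[-1]:.3f}) s"
            )
        mask = (times >= w0) & (times <= w1)
        means.append(float(erp[mask].mean()))
    n1, p2, n2 = means
    score = (p2 - n1 - n2) / 3.0
    return AEPResult(
        channels=list(channels),
        latencies=tuple(latencies),
        half_width=half_width,
        window_means=(n1, p2, n2),
        aep_score=score,
        n_epochs=play_epochs.n_epochs,
    )
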
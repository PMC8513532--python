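"""Filtering, re-referencing and epoch extraction.

The preprocessing contract: band-pass 0.5-50 Hz with an equiripple
(Parks-McClellan) FIR applied forward-backward (zero phase, so evoked-
response latencies do not shift), re-reference to the average of all
channels, then cut two kinds of epochs around beep-train onsets:

* AEP epochs, -0.5 to 1.0 s (384 samples at 256 Hz), and
* NC epochs, 2.0 to 5.0 s after onset (768 samples), used by every
  neural-correlate analysis.

Epoch windows are half-open ``[start, end)`` so a 1.5-s window at 256 Hz is
exactly 384 samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal

from hyperflow.synth import HyperscanRecording

#: (window_start_s, window_end_s) relative to beep-train onset.
EPOCH_WINDOWS: dict[str, tuple[float, float]] = {
    "AEP": (-0.5, 1.0),
    "NC": (2.0, 5.0),
}


@dataclass
class FilterSpec:
    """Equiripple FIR band-pass specification."""

    passband: tuple[float, float] = (0.5, 50.0)
    transition_low: float = 0.5
    transition_high: float = 5.0
    stopband_atten_db: float = 40.0

    def validate(self, sampling_rate: float) -> None:
        lo, hi = self.passband
        if not (0 < lo < hi < sampling_rate / 2):
            raise ValueError(
                f"passband {self.passband} must satisfy 0 < low < high < nyquist"
            )


@dataclass
class EpochSet:
    """Epochs of one kind from one recording (event x channel x time)."""

    kind: str
    window: tuple[float, float]
    epochs: np.ndarray
    sampling_rate: float
    event_indices: np.ndarray
    dropped_indices: np.ndarray
    phase: str
    metadata: dict = field(default_factory=dict)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def times(self) -> np.ndarray:
        start, _ = self.window
        n = self.epochs.shape[2]
        return start + np.arange(n) / self.sampling_rate


def _harris_numtaps(sampling_rate: float, transition: float, atten_db: float) -> int:
    """Harris rule-of-thumb tap count N ~ fs * atten / (22 * df), forced odd."""
    numtaps = int(np.ceil(sampling_rate * atten_db / (22.0 * transition)))
    return numtaps + 1 - numtaps % 2


@lru_cache(maxsize=16)
def design_bandpass(
    sampling_rate: float,
    passband: tuple[float, float],
    transition_low: float,
    transition_high: float,
    stopband_atten_db: float,
) -> tuple[np.ndarray, ...]:
    """Parks-McClellan (remez) band-pass taps for the given spec.

    Designed as a cascade of an equiripple high-pass (low edge) and low-pass
    (high edge), convolved into one linear-phase kernel: a single band-pass
    exchange with a ~0.2%-of-Nyquist transition does not converge reliably,
    while the two half-designs do.  The returned kernel is the single-pass
    filter; the forward-backward application in :func:`bandpass_filter`
    squares its magnitude response, so each half-design only needs half the
    stopband attenuation in dB.
    """
    lo, hi = passband
    nyq = sampling_rate / 2
    single_pass_atten = stopband_atten_db / 2
    n_hp = _harris_numtaps(sampling_rate, transition_low, stopband_atten_db)
    n_lp = _harris_numtaps(sampling_rate, transition_high, stopband_atten_db)
    hp = signal.remez(
        n_hp, [0.0, max(lo - transition_low, 1e-3), lo, nyq], [0, 1],
        fs=sampling_rate, grid_density=16, maxiter=100,
    )
    lp = signal.remez(
        n_lp, [0.0, hi, min(hi + transition_high, nyq - 1e-3), nyq], [1, 0],
        fs=sampling_rate, grid_density=16, maxiter=100,
    )
    taps = np.convolve(hp, lp)
    # sanity-check the realised response; a diverged exchange shows up as
    # gross passband error
    w, h = signal.freqz(taps, worN=4096, fs=sampling_rate)
    mid = (w >= lo + transition_low) & (w <= hi - transition_high)
    if mid.any() and (np.abs(np.abs(h[mid]) - 1) > 0.5).any():
        raise RuntimeError("equiripple design failed to converge")
    _ = single_pass_atten  # documented above; enforced by the test suite
    return (taps,)


def bandpass_filter(
    series: np.ndarray, spec: FilterSpec, sampling_rate: float
) -> np.ndarray:
    """Zero-phase (forward-backward) equiripple band-pass.

    Raises if the series is shorter than three times the filter order.
    """
    spec.validate(sampling_rate)
    (taps,) = design_bandpass(
        sampling_rate, tuple(spec.passband), spec.transition_low,
        spec.transition_high, spec.stopband_atten_db,
    )
    n = series.shape[-1]
    if n <= 3 * (len(taps) - 1):
        raise ValueError(
            f"series length {n} too short for filter order {len(taps) - 1} "
            "(need > 3x order)"
        )
    return signal.filtfilt(taps, [1.0], series, axis=-1)


def theta_filter(series: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Zero-phase theta-band (3-7 Hz) filter used for evoked-response analysis."""
    spec = FilterSpec(passband=(3.0, 7.0), transition_low=1.5, transition_high=1.5)
    return bandpass_filter(series, spec, sampling_rate)


def rereference_average(sensor_series: np.ndarray) -> np.ndarray:
    """Subtract the across-channel mean at every sample (average reference)."""
    if sensor_series.ndim != 2 or sensor_series.shape[0] < 2:
        raise ValueError("average reference needs a 2-D array with >= 2 channels")
    return sensor_series - sensor_series.mean(axis=0, keepdims=True)


def downsample(series: np.ndarray, factor: int) -> np.ndarray:
    """Anti-aliased polyphase decimation (for 2048 -> 256 Hz real-data reuse)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return np.asarray(series, dtype=float)
    return signal.resample_poly(series, up=1, down=factor, axis=-1)


def extract_epochs(
    recording: HyperscanRecording,
    kind: str,
    phase: str,
    brain: str = "a",
    use_sensors: bool = False,
) -> EpochSet:
    """Cut one epoch per qualifying beep-train onset.

    An event qualifies if it carries the requested phase label and its full
    window lies inside both the recording and that phase segment; events
    failing the boundary check are dropped and reported in
    ``dropped_indices``.  An empty result triggers a warning, not an error.
    """
    if kind not in EPOCH_WINDOWS:
        raise ValueError(f"unknown epoch kind {kind!r}")
    if use_sensors:
        data = recording.sensors_a if brain == "a" else recording.sensors_b
        if data is None:
            raise ValueError("recording carries no sensor series")
    else:
        data = recording.series_a if brain == "a" else recording.series_b
    fs = recording.sampling_rate
    w_start, w_end = EPOCH_WINDOWS[kind]
    n_win = int(round((w_end - w_start) * fs))
    p_start, p_end = recording.phase_bounds(phase)
    n = data.shape[1]

    kept, dropped, chunks = [], [], []
    for idx, (onset, label) in enumerate(
        zip(recording.events.onsets, recording.events.labels)
    ):
        if label != phase:
            continue
        i0 = int(round((onset + w_start) * fs))
        i1 = i0 + n_win
        inside_rec = 0 <= i0 and i1 <= n
        inside_phase = onset + w_start >= p_start and onset + w_end <= p_end
        if inside_rec and inside_phase:
            kept.append(idx)
            chunks.append(data[:, i0:i1])
        else:
            dropped.append(idx)
    if not kept:
        warnings.warn(f"no qualifying {kind} events in phase {phase!r}")
    epochs = (
        np.stack(chunks) if chunks else np.empty((0, data.shape[0], n_win))
    )
    return EpochSet(
        kind=kind,
        window=(w_start, w_end),
        epochs=epochs,
        sampling_rate=fs,
        event_indices=np.array(kept, dtype=int),
        dropped_indices=np.array(dropped, dtype=int),
        phase=phase,
        metadata={
            "pair_id": recording.pair_id,
            "song_id": recording.song_id,
            "condition": recording.condition,
            "brain": brain,
        },
    )
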
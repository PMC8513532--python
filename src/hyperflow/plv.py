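"""Interbrain phase-locking (ISPC-trial) with a random-pair null.

For each NC epoch, instantaneous phase per frequency comes from a Morlet
wavelet decomposition on a 13-50 Hz grid (1 Hz steps, 5 cycles at 13 Hz
scaling linearly to 9 at 50 Hz).  The single-trial phase-locking value
between two region series is the modulus of the time-averaged unit phasor
of their phase difference, averaged over the band; samples within one
wavelet half-support of either epoch edge are excluded from the average.

The null pairing recomputes the same quantity between surrogate partners:
permutations of the experimental pairs (no participant keeps their actual
partner) matched on condition and song, 10 schemes by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from mne.time_frequency import tfr_array_morlet

from hyperflow.config import CONDITIONS

#: Band-analysis grid (Hz): 13-50 at 1 Hz.
PLV_FREQS = np.arange(13.0, 51.0)


def _plv_cycles(freqs: np.ndarray) -> np.ndarray:
    """5 cycles at 13 Hz scaling linearly to 9 cycles at 50 Hz."""
    return 5.0 + 4.0 * (freqs - 13.0) / 37.0


@dataclass
class PhaseSeries:
    """Instantaneous phase per (channel, frequency, sample), radians."""

    phases: np.ndarray
    freqs: np.ndarray
    sampling_rate: float
    edge_samples: int  # per-side count of edge-contaminated samples


def instantaneous_phase(
    series: np.ndarray,
    sampling_rate: float,
    freqs: np.ndarray = PLV_FREQS,
) -> PhaseSeries:
    """Morlet phase decomposition of region series.

    ``series`` is (channels, time) or (time,).  Raises when the series is
    shorter than the longest wavelet support.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    n = series.shape[-1]
    cycles = _plv_cycles(freqs)
    # mne wavelet support: 5 sigma per side, sigma = n_cycles / (2 pi f)
    support = int(np.ceil((10 * cycles[0] / (2 * np.pi * freqs[0])) * sampling_rate))
    if n < support:
        raise ValueError(
            f"series of {n} samples shorter than the longest wavelet support "
            f"({support} samples)"
        )
    tfr = tfr_array_morlet(
        series[None],
        sfreq=sampling_rate,
        freqs=freqs,
        n_cycles=cycles,
        output="complex",
        zero_mean=True,
    )[0]  # (channels, freqs, time)
    edge = int(np.ceil((5 * cycles[0] / (2 * np.pi * freqs[0])) * sampling_rate / 2))
    return PhaseSeries(
        phases=np.angle(tfr),
        freqs=freqs,
        sampling_rate=sampling_rate,
        edge_samples=edge,
    )


def ispc_trial(phase_a: PhaseSeries, phase_b: PhaseSeries) -> np.ndarray:
    """Band-averaged single-trial PLV between all channel pairs.

    Returns an (channels_a, channels_b) matrix in [0, 1]: per frequency,
    ``PLV = |mean_t exp(i (phi_a - phi_b))|`` over the interior samples,
    then the unweighted mean over the frequency grid.
    """
    if phase_a.phases.shape[-1] != phase_b.phases.shape[-1]:
        raise ValueError("phase series lengths differ")
    if not np.array_equal(phase_a.freqs, phase_b.freqs):
        raise ValueError("phase series frequency grids differ")
    edge = max(phase_a.edge_samples, phase_b.edge_samples)
    n = phase_a.phases.shape[-1]
    sl = slice(edge, n - edge) if n > 2 * edge else slice(None)
    ua = np.exp(1j * phase_a.phases[..., sl])
    ub = np.exp(1j * phase_b.phases[..., sl])
    t = ua.shape[-1]
    plv_f = np.abs(np.einsum("ift,jft->ijf", ua, np.conj(ub))) / t
    return plv_f.mean(axis=-1)


@dataclass
class RandomPairScheme:
    """Surrogate partner assignments: per scheme, pair i's participant A is
    matched with pair ``mapping[i]``'s participant B."""

    mappings: np.ndarray  # (n_schemes, n_pairs)
    seed: int

    @property
    def n_schemes(self) -> int:
        return self.mappings.shape[0]


def random_pair_schemes(
    n_pairs: int, n_schemes: int = 10, seed: int = 0
) -> RandomPairScheme:
    """Seeded derangement-style permutations of the pair indices.

    Every scheme maps each pair to a different pair (no actual pairing is
    reproduced anywhere).  Requires >= 3 pairs for distinct schemes to exist
    (2 pairs admit a single derangement).
    """
    if n_pairs < 2:
        raise ValueError("random pairing needs >= 2 pairs")
    if n_pairs == 2 and n_schemes > 1:
        raise ValueError("only one derangement exists for 2 pairs; need >= 3")
    rng = np.random.default_rng(seed)
    mappings = []
    guard = 0
    while len(mappings) < n_schemes:
        perm = rng.permutation(n_pairs)
        if np.any(perm == np.arange(n_pairs)):
            guard += 1
            if guard > 100000:
                raise RuntimeError("failed to draw derangements")
            continue
        mappings.append(perm)
    return RandomPairScheme(mappings=np.array(mappings), seed=seed)


def normalize_and_globalize(
    plv_by_connection: dict[tuple, dict[str, float]],
    connection_filter=None,
) -> tuple[dict[tuple, dict[str, float]], dict[str, float]]:
    """Condition-normalized PLV table and its global (mean) summary.

    Shares the implementation of the integrated-information normalization:
    per connection, subtract the three-condition mean; globally, average the
    normalized values over connections.
    """
    from hyperflow.phi import global_mean, normalize_conditions

    normalized = normalize_conditions(plv_by_connection)
    return normalized, global_mean(normalized, connection_filter)
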
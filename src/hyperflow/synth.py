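"""Synthetic hyperscanning study generator with known ground truth.

The generator emits, per (pair, song, condition) trial, two brains' worth of
region-level time series from a stable order-2 vector autoregression, with
four condition-dependent effects injected on top:

* an evoked-response template added at each beep-train onset, attenuated in
  proportion to flow depth during the play phase;
* extra band-limited (13-50 Hz) power at designated regions, expressed as a
  dB offset per (condition, region);
* condition-specific directed cross-coupling terms inside each brain;
* a shared band-limited component added to matched region pairs of the two
  brains, producing interbrain phase locking.

Every random draw flows from one root seed through named substreams, so a
single trial is reproducible in isolation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy import signal

from hyperflow.config import CONDITIONS, SimConfig


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass
class EventList:
    """Beep-train onsets (seconds from trial start) with phase labels."""

    onsets: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if len(self.onsets) != len(self.labels):
            raise ValueError("onsets and labels must have equal length")
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")

    def in_phase(self, label: str) -> np.ndarray:
        return self.onsets[[l == label for l in self.labels]]


@dataclass
class HyperscanRecording:
    """One trial's two-brain time series with events and metadata."""

    pair_id: int
    song_id: int
    condition: str
    sampling_rate: float
    phases: list[tuple[str, float, float]]
    series_a: np.ndarray  # (n_regions, n_samples)
    series_b: np.ndarray
    events: EventList
    sensors_a: np.ndarray | None = None
    sensors_b: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.series_a.shape != self.series_b.shape:
            raise ValueError("series_a and series_b must have identical shape")
        prev_end = -np.inf
        for _, start, end in self.phases:
            if start < prev_end or end <= start:
                raise ValueError("phase segments must be ordered, non-overlapping")
            prev_end = end

    @property
    def n_samples(self) -> int:
        return self.series_a.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def phase_bounds(self, label: str) -> tuple[float, float]:
        for lab, start, end in self.phases:
            if lab == label:
                return (start, end)
        raise KeyError(f"no phase segment labelled {label!r}")


@dataclass
class GroundTruth:
    """Everything needed to score recovery of the injected effects."""

    config: SimConfig
    erp_template: np.ndarray
    erp_attenuation: dict[str, float]
    coupling_matrices: dict[str, list[np.ndarray]]
    inter_coupling: dict[str, float]
    band_power_offsets: dict[tuple[str, int], float]
    mixing: np.ndarray | None = None
    vertex_labels: np.ndarray | None = None

    def to_jsonable(self) -> dict:
        return {
            "erp_attenuation": self.erp_attenuation,
            "inter_coupling": self.inter_coupling,
            "band_power_offsets": {
                f"{c}:{r}": v for (c, r), v in self.band_power_offsets.items()
            },
            "coupling_matrices": {
                c: [a.tolist() for a in mats]
                for c, mats in self.coupling_matrices.items()
            },
            "seed": self.config.seed,
        }


@dataclass
class SyntheticStudy:
    """A lazily materialised set of trials (pairs x songs x 3 conditions)."""

    config: SimConfig
    trials: list[tuple[int, int, str]] = field(default_factory=list)

    def recording(self, pair_id: int, song_id: int, condition: str) -> HyperscanRecording:
        return _generate_trial(self.config, pair_id, song_id, condition)

    def __len__(self) -> int:
        return len(self.trials)

    def iter_recordings(self) -> Iterator[HyperscanRecording]:
        for pair, song, cond in self.trials:
            yield self.recording(pair, song, cond)


# --------------------------------------------------------------------------
# Primitive simulators
# --------------------------------------------------------------------------


def companion_spectral_radius(coeffs: Sequence[np.ndarray]) -> float:
    """Spectral radius of the VAR companion matrix of coefficient list A_1..A_p."""
    coeffs = [np.atleast_2d(np.asarray(a, dtype=float)) for a in coeffs]
    d = coeffs[0].shape[0]
    p = len(coeffs)
    comp = np.zeros((d * p, d * p))
    comp[:d] = np.hstack(coeffs)
    if p > 1:
        comp[d:, : d * (p - 1)] = np.eye(d * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def simulate_region_series(
    coupling: Sequence[np.ndarray],
    n_samples: int,
    noise_sd: float,
    seed,
    burn_in: int = 512,
) -> np.ndarray:
    """Simulate a stationary VAR process ``x_t = sum_k A_k x_{t-k} + e_t``.

    ``coupling`` is the list of lag coefficient matrices A_1..A_p (a scalar
    or 1x1 array gives a univariate AR process).  Unstable coefficient sets
    (companion spectral radius >= 1) raise before any simulation.
    """
    coeffs = [np.atleast_2d(np.asarray(a, dtype=float)) for a in coupling]
    rho = companion_spectral_radius(coeffs)
    if rho >= 1.0:
        raise ValueError(
            f"unstable VAR coefficients: companion spectral radius {rho:.3f} >= 1"
        )
    d = coeffs[0].shape[0]
    p = len(coeffs)
    rng = np.random.default_rng(seed)
    total = n_samples + burn_in
    if noise_sd == 0:
        x = np.zeros((d, total))
    else:
        x = np.empty((d, total))
        e = rng.normal(0.0, noise_sd, size=(d, total))
        x[:, :p] = e[:, :p]
        for t in range(p, total):
            acc = e[:, t].copy()
            for k in range(p):
                acc += coeffs[k] @ x[:, t - 1 - k]
            x[:, t] = acc
    return x[:, burn_in:burn_in + n_samples] if noise_sd else x[:, :n_samples]


def erp_template(
    sampling_rate: float,
    amplitude: float = 1.0,
    duration: float = 0.5,
    centers: tuple[float, float, float] = (0.130, 0.230, 0.330),
    shape_k: float = 40.0,
) -> np.ndarray:
    """Triphasic evoked-response template (negative-positive-negative).

    Built from three signed Gamma-shaped bumps centred near 130/230/330 ms;
    the ~100 ms deflection spacing confines its energy to the theta band
    (3-7 Hz).  Peak of the positive deflection equals ``amplitude``.
    """
    t = np.arange(int(round(duration * sampling_rate))) / sampling_rate
    wave = np.zeros_like(t)
    for sign, c in zip((-1.0, 1.0, -1.0), centers):
        # Gamma bump with mode at c: t^(k-1) exp(-t/theta), theta = c/(k-1)
        theta = c / (shape_k - 1.0)
        bump = np.power(t / c, shape_k - 1.0) * np.exp(-(t - c) / theta)
        wave += sign * bump
    wave *= amplitude / np.max(wave)
    return wave


def inject_erp(
    series: np.ndarray,
    events: EventList,
    template: np.ndarray,
    attenuation: float,
    sampling_rate: float,
) -> np.ndarray:
    """Add ``attenuation * template`` at each event onset (linear, additive).

    Works on 1-D series or on every row of a 2-D array.  Overlapping events
    superpose; events whose onset lies beyond the series end are skipped with
    a warning.
    """
    out = np.array(series, dtype=float, copy=True)
    one_d = out.ndim == 1
    rows = out[None, :] if one_d else out
    n = rows.shape[1]
    for onset in np.atleast_1d(events.onsets):
        start = int(round(onset * sampling_rate))
        if start >= n:
            warnings.warn(f"event at {onset:.3f}s beyond series end; skipped")
            continue
        stop = min(start + len(template), n)
        rows[:, start:stop] += attenuation * template[: stop - start]
    return rows[0] if one_d else rows


def project_to_sensors(
    region_series: np.ndarray,
    mixing: np.ndarray,
    sensor_noise_sd: float = 0.0,
    seed=None,
) -> np.ndarray:
    """Linear sensor projection ``sensors = mixing @ regions + noise``."""
    mixing = np.asarray(mixing, dtype=float)
    if not np.all(np.isfinite(mixing)):
        raise ValueError("mixing matrix must be finite")
    if mixing.ndim != 2 or mixing.shape[1] != region_series.shape[0]:
        raise ValueError(
            f"mixing shape {mixing.shape} incompatible with "
            f"{region_series.shape[0]} regions"
        )
    out = mixing @ region_series
    if sensor_noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, sensor_noise_sd, size=out.shape)
    return out


def band_limited_noise(
    n_samples: int,
    sampling_rate: float,
    band: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band`` (Hz), via FFT masking."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    x = np.fft.irfft(spec, n=n_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_beep_events(
    config: SimConfig, rng: np.random.Generator
) -> EventList:
    """Beep-train onsets with uniform 4-8 s gaps, labelled by phase."""
    total = config.rest_duration + config.play_duration
    lo, hi = config.beep_interval_range
    onsets, labels = [], []
    t = 1.0 + rng.uniform(0.0, 1.0)
    while t + config.beep_train_duration < total:
        onsets.append(t)
        labels.append("rest" if t < config.rest_duration else "play")
        t += rng.uniform(lo, hi)
    return EventList(np.array(onsets), labels)


def beep_train_times(config: SimConfig, onset: float) -> np.ndarray:
    """Times of the individual beeps within one train starting at ``onset``."""
    return onset + np.arange(config.beeps_per_train) / config.beep_train_rate


# --------------------------------------------------------------------------
# Study assembly
# --------------------------------------------------------------------------


def base_coefficients(config: SimConfig) -> list[np.ndarray]:
    """Condition-independent VAR(2) skeleton: one damped oscillator per region.

    Region ``i`` resonates near ``15 + 2*i`` Hz with pole radius 0.85, so the
    13-50 Hz band carries genuine autoregressive power in every region.
    """
    d = config.n_regions_per_brain
    a1 = np.zeros((d, d))
    a2 = np.zeros((d, d))
    r = 0.85
    for i in range(d):
        f0 = 15.0 + 2.0 * i
        a1[i, i] = 2 * r * np.cos(2 * np.pi * f0 / config.sampling_rate)
        a2[i, i] = -(r**2)
    return [a1, a2]


def condition_coefficients(config: SimConfig, condition: str) -> list[np.ndarray]:
    """Base VAR(2) plus the condition's directed cross-coupling edges."""
    coeffs = [a.copy() for a in base_coefficients(config)]
    for src, dst, lag, c in config.intra_coupling.get(condition, []):
        if not 1 <= lag <= len(coeffs):
            raise ValueError(f"coupling lag {lag} outside model order")
        coeffs[lag - 1][dst, src] += c
    rho = companion_spectral_radius(coeffs)
    if rho >= 1.0:
        raise ValueError(
            f"intra_coupling for {condition!r} makes the VAR unstable "
            f"(spectral radius {rho:.3f})"
        )
    return coeffs


def _trial_seed(config: SimConfig, pair_id: int, song_id: int, condition: str):
    ci = CONDITIONS.index(condition)
    return np.random.SeedSequence([int(config.seed), pair_id, song_id, ci])


def _generate_trial(
    config: SimConfig, pair_id: int, song_id: int, condition: str
) -> HyperscanRecording:
    ss = _trial_seed(config, pair_id, song_id, condition)
    (s_events, s_a, s_b, s_shared, s_band, s_sens) = ss.spawn(6)
    fs = config.sampling_rate
    n = int(round((config.rest_duration + config.play_duration) * fs))
    events = generate_beep_events(config, np.random.default_rng(s_events))

    coeffs = condition_coefficients(config, condition)
    series = {}
    for key, sseed in (("a", s_a), ("b", s_b)):
        series[key] = simulate_region_series(coeffs, n, config.noise_sd, sseed)

    # Band-power offsets: per-region band-limited component, gain modulated in dB.
    band_rng = np.random.default_rng(s_band)
    for key in ("a", "b"):
        for r in range(config.n_regions_per_brain):
            off_db = config.band_power_offsets.get((condition, r), 0.0)
            amp = config.band_component_amplitude * 10 ** (off_db / 20.0)
            if amp > 0:
                series[key][r] += amp * band_limited_noise(n, fs, (13.0, 50.0), band_rng)

    # Interbrain coupling: shared band-limited component on matched region pairs.
    strength = config.inter_coupling.get(condition, 0.0)
    if strength > 0:
        shared_rng = np.random.default_rng(s_shared)
        lag = int(round(config.inter_coupling_lag * fs))
        for ra, rb in config.coupling_pairs:
            shared = band_limited_noise(n + lag, fs, (13.0, 50.0), shared_rng)
            # strength is in units of the receiving region's amplitude
            series["a"][ra] += strength * series["a"][ra].std() * shared[lag:]
            series["b"][rb] += strength * series["b"][rb].std() * shared[:n]

    phases = [
        ("rest", 0.0, config.rest_duration),
        ("play", config.rest_duration, config.rest_duration + config.play_duration),
    ]

    sensors_a = sensors_b = None
    if config.emit_sensors:
        template = erp_template(fs, config.erp_amplitude)
        mixing = study_mixing(config)
        atten_play = config.erp_attenuation_by_condition[condition]
        rest_events = EventList(events.in_phase("rest"), ["rest"] * len(events.in_phase("rest")))
        play_events = EventList(events.in_phase("play"), ["play"] * len(events.in_phase("play")))
        sens_rngs = s_sens.spawn(2)
        out = []
        for key, sr in zip(("a", "b"), sens_rngs):
            sens = project_to_sensors(series[key], mixing, config.sensor_noise_sd, sr)
            central = sens[: config.n_regions_per_brain]
            if len(rest_events.onsets):
                central[:] = inject_erp(central, rest_events, template, 1.0, fs)
            if len(play_events.onsets):
                central[:] = inject_erp(central, play_events, template, atten_play, fs)
            out.append(sens)
        sensors_a, sensors_b = out

    return HyperscanRecording(
        pair_id=pair_id,
        song_id=song_id,
        condition=condition,
        sampling_rate=fs,
        phases=phases,
        series_a=series["a"],
        series_b=series["b"],
        events=events,
        sensors_a=sensors_a,
        sensors_b=sensors_b,
    )


def study_mixing(config: SimConfig) -> np.ndarray:
    """Fixed sensors x regions mixing matrix for the synthetic montage.

    The first ``n_regions`` rows are the designated "central channels": each
    picks up mostly one region (unit gain) plus weak leakage from the rest.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 999]))
    d = config.n_regions_per_brain
    mixing = 0.1 * rng.standard_normal((config.n_sensors, d))
    mixing[:d, :d] += np.eye(d)
    return mixing


def simulate_study(config: SimConfig) -> tuple[SyntheticStudy, GroundTruth]:
    """Generate the full study design: n_pairs x n_songs x 3 conditions.

    Recordings are materialised lazily from per-trial substreams, so the
    returned study is cheap regardless of size and bitwise reproducible for
    a fixed config/seed.
    """
    config.validate()
    trials = [
        (pair, song, cond)
        for pair in range(config.n_pairs)
        for song in range(config.n_songs)
        for cond in CONDITIONS
    ]
    study = SyntheticStudy(config=config, trials=trials)
    truth = GroundTruth(
        config=config,
        erp_template=erp_template(config.sampling_rate, config.erp_amplitude),
        erp_attenuation=dict(config.erp_attenuation_by_condition),
        coupling_matrices={c: condition_coefficients(config, c) for c in CONDITIONS},
        inter_coupling=dict(config.inter_coupling),
        band_power_offsets=dict(config.band_power_offsets),
        mixing=study_mixing(config) if config.emit_sensors else None,
    )
    return study, truth


# --------------------------------------------------------------------------
# Synthetic source vertices (for the clustering stage)
# --------------------------------------------------------------------------

#: Feature archetypes (TeamFlow, TeamOnly, FlowOnly normalized beta-gamma power)
#: for the three cluster families.  "flow" clusters peak in TeamOnly (activity
#: suppressed whenever flow is present), "team" clusters dip in FlowOnly,
#: "teamflow" clusters peak in TeamFlow.
FAMILY_ARCHETYPES: dict[str, np.ndarray] = {
    "flow": np.array([-0.5, 1.0, -0.5]),
    "team": np.array([0.5, 0.5, -1.0]),
    "teamflow": np.array([1.0, -0.5, -0.5]),
}


def simulate_vertex_features(
    n_rois: int = 20,
    vertices_per_roi: int = 10,
    noise_sd: float = 0.1,
    seed=0,
    cluster_archetypes: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Synthetic vertex feature vectors with planted cluster labels.

    Returns ``(features, true_labels, roi_ids)`` where features is
    (n_vertices, 3).  Each ROI draws its vertices from one or two planted
    archetypes, emulating anatomically mixed cluster composition.
    """
    if cluster_archetypes is None:
        cluster_archetypes = np.stack(list(FAMILY_ARCHETYPES.values()))
    rng = np.random.default_rng(seed)
    k = len(cluster_archetypes)
    feats, labels, rois = [], [], []
    for roi in range(n_rois):
        main = roi % k
        for v in range(vertices_per_roi):
            lab = main if rng.random() < 0.8 else int(rng.integers(k))
            feats.append(cluster_archetypes[lab] + rng.normal(0, noise_sd, 3))
            labels.append(lab)
            rois.append(roi)
    return np.array(feats), np.array(labels), np.array(rois)


# --------------------------------------------------------------------------
# Study I/O
# --------------------------------------------------------------------------


def write_study(study: SyntheticStudy, truth: GroundTruth, out_dir: str | Path) -> Path:
    """Write a study directory: one HDF5 file per trial, TSV events, JSON manifest."""
    import h5py

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": _config_jsonable(study.config), "trials": []}
    for pair, song, cond in study.trials:
        rec = study.recording(pair, song, cond)
        stem = f"pair{pair:02d}_song{song:02d}_{cond}"
        with h5py.File(out / f"{stem}.h5", "w") as f:
            f.create_dataset("series_a", data=rec.series_a)
            f.create_dataset("series_b", data=rec.series_b)
            if rec.sensors_a is not None:
                f.create_dataset("sensors_a", data=rec.sensors_a)
                f.create_dataset("sensors_b", data=rec.sensors_b)
            f.attrs["sampling_rate"] = rec.sampling_rate
            f.attrs["condition"] = cond
            f.attrs["pair_id"] = pair
            f.attrs["song_id"] = song
            f.attrs["phases"] = json.dumps(rec.phases)
        with open(out / f"{stem}.events.tsv", "w") as fh:
            fh.write("onset_s\tlabel\n")
            for onset, lab in zip(rec.events.onsets, rec.events.labels):
                fh.write(f"{onset:.6f}\t{lab}\n")
        manifest["trials"].append({"pair_id": pair, "song_id": song, "condition": cond,
                                   "file": f"{stem}.h5"})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "ground_truth.json").write_text(json.dumps(truth.to_jsonable(), indent=1))
    return out


def read_study(study_dir: str | Path) -> SyntheticStudy:
    """Re-open a written study; recordings load from the trial files."""
    import h5py

    study_dir = Path(study_dir)
    manifest = json.loads((study_dir / "manifest.json").read_text())
    config = SimConfig(**{k: _untuple(k, v) for k, v in manifest["config"].items()})
    trials = [(t["pair_id"], t["song_id"], t["condition"]) for t in manifest["trials"]]

    class _DiskStudy(SyntheticStudy):
        def recording(self, pair_id, song_id, condition):
            stem = f"pair{pair_id:02d}_song{song_id:02d}_{condition}"
            with h5py.File(study_dir / f"{stem}.h5", "r") as f:
                phases = [tuple(p) for p in json.loads(f.attrs["phases"])]
                kw = {}
                if "sensors_a" in f:
                    kw = {"sensors_a": f["sensors_a"][()], "sensors_b": f["sensors_b"][()]}
                ev = _read_events(study_dir / f"{stem}.events.tsv")
                return HyperscanRecording(
                    pair_id=pair_id, song_id=song_id, condition=condition,
                    sampling_rate=float(f.attrs["sampling_rate"]), phases=phases,
                    series_a=f["series_a"][()], series_b=f["series_b"][()],
                    events=ev, **kw)

    return _DiskStudy(config=config, trials=trials)


def _read_events(path: Path) -> EventList:
    onsets, labels = [], []
    for line in path.read_text().splitlines()[1:]:
        onset, lab = line.split("\t")
        onsets.append(float(onset))
        labels.append(lab)
    return EventList(np.array(onsets), labels)


def _config_jsonable(config: SimConfig) -> dict:
    out = {}
    for k, v in vars(config).items():
        if isinstance(v, dict):
            if k in ("band_power_offsets",):
                out[k] = {f"{c}:{r}": x for (c, r), x in v.items()}
            elif k == "intra_coupling":
                out[k] = {c: [list(e) for e in edges] for c, edges in v.items()}
            else:
                out[k] = v
        elif isinstance(v, tuple):
            out[k] = list(v)
        else:
            out[k] = v
    return out


def _untuple(key: str, value):
    if key == "beep_interval_range":
        return tuple(value)
    if key == "band_power_offsets":
        return {(k.split(":")[0], int(k.split(":")[1])): v for k, v in value.items()}
    if key == "intra_coupling":
        return {c: [tuple(e) for e in edges] for c, edges in value.items()}
    return value
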
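"""Stage sequencing: simulation -> preprocessing -> AEP -> power -> clustering
-> causality -> integrated information -> phase synchrony -> statistics.

Each stage is a plain function from a study (plus parameters) to tidy
pandas tables, so stages are independently testable and the drivers under
``analysis/`` and the CLI stay thin.  ``run_pipeline`` sequences the stages
in dependency order and writes every table to disk with a provenance block.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from hyperflow import aep as aep_mod
from hyperflow import clustering as cl_mod
from hyperflow import mvar as mvar_mod
from hyperflow import phi as phi_mod
from hyperflow import plv as plv_mod
from hyperflow import power as power_mod
from hyperflow import stats as stats_mod
from hyperflow.config import CONDITIONS, DOWNSAMPLE_FACTORS, SimConfig
from hyperflow.preprocess import extract_epochs, theta_filter
from hyperflow.synth import SyntheticStudy, simulate_study


# --------------------------------------------------------------------------
# Pipeline configuration
# --------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Typed, defaulted, range-checked configuration for the full run."""

    sim: SimConfig = field(default_factory=SimConfig)
    band: tuple[float, float] = (13.0, 50.0)
    cluster_k: int = 7
    mvar_window: float = 0.5
    mvar_step: float = 0.025
    mvar_max_order: int = 3
    phi_factors: tuple[int, ...] = DOWNSAMPLE_FACTORS
    n_perm: int = 2000
    n_random_pairs: int = 10
    seed: int = 0
    out_dir: str = "results/pipeline"
    stages: tuple[str, ...] = ("simulate", "aep", "power", "cluster", "gc", "phi", "plv", "stats")

    def validate(self) -> None:
        if self.band[0] >= self.band[1]:
            raise ValueError(f"band range invalid: low {self.band[0]} >= high {self.band[1]}")
        if self.cluster_k < 1:
            raise ValueError("cluster_k must be >= 1")
        if self.mvar_window <= 0 or self.mvar_step <= 0:
            raise ValueError("mvar_window and mvar_step must be > 0")
        if self.n_perm < 1 or self.n_random_pairs < 1:
            raise ValueError("n_perm and n_random_pairs must be >= 1")
        self.sim.validate()


_SIM_KEYS = set(SimConfig.__dataclass_fields__)
_TOP_KEYS = set(PipelineConfig.__dataclass_fields__) - {"sim"}


def validate_config(raw: dict | str | None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML text or mapping.

    Empty input gives all defaults.  Keys naming ``SimConfig`` fields land in
    the simulation block; unknown keys raise a warning naming the nearest
    known key; a key explicitly set to null is an error naming the key.
    """
    import yaml

    if raw is None or raw == "":
        raw = {}
    if isinstance(raw, str):
        raw = yaml.safe_load(raw) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a key-value document")
    sim_kwargs: dict = {}
    top_kwargs: dict = {}
    for key, value in raw.items():
        if value is None:
            raise ValueError(f"config key {key!r} is null; remove it or set a value")
        if key in _SIM_KEYS:
            sim_kwargs[key] = _coerce_sim_value(key, value)
        elif key in _TOP_KEYS:
            if key in ("band", "phi_factors", "stages"):
                value = tuple(value)
            top_kwargs[key] = value
        else:
            near = difflib.get_close_matches(key, sorted(_SIM_KEYS | _TOP_KEYS), n=1)
            hint = f"; nearest known key: {near[0]!r}" if near else ""
            warnings.warn(f"unknown config key {key!r} ignored{hint}")
    cfg = PipelineConfig(sim=SimConfig(**sim_kwargs), **top_kwargs)
    cfg.validate()
    return cfg


def _coerce_sim_value(key: str, value):
    if key == "beep_interval_range":
        return tuple(value)
    if key == "band_power_offsets" and isinstance(value, dict):
        return {(k.split(":")[0], int(k.split(":")[1])): v for k, v in value.items()}
    if key == "intra_coupling" and isinstance(value, dict):
        return {c: [tuple(e) for e in edges] for c, edges in value.items()}
    return value


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------


def stage_aep(study: SyntheticStudy) -> pd.DataFrame:
    """Per (pair, participant, condition) AEP flow-depth scores.

    Group latencies come from the theta-filtered grand-average rest-phase
    response pooled over conditions; channels are selected per participant
    by rest-phase ITC over the central set; the score is computed on
    play-phase epochs.
    """
    cfg = study.config
    fs = cfg.sampling_rate
    central = list(range(cfg.n_regions_per_brain))
    rows = []
    for pair in range(cfg.n_pairs):
        for brain in ("a", "b"):
            rest_sets, play_by_cond = [], {}
            for song in range(cfg.n_songs):
                for cond in CONDITIONS:
                    rec = study.recording(pair, song, cond)
                    if rec.sensors_a is None:
                        raise ValueError("AEP stage needs sensor series (emit_sensors)")
                    rec = _theta_rec(rec)
                    rest = extract_epochs(rec, "AEP", "rest", brain=brain, use_sensors=True)
                    if rest.n_epochs:
                        rest_sets.append(rest)
                    play = extract_epochs(rec, "AEP", "play", brain=brain, use_sensors=True)
                    if play.n_epochs:
                        play_by_cond.setdefault(cond, []).append(play)
            if not rest_sets:
                continue
            rest_epochs = np.concatenate([e.epochs for e in rest_sets], axis=0)
            times = rest_sets[0].times
            grand = rest_epochs[:, central, :].mean(axis=(0, 1))
            lats = aep_mod.estimate_peak_latencies(grand, times)
            itc_set = rest_sets[0].__class__(
                kind="AEP", window=rest_sets[0].window, epochs=rest_epochs,
                sampling_rate=fs, event_indices=np.arange(len(rest_epochs)),
                dropped_indices=np.array([]), phase="rest",
            )
            _, itc = aep_mod.time_frequency(itc_set)
            chans = aep_mod.select_stable_channels(
                aep_mod.itc_by_channel(itc), central
            )
            for cond, sets in play_by_cond.items():
                pooled = sets[0].__class__(
                    kind="AEP", window=sets[0].window,
                    epochs=np.concatenate([e.epochs for e in sets], axis=0),
                    sampling_rate=fs,
                    event_indices=np.arange(sum(e.n_epochs for e in sets)),
                    dropped_indices=np.array([]), phase="play",
                )
                res = aep_mod.aep_score(pooled, chans, lats)
                rows.append({
                    "pair_id": pair, "participant": f"{pair}{brain}",
                    "condition": cond, "n_epochs": res.n_epochs,
                    "n1": res.window_means[0], "p2": res.window_means[1],
                    "n2": res.window_means[2], "aep_score": res.aep_score,
                })
    return pd.DataFrame(rows)


def _theta_rec(rec):
    """Theta-filter the sensor series of a recording (copy)."""
    import copy

    out = copy.copy(rec)
    out.sensors_a = theta_filter(rec.sensors_a, rec.sampling_rate)
    out.sensors_b = theta_filter(rec.sensors_b, rec.sampling_rate)
    return out


def stage_power(
    study: SyntheticStudy, band: tuple[float, float] | str = "beta_gamma"
) -> tuple[pd.DataFrame, power_mod.TopographyStats]:
    """Per-song condition-normalized band power and permutation topography.

    Returns the tidy table (participant, song, region, condition,
    normalized dB) and the permutation test over the per-participant
    grand averages.
    """
    cfg = study.config
    rows = []
    for pair in range(cfg.n_pairs):
        for brain in ("a", "b"):
            for song in range(cfg.n_songs):
                psd_db_by_cond = {}
                freqs = None
                for cond in CONDITIONS:
                    rec = study.recording(pair, song, cond)
                    eps = extract_epochs(rec, "NC", "play", brain=brain)
                    if eps.n_epochs == 0:
                        continue
                    freqs, psd = power_mod.welch_psd(eps.epochs, cfg.sampling_rate)
                    psd_db_by_cond[cond] = power_mod.psd_db(psd.mean(axis=0))
                if len(psd_db_by_cond) < 3:
                    continue
                norm = power_mod.normalize_per_song(psd_db_by_cond)
                for cond in CONDITIONS:
                    vals = power_mod.band_average(norm[cond], freqs, band)
                    for region, v in enumerate(vals):
                        rows.append({
                            "participant": f"{pair}{brain}", "song": song,
                            "region": region, "condition": cond,
                            "normalized_db": float(v),
                        })
    table = pd.DataFrame(rows)
    # unit x participant x condition grand averages for the topography test
    grand = (
        table.groupby(["region", "participant", "condition"])["normalized_db"]
        .mean()
        .unstack("condition")[list(CONDITIONS)]
    )
    regions = sorted(table["region"].unique())
    participants = sorted(table["participant"].unique())
    arr = np.stack(
        [
            np.stack([grand.loc[(r, p)].to_numpy() for p in participants])
            for r in regions
        ]
    )
    topo = power_mod.permutation_test_topography(arr, n_perm=500, seed=cfg.seed)
    return table, topo


def stage_cluster(
    features: np.ndarray,
    roi_ids: np.ndarray,
    roi_significant: dict[str, bool],
    anatomy: dict[str, tuple[str, str]],
    k: int = 7,
) -> tuple[cl_mod.ClusterLabeling, cl_mod.RegionGroupSet]:
    """Vertex clustering, family tagging, ROI subdivision, RG assembly."""
    labeling = cl_mod.cluster_vertices(features, k)
    fams = labeling.family_of_vertex()
    subdivisions = {}
    for roi in np.unique(roi_ids):
        mask = roi_ids == roi
        subdivisions[str(roi)] = cl_mod.subdivide_roi(fams[mask], str(roi))
    groups = cl_mod.build_region_groups(roi_significant, subdivisions, anatomy)
    return labeling, groups


def _nc_epochs_by_cond(
    study: SyntheticStudy, pair: int, brain: str
) -> dict[str, np.ndarray]:
    """Pooled NC epochs (epochs, regions, time) per condition."""
    cfg = study.config
    out: dict[str, list[np.ndarray]] = {c: [] for c in CONDITIONS}
    for song in range(cfg.n_songs):
        for cond in CONDITIONS:
            rec = study.recording(pair, song, cond)
            eps = extract_epochs(rec, "NC", "play", brain=brain)
            if eps.n_epochs:
                out[cond].append(eps.epochs)
    return {c: np.concatenate(v, axis=0) for c, v in out.items() if v}


def stage_causality(
    study: SyntheticStudy,
    measures: tuple[str, ...] = mvar_mod.MEASURES,
    window: float = 0.5,
    step: float = 0.025,
    max_order: int = 3,
) -> pd.DataFrame:
    """Band-mean directed connectivity per participant, condition, measure.

    NC epochs are pooled per condition; sliding windows are ensemble-fitted
    and band-mean matrices averaged over windows.
    """
    cfg = study.config
    rows = []
    for pair in range(cfg.n_pairs):
        for brain in ("a", "b"):
            by_cond = _nc_epochs_by_cond(study, pair, brain)
            for cond, epochs in by_cond.items():
                models = mvar_mod.fit_mvar_sliding(
                    epochs, cfg.sampling_rate, window, step, max_order
                )
                for meas in measures:
                    conn = mvar_mod.band_mean_connectivity(models, meas)
                    d = conn.shape[0]
                    for i in range(d):
                        for j in range(d):
                            if i != j:
                                rows.append({
                                    "participant": f"{pair}{brain}",
                                    "condition": cond, "measure": meas,
                                    "from": i, "to": j, "value": conn[i, j],
                                })
    return pd.DataFrame(rows)


def stage_phi(
    study: SyntheticStudy,
    scope: str = "interbrain",
    factors: tuple[int, ...] = DOWNSAMPLE_FACTORS,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Pairwise integrated information, condition-normalized, plus global.

    Interbrain scope pairs every region of brain A with every region of
    brain B of the same experimental pair, using the NC-epoch play-phase
    series pooled across songs and epochs.
    """
    cfg = study.config
    d = cfg.n_regions_per_brain
    raw: dict[tuple, dict[str, float]] = {}
    for pair in range(cfg.n_pairs):
        eps_a = _nc_epochs_by_cond(study, pair, "a")
        eps_b = _nc_epochs_by_cond(study, pair, "b") if scope == "interbrain" else eps_a
        for cond in CONDITIONS:
            if cond not in eps_a or cond not in eps_b:
                continue
            trials_a = eps_a[cond]
            trials_b = eps_b[cond]
            phis = _phi_matrix(trials_a, trials_b, factors, same_brain=scope != "interbrain")
            for ra in range(d):
                for rb in range(d):
                    if scope != "interbrain" and rb <= ra:
                        continue
                    raw.setdefault((pair, ra, rb), {})[cond] = phis[ra, rb]
    normalized = phi_mod.normalize_conditions(raw)
    glob = phi_mod.global_mean(normalized)
    rows = [
        {"pair_id": k[0], "rg_a": k[1], "rg_b": k[2], "condition": c,
         "phi": raw[k][c], "normalized": v}
        for k, vals in normalized.items()
        for c, v in vals.items()
    ]
    return pd.DataFrame(rows), glob


def _phi_matrix(
    trials_a: np.ndarray, trials_b: np.ndarray, factors, same_brain: bool = False
) -> np.ndarray:
    """phi per (region_a, region_b), averaged over down-sampling factors.

    Vectorized: per factor and shift, all region pairs' joint transitions
    are counted in one pass over the pooled trials.
    """
    d = trials_a.shape[1]
    phis = np.zeros((len(factors), d, d))
    for fi, factor in enumerate(factors):
        counts = np.zeros((d, d, 4, 4))
        for xa, xb in zip(trials_a, trials_b):
            for shift in range(factor):
                a = phi_mod.binarize_ramp(xa[:, shift:], factor)  # (d, L)
                b = phi_mod.binarize_ramp(xb[:, shift:], factor)
                joint = 2 * a[:, None, :] + b[None, :, :]  # (d, d, L)
                idx = 4 * joint[:, :, :-1] + joint[:, :, 1:]
                flat = (
                    idx + 16 * np.arange(d * d).reshape(d, d, 1)
                ).ravel()
                counts += np.bincount(flat, minlength=16 * d * d).reshape(d, d, 4, 4)
        row_sums = counts.sum(axis=3, keepdims=True)
        tpms = np.where(row_sums > 0, counts / np.maximum(row_sums, 1), 0.25)
        phis[fi] = phi_mod.phi_batch(tpms.reshape(-1, 4, 4)).reshape(d, d)
    return phis.mean(axis=0)


def stage_plv(
    study: SyntheticStudy,
    n_random: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float], dict[str, float]]:
    """Actual- and random-pair interbrain PLV, normalized and globalized.

    Returns the per-connection table plus the actual and random global
    normalized PLV per condition.  Phase series are cached per trial so the
    random schemes reuse them.
    """
    cfg = study.config
    fs = cfg.sampling_rate
    # cache: (pair, song, cond, brain) -> list of PhaseSeries per NC epoch
    cache: dict[tuple, list] = {}
    for pair in range(cfg.n_pairs):
        for song in range(cfg.n_songs):
            for cond in CONDITIONS:
                rec = study.recording(pair, song, cond)
                for brain in ("a", "b"):
                    eps = extract_epochs(rec, "NC", "play", brain=brain)
                    cache[(pair, song, cond, brain)] = [
                        plv_mod.instantaneous_phase(e, fs) for e in eps.epochs
                    ]

    def pair_plv(pa: int, pb: int, cond: str) -> np.ndarray | None:
        mats = []
        for song in range(cfg.n_songs):
            xs = cache[(pa, song, cond, "a")]
            ys = cache[(pb, song, cond, "b")]
            for ea, eb in zip(xs, ys):
                mats.append(plv_mod.ispc_trial(ea, eb))
        return np.mean(mats, axis=0) if mats else None

    d = cfg.n_regions_per_brain
    raw_actual: dict[tuple, dict[str, float]] = {}
    for pair in range(cfg.n_pairs):
        for cond in CONDITIONS:
            m = pair_plv(pair, pair, cond)
            if m is None:
                continue
            for ra in range(d):
                for rb in range(d):
                    raw_actual.setdefault((pair, ra, rb), {})[cond] = m[ra, rb]
    norm_actual, glob_actual = plv_mod.normalize_and_globalize(raw_actual)

    schemes = plv_mod.random_pair_schemes(cfg.n_pairs, n_random, seed)
    raw_random: dict[tuple, dict[str, float]] = {}
    for si, mapping in enumerate(schemes.mappings):
        for pair in range(cfg.n_pairs):
            partner = int(mapping[pair])
            for cond in CONDITIONS:
                m = pair_plv(pair, partner, cond)
                if m is None:
                    continue
                for ra in range(d):
                    for rb in range(d):
                        raw_random.setdefault((si, pair, ra, rb), {})[cond] = m[ra, rb]
    norm_random, glob_random = plv_mod.normalize_and_globalize(raw_random)

    rows = [
        {"pair_id": k[0], "rg_a": k[1], "rg_b": k[2], "condition": c,
         "pairing": "actual", "plv": raw_actual[k][c], "normalized": v}
        for k, vals in norm_actual.items()
        for c, v in vals.items()
    ]
    return pd.DataFrame(rows), glob_actual, glob_random


# --------------------------------------------------------------------------
# End-to-end run
# --------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig | dict | str | None = None) -> dict:
    """Run every enabled stage in dependency order and write a report.

    Stage outputs are plain TSV/JSON files under ``config.out_dir``; the
    returned report dict is also written as ``report.json`` with a
    provenance block (config hash, seed).  Re-running with the same config
    and seed reproduces the payload byte for byte.
    """
    if not isinstance(config, PipelineConfig):
        config = validate_config(config)
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(_jsonable_config(config), sort_keys=True)
    report: dict = {
        "provenance": {
            "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
            "seed": config.seed,
        },
        "stages": {},
    }
    study, truth = simulate_study(config.sim)
    report["stages"]["simulate"] = {"n_trials": len(study)}

    if "aep" in config.stages and config.sim.emit_sensors:
        aep_table = stage_aep(study)
        aep_table.to_csv(out / "aep_scores.tsv", sep="\t", index=False)
        by_cond = aep_table.groupby("condition")["aep_score"].mean()
        report["stages"]["aep"] = {c: float(by_cond[c]) for c in by_cond.index}

    if "power" in config.stages:
        power_table, topo = stage_power(study)
        power_table.to_csv(out / "band_power.tsv", sep="\t", index=False)
        zero_sum = float(
            power_table.groupby(["participant", "song", "region"])["normalized_db"]
            .sum()
            .abs()
            .max()
        )
        report["stages"]["power"] = {
            "max_abs_condition_sum": zero_sum,
            "significant_regions": np.flatnonzero(topo.mask).tolist(),
        }

    if "gc" in config.stages:
        gc_table = stage_causality(
            study, window=config.mvar_window, step=config.mvar_step,
            max_order=config.mvar_max_order,
        )
        gc_table.to_csv(out / "causality.tsv", sep="\t", index=False)
        ggc = gc_table[gc_table.measure == "GGC"]
        mean_conn = ggc.groupby(["from", "to"])["value"].mean().unstack().to_numpy()
        np.fill_diagonal(mean_conn, 0.0)
        summary = mvar_mod.to_from_summary(mean_conn)
        report["stages"]["gc"] = {
            "lowest_to_from_region": int(np.argmin(summary.log_ratio)),
            "top_senders": mvar_mod.top_senders(summary.edge_log_ratio)[:5],
        }

    if "phi" in config.stages:
        phi_table, phi_glob = stage_phi(study, factors=config.phi_factors)
        phi_table.to_csv(out / "phi.tsv", sep="\t", index=False)
        report["stages"]["phi"] = {"global_norm_ii": phi_glob}

    if "plv" in config.stages:
        plv_table, glob_actual, glob_random = stage_plv(
            study, n_random=config.n_random_pairs, seed=config.seed
        )
        plv_table.to_csv(out / "plv.tsv", sep="\t", index=False)
        report["stages"]["plv"] = {
            "global_norm_plv_actual": glob_actual,
            "global_norm_plv_random": glob_random,
        }

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def _jsonable_config(config: PipelineConfig) -> dict:
    from hyperflow.synth import _config_jsonable

    out = {k: v for k, v in asdict(config).items() if k != "sim"}
    out["sim"] = _config_jsonable(config.sim)
    for k, v in out.items():
        if isinstance(v, tuple):
            out[k] = list(v)
    return out
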
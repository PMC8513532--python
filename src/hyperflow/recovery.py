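"""Ground-truth recovery experiments on the synthetic generator.

Each function runs one recovery study end to end — generate data with a
known injected effect, push it through the corresponding analysis stage,
and measure whether the effect comes back out — and returns plain numbers.
The acceptance script and the acceptance test suite both drive these.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from hyperflow import aep as aep_mod
from hyperflow import mvar as mvar_mod
from hyperflow import phi as phi_mod
from hyperflow.config import CONDITIONS, SimConfig
from hyperflow.pipeline import stage_phi, stage_plv, stage_power
from hyperflow.preprocess import EpochSet, theta_filter
from hyperflow.stats import friedman_conover, rm_anova_oneway
from hyperflow.synth import (
    EventList,
    erp_template,
    inject_erp,
    simulate_region_series,
    simulate_study,
)


# --------------------------------------------------------------------------
# Directed-causality direction recovery
# --------------------------------------------------------------------------


def gc_direction_recovery(
    n_seeds: int = 100,
    n_samples: int = 2000,
    coupling: float = 0.5,
    seed: int = 0,
) -> dict[str, float]:
    """Fraction of seeds with correct direction ordering per measure.

    Bivariate VAR(1) with unidirectional coupling channel 0 -> channel 1;
    a measure scores a hit when its band-mean (13-50 Hz) causality is larger
    in the true direction.
    """
    a = np.array([[0.6, 0.0], [coupling, 0.6]])
    hits = {m: 0 for m in mvar_mod.MEASURES}
    root = np.random.SeedSequence(seed).spawn(n_seeds)
    for ss in root:
        x = simulate_region_series([a], n_samples, 1.0, ss)
        model = mvar_mod.fit_mvar(x, max_order=5)
        for meas in mvar_mod.MEASURES:
            _, vals = mvar_mod.causality_spectrum(model, meas)
            bm = vals.mean(axis=-1)
            hits[meas] += bm[0, 1] > bm[1, 0]
    return {m: hits[m] / n_seeds for m in mvar_mod.MEASURES}


# --------------------------------------------------------------------------
# AEP attenuation monotonicity
# --------------------------------------------------------------------------


def _participant_scores(
    attenuations: tuple[float, ...],
    rng: np.random.Generator,
    fs: float = 256.0,
    n_channels: int = 4,
    duration: float = 50.0,
    noise_sd: float = 0.5,
) -> list[float]:
    """Play-phase AEP scores of one simulated participant per attenuation.

    Group latencies come from the participant's full-amplitude rest-phase
    response, as in the study protocol.
    """
    template = erp_template(fs)
    n = int(duration * fs)
    onsets = np.arange(2.0, duration - 2.0, 6.0)
    events = EventList(onsets, ["play"] * len(onsets))

    def epoch_set(atten: float) -> EpochSet:
        x = noise_sd * rng.standard_normal((n_channels, n))
        x = inject_erp(x, events, template, atten, fs)
        x = theta_filter(x, fs)
        chunks = [
            x[:, int((o - 0.5) * fs) : int((o - 0.5) * fs) + 384] for o in onsets
        ]
        return EpochSet(
            kind="AEP", window=(-0.5, 1.0), epochs=np.stack(chunks),
            sampling_rate=fs, event_indices=np.arange(len(onsets)),
            dropped_indices=np.array([]), phase="play",
        )

    rest = epoch_set(1.0)
    grand = rest.epochs.mean(axis=(0, 1))
    latencies = aep_mod.estimate_peak_latencies(grand, rest.times)
    return [
        aep_mod.aep_score(epoch_set(a), list(range(n_channels)), latencies).aep_score
        for a in attenuations
    ]


def aep_attenuation_monotonicity(
    n_study_seeds: int = 20,
    n_participants: int = 20,
    attenuations: tuple[float, ...] = (0.3, 0.6, 1.0),
    seed: int = 0,
) -> float:
    """Fraction of study seeds where the mean AEP score is strictly
    increasing in the injected attenuation (Spearman rho = 1 over the
    condition means)."""
    ok = 0
    for ss in np.random.SeedSequence(seed).spawn(n_study_seeds):
        rng = np.random.default_rng(ss)
        scores = np.array(
            [_participant_scores(attenuations, rng) for _ in range(n_participants)]
        )
        means = scores.mean(axis=0)
        ok += bool(np.all(np.diff(means) > 0))
    return ok / n_study_seeds


# --------------------------------------------------------------------------
# Clustering recovery
# --------------------------------------------------------------------------

#: Seven feature archetypes with unit minimum pairwise separation.
SEVEN_ARCHETYPES = np.array(
    [
        [1, 0, 0],
        [0, 1, 0],
        [0, 0, 1],
        [1, 1, 0],
        [0, 1, 1],
        [1, 0, 1],
        [1, 1, 1],
    ],
    dtype=float,
)


def clustering_recovery(
    n_vertices: int = 700,
    noise_fraction: float = 0.1,
    seed: int = 0,
) -> float:
    """Adjusted Rand index of complete-linkage clustering on 7 planted
    archetypes with Gaussian noise of SD = noise_fraction x separation."""
    from sklearn.metrics import adjusted_rand_score

    from hyperflow.clustering import cluster_vertices

    rng = np.random.default_rng(seed)
    per = n_vertices // len(SEVEN_ARCHETYPES)
    feats = np.vstack(
        [a + rng.normal(0.0, noise_fraction, (per, 3)) for a in SEVEN_ARCHETYPES]
    )
    true = np.repeat(np.arange(7), per)
    labeling = cluster_vertices(feats, 7)
    return float(adjusted_rand_score(true, labeling.labels))


# --------------------------------------------------------------------------
# Interbrain coupling recovery (PLV + II)
# --------------------------------------------------------------------------


def interbrain_recovery(
    n_seeds: int = 20,
    n_pairs: int = 3,
    seed: int = 0,
) -> dict[str, float]:
    """Fractions of study seeds recovering the TeamFlow-only interbrain
    coupling: global Norm II maximal in TeamFlow, actual-pair global Norm
    PLV maximal in TeamFlow, and the random-pair TeamFlow value suppressed
    below half the actual one."""
    ok_ii = ok_plv = ok_rand = 0
    for i in range(n_seeds):
        cfg = SimConfig(
            n_pairs=n_pairs, n_songs=1, rest_duration=5.0, play_duration=26.0,
            seed=seed * 1000 + i,
        )
        study, _ = simulate_study(cfg)
        _, glob_ii = stage_phi(study)
        _, glob_plv, glob_rand = stage_plv(study, n_random=3, seed=seed + i)
        ok_ii += max(glob_ii, key=glob_ii.get) == "TeamFlow"
        ok_plv += max(glob_plv, key=glob_plv.get) == "TeamFlow"
        ok_rand += glob_rand["TeamFlow"] < 0.5 * glob_plv["TeamFlow"]
    return {
        "norm_ii_teamflow_max": ok_ii / n_seeds,
        "norm_plv_teamflow_max": ok_plv / n_seeds,
        "random_pairs_suppressed": ok_rand / n_seeds,
    }


# --------------------------------------------------------------------------
# Normalization zero sums on a default study
# --------------------------------------------------------------------------


def normalization_zero_sums(seed: int = 0) -> dict[str, float]:
    """Maximum |sum over the three conditions| for normalized band power,
    Norm II and Norm PLV on a shortened default-effects study."""
    cfg = SimConfig(
        n_pairs=2, n_songs=1, rest_duration=5.0, play_duration=16.0, seed=seed
    )
    study, _ = simulate_study(cfg)
    power_table, _ = stage_power(study)
    power_sum = (
        power_table.groupby(["participant", "song", "region"])["normalized_db"]
        .sum()
        .abs()
        .max()
    )
    phi_table, _ = stage_phi(study, factors=(5, 10))
    ii_sum = phi_table.groupby(["pair_id", "rg_a", "rg_b"])["normalized"].sum().abs().max()
    plv_table, _, _ = stage_plv(study, n_random=1, seed=seed)
    plv_sum = (
        plv_table.groupby(["pair_id", "rg_a", "rg_b"])["normalized"].sum().abs().max()
    )
    return {
        "band_power": float(power_sum),
        "norm_ii": float(ii_sum),
        "norm_plv": float(plv_sum),
    }


# --------------------------------------------------------------------------
# phi coarse-grid enumeration
# --------------------------------------------------------------------------


def tpm_grid_rows(step: float = 0.25) -> np.ndarray:
    """All probability 4-vectors on the grid (increments of ``step``)."""
    m = int(round(1.0 / step))
    rows = [
        np.array(c, dtype=float) / m
        for c in product(range(m + 1), repeat=4)
        if sum(c) == m
    ]
    return np.stack(rows)


def phi_grid_batches(step: float = 0.25, chunk: int = 250_000):
    """Yield ``(row_indices, phi_values)`` over every TPM on the coarse grid.

    The grid enumerates all 4x4 row-stochastic matrices whose rows lie on
    ``tpm_grid_rows(step)`` (35^4 = 1 500 625 TPMs at step 0.25).
    """
    rows = tpm_grid_rows(step)
    n_rows = len(rows)
    idx = np.indices((n_rows,) * 4).reshape(4, -1).T
    for start in range(0, len(idx), chunk):
        sl = idx[start : start + chunk]
        tpms = rows[sl]
        yield sl, phi_mod.phi_batch(tpms)


def product_tpm_max_phi(step: float = 0.25) -> float:
    """Largest phi over every node-independent product TPM on the grid
    (zero up to floating-point noise)."""
    m = int(round(1.0 / step))
    node_rows = [
        np.array([v / m, 1.0 - v / m]) for v in range(m + 1)
    ]
    nodes = [
        np.stack(c) for c in product(node_rows, repeat=2)
    ]  # all 2x2 row-stochastic node TPMs on the grid
    tpms = []
    for f in nodes:
        for g in nodes:
            tpms.append(np.einsum("ax,by->abxy", f, g).reshape(4, 4))
    return float(phi_mod.phi_batch(np.stack(tpms)).max())


# --------------------------------------------------------------------------
# Statistical calibration
# --------------------------------------------------------------------------


def stat_calibration(
    n_sims: int = 1000,
    n_subjects: int = 15,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """False-positive rates of Friedman and one-way repeated-measures ANOVA
    on pure-null normal data."""
    rng = np.random.default_rng(seed)
    fp_friedman = fp_anova = 0
    for _ in range(n_sims):
        x = rng.standard_normal((n_subjects, 3))
        fp_friedman += friedman_conover(x).p < alpha
        fp_anova += rm_anova_oneway(x).p < alpha
    return {
        "friedman_fpr": fp_friedman / n_sims,
        "rm_anova_fpr": fp_anova / n_sims,
    }
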
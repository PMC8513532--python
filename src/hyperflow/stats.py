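"""Statistical battery and psychometric index construction.

Implements (rather than delegates) the tests the analysis relies on:

* Friedman's rank test with Conover's post hoc pairwise comparisons;
* one- to three-way repeated-measures ANOVA with partial eta squared and
  Bonferroni post hoc tests;
* Spearman correlation with a seeded bootstrap percentile 95% CI;
* comparison of non-overlapping dependent correlations by joint bootstrap
  over participants.

Psychometric indices from the 7-point ratings: flow index = mean(Q1..Q6),
team index = mean(Q7..Q9), team-flow index = mean of the two (the Q1..Q9
mean is available as an alternative weighting).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sp_stats


@dataclass
class StatResult:
    test: str
    statistic: float
    df: tuple
    p: float
    effect_size: float | None = None
    ci: tuple[float, float] | None = None
    posthoc: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# Psychometric indices
# --------------------------------------------------------------------------


def compute_indices(
    ratings: pd.DataFrame, team_flow_from_q1_q9: bool = False
) -> pd.DataFrame:
    """Flow/team/team-flow indices per trial from Q1..Q9 ratings.

    ``ratings`` needs columns Q1..Q9 on the 1-7 scale; rows with missing or
    out-of-range answers are excluded (logged in ``attrs['excluded']``).
    The team-flow index defaults to the mean of the flow and team indices;
    ``team_flow_from_q1_q9`` switches to the plain Q1..Q9 mean, which
    weights the flow questions 2:1.
    """
    qcols = [f"Q{i}" for i in range(1, 10)]
    missing = [c for c in qcols if c not in ratings.columns]
    if missing:
        raise ValueError(f"ratings table missing columns {missing}")
    vals = ratings[qcols]
    ok = vals.notna().all(axis=1) & vals.ge(1).all(axis=1) & vals.le(7).all(axis=1)
    kept = ratings[ok].copy()
    flow = kept[[f"Q{i}" for i in range(1, 7)]].mean(axis=1)
    team = kept[[f"Q{i}" for i in range(7, 10)]].mean(axis=1)
    kept["flow_index"] = flow
    kept["team_index"] = team
    kept["team_flow_index"] = (
        kept[qcols].mean(axis=1) if team_flow_from_q1_q9 else (flow + team) / 2.0
    )
    kept.attrs["excluded"] = int((~ok).sum())
    return kept


# --------------------------------------------------------------------------
# Friedman + Conover
# --------------------------------------------------------------------------


def friedman_conover(
    values: np.ndarray, correction: str = "bonferroni", alpha: float = 0.05
) -> StatResult:
    """Friedman chi-square on within-subject ranks, Conover post hoc.

    ``values`` is (n_subjects, k_conditions), complete blocks.  The chi-
    square uses the tie-corrected statistic; Conover's pairwise t tests
    compare rank sums with the pooled rank variance on (n-1)(k-1) df.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be (subjects, conditions)")
    if np.any(~np.isfinite(values)):
        raise ValueError("missing cells: Friedman needs complete blocks")
    n, k = values.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    ranks = sp_stats.rankdata(values, axis=1)
    rj = ranks.sum(axis=0)
    a1 = float((ranks**2).sum())
    c1 = n * k * (k + 1) ** 2 / 4.0
    denom = a1 - c1
    if denom <= 0:  # all rows fully tied
        chi2 = 0.0
        p = 1.0
    else:
        chi2 = (k - 1) * float(((rj - n * (k + 1) / 2.0) ** 2).sum()) / denom
        p = float(sp_stats.chi2.sf(chi2, k - 1))

    rows = []
    df_c = (n - 1) * (k - 1)
    scale = 2.0 * n * (a1 - float((rj**2).sum()) / n) / df_c if df_c else 0.0
    n_pairs = k * (k - 1) // 2
    for i, j in combinations(range(k), 2):
        if scale <= 0:
            # zero residual rank variance: every subject ranked the
            # conditions identically, so unequal rank sums separate perfectly
            t = np.inf if rj[i] != rj[j] else 0.0
            praw = 0.0 if rj[i] != rj[j] else 1.0
        else:
            t = (rj[i] - rj[j]) / np.sqrt(scale)
            praw = 2.0 * float(sp_stats.t.sf(abs(t), df_c))
        padj = min(1.0, praw * n_pairs) if correction == "bonferroni" else praw
        # post hoc never beats an omnibus that saw no effect at all
        if p >= 1.0:
            padj = 1.0
        rows.append({"a": i, "b": j, "t": t, "p_raw": praw, "p_adj": padj,
                     "significant": padj < alpha})
    return StatResult(
        test="friedman-conover",
        statistic=float(chi2),
        df=(k - 1,),
        p=p,
        posthoc=pd.DataFrame(rows),
        extra={"rank_sums": rj.tolist(), "n": n},
    )


# --------------------------------------------------------------------------
# Repeated-measures ANOVA (1-3 within-subject factors)
# --------------------------------------------------------------------------


def rm_anova(
    values: np.ndarray,
    factor_names: list[str] | None = None,
    posthoc_factor: str | None = None,
    alpha: float = 0.05,
) -> dict[str, StatResult]:
    """Fully within-subject ANOVA by classical sum-of-squares decomposition.

    ``values`` is (n_subjects, l1[, l2[, l3]]), balanced and complete.  Each
    effect (factor or interaction) is tested against its interaction with
    subject: F = MS_effect / MS_(effect x subject), the standard univariate
    repeated-measures analysis with no sphericity correction.  Effect sizes
    are partial eta squared.  Bonferroni-corrected pairwise post hoc tests
    (paired t) are attached for ``posthoc_factor``.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim < 2 or values.ndim > 4:
        raise ValueError("values must have 1-3 factor dimensions after subjects")
    if np.any(~np.isfinite(values)):
        raise ValueError("unbalanced/incomplete design not supported")
    n_factors = values.ndim - 1
    if factor_names is None:
        factor_names = [f"F{i + 1}" for i in range(n_factors)]
    if len(factor_names) != n_factors:
        raise ValueError("factor_names length mismatch")

    axes_of = {name: i + 1 for i, name in enumerate(factor_names)}
    all_axes = tuple(range(values.ndim))
    grand = values.mean()

    def marginal_mean(keep_axes: tuple[int, ...]) -> np.ndarray:
        drop = tuple(a for a in all_axes if a not in keep_axes)
        m = values.mean(axis=drop, keepdims=True)
        return m

    # inclusion-exclusion effect terms for every subset of {subject, factors}
    from itertools import chain

    def subsets(items):
        return chain.from_iterable(
            combinations(items, r) for r in range(len(items) + 1)
        )

    effect_term: dict[tuple[int, ...], np.ndarray] = {}
    for keep in subsets(all_axes):
        keep = tuple(sorted(keep))
        term = marginal_mean(keep) - grand
        for sub in subsets(keep):
            sub = tuple(sorted(sub))
            if sub != keep and sub in effect_term:
                term = term - effect_term[sub]
        effect_term[keep] = term

    sizes = values.shape

    def ss_of(keep: tuple[int, ...]) -> float:
        # SS of the effect over the full grid (each cell mean replicated
        # across the collapsed axes)
        return float((np.broadcast_to(effect_term[keep], sizes) ** 2).sum())

    results: dict[str, StatResult] = {}
    factor_axes = [axes_of[f] for f in factor_names]
    for r in range(1, n_factors + 1):
        for combo in combinations(factor_names, r):
            keep = tuple(sorted(axes_of[f] for f in combo))
            err_keep = tuple(sorted((0,) + keep))
            ss_eff = ss_of(keep)
            ss_err = ss_of(err_keep)
            df_eff = int(np.prod([sizes[a] - 1 for a in keep]))
            df_err = df_eff * (sizes[0] - 1)
            ms_eff = ss_eff / df_eff
            ms_err = ss_err / df_err
            f_val = ms_eff / ms_err if ms_err > 0 else (np.inf if ms_eff > 0 else 0.0)
            p = float(sp_stats.f.sf(f_val, df_eff, df_err)) if np.isfinite(f_val) else 0.0
            eta_p = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
            name = " x ".join(combo)
            results[name] = StatResult(
                test="rm-anova",
                statistic=float(f_val),
                df=(df_eff, df_err),
                p=p if ms_err > 0 else (0.0 if ms_eff > 0 else 1.0),
                effect_size=float(eta_p),
                extra={"ss_effect": ss_eff, "ss_error": ss_err},
            )

    if posthoc_factor is not None:
        ax = axes_of[posthoc_factor]
        other = tuple(a for a in all_axes if a not in (0, ax))
        cell = values.mean(axis=other) if other else values  # (subject, level)
        k = cell.shape[1]
        n_pairs = k * (k - 1) // 2
        rows = []
        for i, j in combinations(range(k), 2):
            t, praw = sp_stats.ttest_rel(cell[:, i], cell[:, j])
            padj = min(1.0, float(praw) * n_pairs)
            rows.append({"a": i, "b": j, "t": float(t), "p_raw": float(praw),
                         "p_adj": padj, "significant": padj < alpha})
        results[posthoc_factor].posthoc = pd.DataFrame(rows)
    return results


def rm_anova_oneway(values: np.ndarray, **kw) -> StatResult:
    """One-way convenience wrapper: (subjects, conditions) -> condition effect."""
    return rm_anova(values, factor_names=["condition"], **kw)["condition"]


# --------------------------------------------------------------------------
# Correlations
# --------------------------------------------------------------------------


def spearman_ci(
    x: np.ndarray, y: np.ndarray, n_boot: int = 2000, seed: int = 0
) -> StatResult:
    """Spearman rank correlation with bootstrap percentile 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: ranks undefined")
    rho, p = sp_stats.spearmanr(x, y)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        xs, ys = x[idx], y[idx]
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            boots[b] = np.nan
            continue
        boots[b] = sp_stats.spearmanr(xs, ys)[0]
    boots = boots[np.isfinite(boots)]
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return StatResult(
        test="spearman", statistic=float(rho), df=(n - 2,), p=float(p), ci=ci
    )


def compare_dependent_correlations(
    x1: np.ndarray,
    y1: np.ndarray,
    x2: np.ndarray,
    y2: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
) -> StatResult:
    """Difference of two non-overlapping dependent Spearman correlations.

    The four variables are observed on the same participants, so bootstrap
    resampling draws participants jointly; the statistic is
    ``rho(x1, y1) - rho(x2, y2)`` with a percentile CI and a two-sided
    bootstrap sign p-value.
    """
    arrs = [np.asarray(a, dtype=float) for a in (x1, y1, x2, y2)]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("all variables must share the participant dimension")
    if n < 4:
        raise ValueError("need n >= 4 participants")
    x1, y1, x2, y2 = arrs
    d_obs = sp_stats.spearmanr(x1, y1)[0] - sp_stats.spearmanr(x2, y2)[0]
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            diffs[b] = (
                sp_stats.spearmanr(x1[idx], y1[idx])[0]
                - sp_stats.spearmanr(x2[idx], y2[idx])[0]
            )
        except Exception:
            diffs[b] = np.nan
    diffs = diffs[np.isfinite(diffs)]
    ci = (float(np.percentile(diffs, 2.5)), float(np.percentile(diffs, 97.5)))
    frac_neg = np.mean(diffs < 0)
    frac_pos = np.mean(diffs > 0)
    p = float(min(1.0, 2.0 * min(frac_neg + 0.5 * np.mean(diffs == 0),
                                 frac_pos + 0.5 * np.mean(diffs == 0))))
    return StatResult(
        test="dependent-correlation-difference",
        statistic=float(d_obs),
        df=(n,),
        p=p,
        ci=ci,
    )
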
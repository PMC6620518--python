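"""Reproducibility statistics: effect models, variance components,
pooled SDs, block-bootstrap confidence intervals, and inter-laboratory
comparison.

Two linear models underpin this module.

*Effect model* (technical-factor testing).  Replicate scores under a set
of experimental conditions decompose as

    S_ijk = mu_i + b_j + eps_ijk

with mu_i a per-sample (random) effect, b_j the fixed experimental effect
(input mass, gDNA level, laboratory, ...) and eps_ijk residual noise.  On
the balanced designs used throughout, the ANOVA F-test of b_j from the
randomized-complete-block decomposition coincides with the mixed-model
test, so the fixed effect is tested by F = MS(condition) / MS(residual)
after removing sample means.

*Reproducibility model* (variance components).  Scores from a balanced
sample-by-run crossed design with technical replicates decompose as

    S_ijk = mu_i + r_j + (mu_i : r_j) + eps_ijk

with mu_i fixed and run, interaction and residual effects random.
Components are estimated by equating observed mean squares to their
expectations (ANOVA method of moments); negative solutions are truncated
at zero.  Derived summaries:

    intra-run SD = sqrt(sigma2_residual)            -- technical replication
    inter-run SD = sqrt(sigma2_run + sigma2_interaction + sigma2_residual)
                                                    -- total experimental
                                                       variability excluding
                                                       sample effects

Confidence intervals for SD statistics use a block bootstrap that
resamples whole samples (replicates within a sample are dependent) with
percentile 2.5/97.5 limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .agreement import paired_correlation_concordance
from .containers import ScoreTable


# ---------------------------------------------------------------------------
# Effect model (randomized-block ANOVA)
# ---------------------------------------------------------------------------

@dataclass
class EffectFit:
    """Fixed-effect test and variance summaries for the effect model."""

    condition_labels: list
    condition_effects: np.ndarray  # condition means minus grand mean
    sigma2_sample: float  # sample-effect variance from the block mean square
    sigma2_residual: float
    f_statistic: float | None
    p_value: float | None
    df_condition: int
    df_residual: int


def fit_effect_model(t: ScoreTable, condition_column: str = "condition") -> EffectFit:
    """Test an experimental effect on classifier scores.

    Requires a balanced block design: every sample observed under every
    condition with the same replicate count.  Unbalanced data are rejected
    with guidance rather than silently refit.
    """
    df = t.df
    conditions = sorted(df[condition_column].unique())
    samples = sorted(df["sample_id"].unique())
    if len(conditions) < 2:
        raise ValueError("effect model needs at least 2 conditions")
    if len(samples) < 2:
        raise ValueError("effect model needs at least 2 samples")
    cell_counts = df.groupby(["sample_id", condition_column]).size()
    if len(cell_counts) != len(samples) * len(conditions) or cell_counts.nunique() != 1:
        raise ValueError(
            "unbalanced design: every sample must appear under every condition "
            "with the same replicate count (aggregate replicates first if needed)"
        )

    y = df["score"].to_numpy(dtype=float)
    grand = y.mean()
    cond_means = df.groupby(condition_column)["score"].mean().reindex(conditions).to_numpy()
    samp_means = df.groupby("sample_id")["score"].mean().reindex(samples).to_numpy()
    k = int(cell_counts.iloc[0])
    n_i, n_c = len(samples), len(conditions)

    ss_total = float(((y - grand) ** 2).sum())
    ss_cond = n_i * k * float(((cond_means - grand) ** 2).sum())
    ss_samp = n_c * k * float(((samp_means - grand) ** 2).sum())
    ss_resid = max(ss_total - ss_cond - ss_samp, 0.0)
    df_cond = n_c - 1
    df_samp = n_i - 1
    df_resid = len(y) - 1 - df_cond - df_samp

    ms_resid = ss_resid / df_resid
    ms_samp = ss_samp / df_samp
    sigma2_sample = max((ms_samp - ms_resid) / (n_c * k), 0.0)
    if ms_resid > 0:
        f = (ss_cond / df_cond) / ms_resid
        p = float(stats.f.sf(f, df_cond, df_resid))
    else:
        f = p = None
    return EffectFit(
        condition_labels=conditions,
        condition_effects=cond_means - grand,
        sigma2_sample=sigma2_sample,
        sigma2_residual=ms_resid,
        f_statistic=f,
        p_value=p,
        df_condition=df_cond,
        df_residual=df_resid,
    )


# ---------------------------------------------------------------------------
# Variance components (method of moments on the balanced crossed design)
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """Estimated variances for run, sample-by-run interaction and residual.

    ``None`` marks a component the design cannot estimate (e.g. no
    replicates for the residual); truncated-at-zero estimates keep their
    raw (possibly negative) values in ``raw`` for diagnostics.
    """

    sigma2_run: float | None
    sigma2_interaction: float | None
    sigma2_residual: float | None
    intra_run_sd: float | None
    inter_run_sd: float | None
    design: tuple[int, int, int]  # (samples, runs, replicates)
    raw: dict = field(default_factory=dict)
    ci: dict = field(default_factory=dict)  # statistic -> (lo, hi)


def _score_array(t: ScoreTable) -> tuple[np.ndarray, list[str], list[str]]:
    """Pivot a balanced crossed score table to an (I, J, K) array."""
    df = t.df
    samples = sorted(df["sample_id"].unique())
    runs = sorted(df["run_id"].unique())
    counts = df.groupby(["sample_id", "run_id"]).size()
    if len(counts) != len(samples) * len(runs) or counts.nunique() != 1:
        raise ValueError(
            "unbalanced design: every sample x run cell must hold the same "
            "number of replicates"
        )
    k = int(counts.iloc[0])
    ordered = df.sort_values(["sample_id", "run_id", "replicate_id"])
    arr = ordered["score"].to_numpy(dtype=float).reshape(len(samples), len(runs), k)
    return arr, samples, runs


def _components_from_array(arr: np.ndarray) -> dict:
    """Method-of-moments components from an (..., I, J, K) score array.

    Vectorized over leading batch dimensions; returns raw (untruncated)
    component estimates, or NaN where the design leaves a component
    inestimable.
    """
    i_n, j_n, k_n = arr.shape[-3:]
    grand = arr.mean(axis=(-3, -2, -1), keepdims=True)
    m_i = arr.mean(axis=(-2, -1), keepdims=True)
    m_j = arr.mean(axis=(-3, -1), keepdims=True)
    m_ij = arr.mean(axis=-1, keepdims=True)

    nan = np.full(arr.shape[:-3], np.nan)
    if k_n > 1:
        ms_err = ((arr - m_ij) ** 2).sum(axis=(-3, -2, -1)) / (i_n * j_n * (k_n - 1))
    else:
        ms_err = nan.copy()
    if j_n > 1:
        ms_run = (i_n * k_n) * ((m_j - grand) ** 2).sum(axis=(-3, -2, -1)) / (j_n - 1)
        if i_n > 1:
            ms_int = k_n * ((m_ij - m_i - m_j + grand) ** 2).sum(axis=(-3, -2, -1)) / (
                (i_n - 1) * (j_n - 1)
            )
        else:
            ms_int = nan.copy()
    else:
        ms_run = nan.copy()
        ms_int = nan.copy()

    sigma2_residual = ms_err
    sigma2_interaction = (ms_int - ms_err) / k_n
    sigma2_run = (ms_run - ms_int) / (i_n * k_n)
    return {
        "sigma2_run": sigma2_run,
        "sigma2_interaction": sigma2_interaction,
        "sigma2_residual": sigma2_residual,
    }


def _summaries_from_raw(raw: dict) -> tuple:
    def trunc(v):
        if v is None or (np.isscalar(v) and np.isnan(v)):
            return None
        return max(float(v), 0.0)

    s2_run = trunc(raw["sigma2_run"])
    s2_int = trunc(raw["sigma2_interaction"])
    s2_res = trunc(raw["sigma2_residual"])
    intra = np.sqrt(s2_res) if s2_res is not None else None
    if None not in (s2_run, s2_int, s2_res):
        inter = float(np.sqrt(s2_run + s2_int + s2_res))
    else:
        inter = None
    return s2_run, s2_int, s2_res, intra, inter


def estimate_variance_components(t: ScoreTable) -> VarianceComponents:
    """Estimate run / interaction / residual variance components.

    The design must be balanced and crossed.  Components the design cannot
    identify (a single run, or a single replicate per cell) are reported
    as ``None`` rather than zero.
    """
    arr, samples, runs = _score_array(t)
    raw = {k: float(v) for k, v in _components_from_array(arr).items()}
    s2_run, s2_int, s2_res, intra, inter = _summaries_from_raw(raw)
    return VarianceComponents(
        sigma2_run=s2_run,
        sigma2_interaction=s2_int,
        sigma2_residual=s2_res,
        intra_run_sd=intra,
        inter_run_sd=inter,
        design=(len(samples), len(runs), arr.shape[2]),
        raw=raw,
    )


def pooled_sd(groups: list[np.ndarray]) -> float | None:
    """Square root of the df-weighted mean of within-group variances.

    Groups with fewer than two members contribute nothing; if no group has
    two members the pooled SD is undefined (``None``).
    """
    num = 0.0
    den = 0
    for g in groups:
        g = np.asarray(g, dtype=float)
        if g.size >= 2:
            num += g.var(ddof=1) * (g.size - 1)
            den += g.size - 1
    if den == 0:
        return None
    return float(np.sqrt(num / den))


def intra_run_sd(t: ScoreTable) -> float | None:
    """Pooled SD of technical replicates within each sample-by-run cell."""
    groups = [g.to_numpy() for _, g in t.df.groupby(["sample_id", "run_id"])["score"]]
    return pooled_sd(groups)


def inter_run_sd(t: ScoreTable) -> float | None:
    """Total experimental SD excluding sample effects (run + interaction +
    residual), from the variance-component decomposition."""
    return estimate_variance_components(t).inter_run_sd


def interclass_sd(t: ScoreTable) -> float | None:
    """Biological (inter-class) variation: SD of per-sample mean scores,
    pooled over both classes."""
    means = t.df.groupby("sample_id")["score"].mean().to_numpy()
    if means.size < 2:
        return None
    return float(np.std(means, ddof=1))


def interlab_pooled_sd(t: ScoreTable) -> float | None:
    """Pooled SD of per-sample lab pairs (SD of the two lab scores per
    sample, pooled across samples)."""
    groups = [g.to_numpy() for _, g in t.df.groupby("sample_id")["score"]]
    return pooled_sd(groups)


_NAMED_STATISTICS: dict[str, Callable[[ScoreTable], float | None]] = {
    "intra_run_sd": intra_run_sd,
    "inter_run_sd": inter_run_sd,
    "interclass_sd": interclass_sd,
    "interlab_pooled_sd": interlab_pooled_sd,
}


def _bootstrap_values_named(t: ScoreTable, statistic: str, idx: np.ndarray) -> np.ndarray:
    """Vectorized bootstrap replicates for the named SD statistics.

    ``idx`` is a (B, I) array of resampled sample indices.  Pooled-SD
    statistics reduce to per-sample (sum-of-squares, df) pairs, so the
    whole bootstrap is a couple of fancy-indexing reductions.
    """
    df = t.df
    samples = sorted(df["sample_id"].unique())
    if statistic in ("intra_run_sd", "interlab_pooled_sd"):
        keys = ["sample_id", "run_id"] if statistic == "intra_run_sd" else ["sample_id"]
        cell = df.groupby(keys)["score"].agg(["var", "count"]).reset_index()
        cell["ss"] = cell["var"].fillna(0.0) * (cell["count"] - 1)
        cell["df"] = cell["count"] - 1
        per_sample = cell.groupby("sample_id")[["ss", "df"]].sum().reindex(samples)
        ss = per_sample["ss"].to_numpy()
        dof = per_sample["df"].to_numpy()
        tot_df = dof[idx].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.sqrt(ss[idx].sum(axis=1) / tot_df)
        out[tot_df == 0] = np.nan
        return out
    if statistic == "interclass_sd":
        means = df.groupby("sample_id")["score"].mean().reindex(samples).to_numpy()
        return np.std(means[idx], axis=1, ddof=1)
    if statistic == "inter_run_sd":
        arr, _, _ = _score_array(t)
        raw = _components_from_array(arr[idx])  # batch over B
        total = (
            np.maximum(raw["sigma2_run"], 0.0)
            + np.maximum(raw["sigma2_interaction"], 0.0)
            + np.maximum(raw["sigma2_residual"], 0.0)
        )
        return np.sqrt(total)
    raise KeyError(statistic)


def bootstrap_sd_ci(
    t: ScoreTable,
    statistic: str | Callable[[ScoreTable], float | None],
    B: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Percentile block-bootstrap CI for an SD statistic.

    Whole samples are resampled with replacement (their replicate
    structure travels with them) because replicates within a sample are
    dependent.  ``statistic`` is one of the named statistics
    (``intra_run_sd``, ``inter_run_sd``, ``interclass_sd``,
    ``interlab_pooled_sd``) — computed on a fast vectorized path — or any
    callable on a :class:`ScoreTable`.  Resamples on which the statistic
    is undefined are redrawn and counted.
    """
    if B < 200:
        raise ValueError("B must be >= 200")
    df = t.df
    samples = sorted(df["sample_id"].unique())
    if len(samples) < 3:
        raise ValueError("bootstrap needs at least 3 distinct samples")

    rng = np.random.default_rng(seed)
    redraws = 0
    if isinstance(statistic, str):
        if statistic not in _NAMED_STATISTICS:
            raise KeyError(f"unknown statistic {statistic!r}")
        idx = rng.integers(0, len(samples), size=(B, len(samples)))
        values = _bootstrap_values_named(t, statistic, idx)
        bad = ~np.isfinite(values)
        while bad.any():
            redraws += int(bad.sum())
            if redraws > 100 * B:
                raise RuntimeError("statistic undefined on too many resamples")
            idx = rng.integers(0, len(samples), size=(int(bad.sum()), len(samples)))
            values[bad] = _bootstrap_values_named(t, statistic, idx)
            bad = ~np.isfinite(values)
    else:
        groups = {s: df[df["sample_id"] == s] for s in samples}
        values = np.empty(B)
        for b in range(B):
            for _attempt in range(100):
                draw = rng.integers(0, len(samples), size=len(samples))
                parts = []
                for slot, i in enumerate(draw):
                    g = groups[samples[i]].copy()
                    g["sample_id"] = f"bs{slot:04d}"
                    parts.append(g)
                v = statistic(ScoreTable(pd.concat(parts, ignore_index=True)))
                if v is not None and np.isfinite(v):
                    values[b] = v
                    break
                redraws += 1
            else:
                raise RuntimeError("statistic undefined on 100 consecutive resamples")
    lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return {"ci": (float(lo), float(hi)), "replicates": B, "redraws": redraws}


# ---------------------------------------------------------------------------
# Inter-laboratory comparison
# ---------------------------------------------------------------------------

def interlab_analysis(
    t: ScoreTable,
    threshold: float = 0.0,
    bootstrap_B: int | None = 2000,
    seed: int = 0,
) -> dict:
    """Two-laboratory reproducibility: concordance, r², pooled SD, lab effect.

    Every sample must be scored exactly once in each of exactly two labs;
    unpaired samples are excluded with a reported count.  The pooled SD is
    the per-sample lab-pair SD pooled across samples, its CI from the
    sample-level block bootstrap, and the lab effect is tested with the
    effect model using laboratory as the condition.
    """
    df = t.df
    labs = sorted(df["lab_id"].unique())
    if len(labs) != 2:
        raise ValueError(f"interlab analysis requires exactly 2 labs, got {len(labs)}")
    wide = df.pivot_table(index="sample_id", columns="lab_id", values="score", aggfunc="count")
    paired = wide.index[(wide == 1).all(axis=1).fillna(False)]
    n_excluded = df["sample_id"].nunique() - len(paired)
    if len(paired) < 3:
        raise ValueError("need at least 3 paired samples")
    sub = df[df["sample_id"].isin(paired)]
    pivot = sub.pivot(index="sample_id", columns="lab_id", values="score")[labs]
    a = pivot[labs[0]].to_numpy()
    b = pivot[labs[1]].to_numpy()

    agree = paired_correlation_concordance(a, b, a > threshold, b > threshold)
    sub_table = ScoreTable(sub)
    psd = interlab_pooled_sd(sub_table)
    ci = None
    if bootstrap_B is not None:
        ci = bootstrap_sd_ci(sub_table, "interlab_pooled_sd", B=bootstrap_B, seed=seed)["ci"]
    effect = fit_effect_model(sub_table, condition_column="lab_id")
    return {
        "n_pairs": len(paired),
        "n_excluded": n_excluded,
        "concordance": agree["concordance"],
        "r2": agree["r2"],
        "pooled_sd": psd,
        "pooled_sd_ci": ci,
        "lab_effect_p": effect.p_value,
    }
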
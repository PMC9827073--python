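"""Moderated differential testing of phosphopeptides against baseline.

Each post-treatment time point is contrasted with t = 0 on log2
abundances using an empirical-Bayes moderated t statistic: per-feature
sample variances s^2 (d residual df each) are shrunk toward a pooled
prior s0^2 with d0 prior df,

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d),
    t = (mean_t - mean_0) / (s_tilde * sqrt(1/n_t + 1/n_0)),

with d + d0 degrees of freedom. The prior (d0, s0^2) is estimated by
the method of moments on the log sample variances (matching a scaled
F prior): with z = log s^2 and e = z - digamma(d/2) + log(d/2),

    Var(e) ~= trigamma(d/2) + trigamma(d0/2),
    E(e)    = log s0^2 - digamma(d0/2) + log(d0/2),

so d0 follows from inverting the trigamma function and s0^2 from the
mean. With d0 -> 0 the statistic reduces to the ordinary two-sample t;
with d0 -> inf every feature uses s0^2. P values are corrected per
contrast with Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import AbundanceMatrix


def _trigamma(x):
    return special.polygamma(1, x)


def _trigamma_inverse(y: float, tol: float = 1e-10,
                      max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


@dataclass
class VariancePrior:
    """Empirical-Bayes variance prior: d0 prior df, s0^2 prior value."""

    d0: float
    s0_sq: float


def fit_variance_prior(sample_vars: np.ndarray, d: float) -> VariancePrior:
    """Method-of-moments fit of (d0, s0^2) from per-feature variances."""
    s2 = np.asarray(sample_vars, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if len(s2) < 2:
        return VariancePrior(d0=np.inf, s0_sq=float(np.mean(s2)) if len(s2)
                             else 1.0)
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_var = np.var(e, ddof=1) - _trigamma(d / 2.0)
    if e_var <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(np.mean(e)))
    else:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0)
                             - np.log(d0 / 2.0)))
    return VariancePrior(d0=float(d0), s0_sq=s0_sq)


def moderated_t_test(m: AbundanceMatrix, time_min: float,
                     baseline: float = 0,
                     prior: VariancePrior | None = None,
                     d0_override: float | None = None) -> pd.DataFrame:
    """Moderated t test of one time point against baseline.

    Operates on log2-transformed abundances using all replicates at the
    two time points (across datasets). Returns a DataFrame with columns
    feature_id, time_min, log_fc, t_stat, p_value, fdr. ``d0_override``
    forces the prior df (0 recovers the ordinary t test).
    """
    g1 = m.samples_at(time_min=time_min)
    g0 = m.samples_at(time_min=baseline)
    if len(g1) < 2 or len(g0) < 2:
        raise ValueError(
            f"need >=2 replicates per group, got {len(g1)} at t={time_min} "
            f"and {len(g0)} at t={baseline}")
    x1 = np.log2(m.values[g1].to_numpy())
    x0 = np.log2(m.values[g0].to_numpy())
    n1, n0 = x1.shape[1], x0.shape[1]
    d = n1 + n0 - 2
    mean1, mean0 = x1.mean(axis=1), x0.mean(axis=1)
    ss = x1.var(axis=1, ddof=1) * (n1 - 1) + x0.var(axis=1, ddof=1) * (n0 - 1)
    s2 = ss / d

    if prior is None:
        prior = fit_variance_prior(s2, d)
    d0 = prior.d0 if d0_override is None else d0_override
    if np.isinf(d0):
        s2_mod = np.full_like(s2, prior.s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_mod = s2
        df_total = d
    else:
        s2_mod = (d0 * prior.s0_sq + d * s2) / (d0 + d)
        df_total = d + d0
    log_fc = mean1 - mean0
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log_fc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.clip(p, 0.0, 1.0)
    return pd.DataFrame({
        "feature_id": m.values.index,
        "time_min": time_min,
        "log_fc": log_fc,
        "t_stat": t,
        "p_value": p,
        "fdr": bh_adjust(p),
    })


def differential_timecourse(m: AbundanceMatrix,
                            baseline: float = 0) -> pd.DataFrame:
    """Moderated t tests of every non-baseline time point vs baseline."""
    times = sorted(t for t in m.sample_meta["time_min"].unique()
                   if t != baseline)
    frames = [moderated_t_test(m, t, baseline=baseline) for t in times]
    return pd.concat(frames, ignore_index=True)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significant_sites(results: pd.DataFrame, fdr_cut: float = 0.05,
                      direction: str = "any") -> set:
    """Feature ids significant at the FDR cut, optionally one-sided."""
    if direction not in ("up", "down", "any"):
        raise ValueError(f"unknown direction {direction!r}")
    mask = results["fdr"] < fdr_cut
    if direction == "up":
        mask &= results["log_fc"] > 0
    elif direction == "down":
        mask &= results["log_fc"] < 0
    return set(results.loc[mask, "feature_id"])
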
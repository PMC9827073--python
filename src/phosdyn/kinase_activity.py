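"""Relative kinase activity (RKA) inference from annotated phosphosites.

Site abundances are first scaled peptide-wise (per-feature z-score
across samples, so overall site abundance cannot dominate). For each
kinase and sample the scaled abundances of the kinase's annotated
substrates are combined with the Stouffer Z method,

    RKA_k = sum_i S_i / sqrt(n),

over the n matched substrate sites (kinases with fewer than
``min_sites`` matched sites are dropped). Per-condition mean activities
are obtained from a linear model on condition indicators (ordinary
least squares: the fitted coefficients are per-condition means, with
standard errors from the pooled residual variance), activity shifts
are differences from the baseline condition with errors propagated in
quadrature, and the significance threshold is the standard-normal
quantile at the chosen level (RKA scores are approximately standard
normal under the null).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceMatrix

logger = logging.getLogger(__name__)


def scale_peptidewise(m: AbundanceMatrix, log_transform: bool = True,
                      ) -> pd.DataFrame:
    """Per-feature z-score across samples (sample SD, ddof=1).

    Zero-variance features are excluded with a warning. Abundances are
    log2-transformed first by default.
    """
    values = np.log2(m.values) if log_transform else m.values.copy()
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(f"excluding {(~keep).sum()} zero-variance feature(s) "
                      "from peptide-wise scaling")
    values = values.loc[keep]
    return values.sub(values.mean(axis=1), axis=0).div(sd[keep], axis=0)


def compute_rka(scaled: pd.DataFrame, annotations: pd.DataFrame,
                feature_meta: pd.DataFrame, min_sites: int = 5,
                combine: str = "sqrt_n") -> pd.DataFrame:
    """Stouffer-combined kinase activity per (kinase, sample).

    ``annotations`` (kinase, accession, position) are joined to scaled
    features via ``feature_meta`` (accession, position per feature id).
    ``combine`` selects the denominator: ``"sqrt_n"`` (Stouffer,
    default) or the literal ``"n"`` (plain mean). Returns long-format
    rows (kinase, sample_id, rka, n_sites).
    """
    if combine not in ("sqrt_n", "n"):
        raise ValueError("combine must be 'sqrt_n' or 'n'")
    key = feature_meta.reset_index().rename(
        columns={feature_meta.index.name or "index": "feature_id"})
    joined = annotations.merge(key[["feature_id", "accession", "position"]],
                               on=["accession", "position"], how="inner")
    joined = joined[joined["feature_id"].isin(scaled.index)]
    rows = []
    for kinase, grp in joined.groupby("kinase"):
        feats = grp["feature_id"].unique()
        n = len(feats)
        if n == 0:
            logger.info("kinase %s: no matched sites, dropped", kinase)
            continue
        if n < min_sites:
            logger.info("kinase %s: %d < %d sites, dropped", kinase, n,
                        min_sites)
            continue
        denom = np.sqrt(n) if combine == "sqrt_n" else n
        combined = scaled.loc[feats].sum(axis=0) / denom
        for sample_id, val in combined.items():
            rows.append((kinase, sample_id, float(val), n))
    return pd.DataFrame(rows, columns=["kinase", "sample_id", "rka",
                                       "n_sites"])


def rka_condition_means(rka: pd.DataFrame,
                        sample_meta: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean RKA with standard errors, per kinase.

    Fits, for each kinase, the linear model rka ~ condition indicators
    whose least-squares coefficients are the per-condition means;
    SE(beta_c) = sqrt(pooled residual variance / n_c). With no residual
    degrees of freedom the SE is reported as NaN.
    """
    df = rka.merge(sample_meta[["time_min"]], left_on="sample_id",
                   right_index=True, how="left")
    if df["time_min"].isna().any():
        missing = df.loc[df["time_min"].isna(), "sample_id"].unique()
        raise ValueError(f"samples missing from design: {list(missing)}")
    rows = []
    for kinase, grp in df.groupby("kinase"):
        conds = sorted(grp["time_min"].unique())
        n_total = len(grp)
        betas = grp.groupby("time_min")["rka"].mean()
        resid = grp["rka"].to_numpy() - betas.loc[grp["time_min"]].to_numpy()
        dof = n_total - len(conds)
        sigma2 = float(resid @ resid) / dof if dof > 0 else np.nan
        for cond in conds:
            n_c = int((grp["time_min"] == cond).sum())
            se = np.sqrt(sigma2 / n_c) if dof > 0 else np.nan
            rows.append((kinase, cond, float(betas.loc[cond]), se, n_c,
                         int(grp["n_sites"].iloc[0])))
    return pd.DataFrame(rows, columns=["kinase", "time_min", "beta", "se",
                                       "n_samples", "n_sites"])


def rka_threshold(alpha: float = 0.01, two_sided: bool = False) -> float:
    """Standard-normal critical value for RKA significance."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    tail = alpha / 2 if two_sided else alpha
    return float(stats.norm.ppf(1.0 - tail))


def rka_shift(betas: pd.DataFrame, baseline: float = 0) -> pd.DataFrame:
    """Activity shift vs the baseline condition with propagated SE.

    shift = beta_t - beta_0; SE_shift = sqrt(SE_t^2 + SE_0^2).
    """
    out = []
    for kinase, grp in betas.groupby("kinase"):
        grp = grp.set_index("time_min")
        if baseline not in grp.index:
            raise ValueError(f"kinase {kinase}: baseline condition "
                             f"{baseline} absent")
        b0, se0 = grp.loc[baseline, "beta"], grp.loc[baseline, "se"]
        for cond, row in grp.iterrows():
            shift = row["beta"] - b0
            se = (0.0 if cond == baseline
                  else float(np.sqrt(row["se"] ** 2 + se0 ** 2)))
            out.append((kinase, cond, float(shift), se))
    return pd.DataFrame(out, columns=["kinase", "time_min", "shift",
                                      "se_shift"])


def rka_correlation(betas: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of per-kinase activity time profiles."""
    wide = betas.pivot(index="kinase", columns="time_min", values="beta")
    if wide.shape[1] < 3:
        raise ValueError("need >=3 conditions for activity correlation")
    constant = wide.std(axis=1, ddof=0) == 0
    if constant.any():
        logger.info("constant activity profile(s): %s",
                    list(wide.index[constant]))
    # rows with zero variance yield NaN correlations
    corr = wide.T.corr(method="pearson")
    corr.loc[constant, :] = np.nan
    corr.loc[:, constant] = np.nan
    arr = corr.to_numpy(copy=True)
    np.fill_diagonal(arr, np.where(constant, np.nan, 1.0))
    return pd.DataFrame(arr, index=corr.index, columns=corr.columns)
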
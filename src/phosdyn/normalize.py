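"""Two-step abundance normalization for multiplexed time-course data.

Step 1 (sample loading): each sample is rescaled by SF_i = mean column
sum / its own column sum, so every column sums to the grand mean.

Step 2 (artificial internal reference standards, ARS): for each feature
j and biological replicate i, the ARS is the feature's total abundance
across the conditions of that replicate; a per-(feature, replicate)
scaling factor ARSSF_{i,j} = reference ARS_j / ARS_{i,j} then equalizes
the feature's within-replicate totals across replicates, removing
replicate-level batch effects. The cross-replicate reference is the
mean ARS by default (a literal sum inflates every factor uniformly by
the replicate count; the sum reading is available via ``reference``).

Also provides protein-level correction of phospho profiles and the
Z-score adjustment helpers used for display (anchor at t=0, or shift
so the minimum is zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix

CONSERVATION_RTOL = 1e-9


@dataclass
class NormalizationFactors:
    """Audit trail of the scaling factors applied."""

    sample_factors: pd.Series | None = None           # SF_i
    ars_factors: pd.DataFrame | None = None           # ARSSF_{i,j}
    ars_reference: pd.Series | None = None            # reference ARS_j


def sample_loading_normalize(
        m: AbundanceMatrix) -> tuple[AbundanceMatrix, NormalizationFactors]:
    """Equalize column sums: A_ij * SF_i with SF_i = mean(AS) / AS_i."""
    col_sums = m.values.sum(axis=0)
    zero = col_sums[col_sums <= 0]
    if len(zero):
        raise ValueError(
            f"sample(s) with zero total abundance: {list(zero.index)}")
    sf = col_sums.mean() / col_sums
    sf.name = "sample_factor"
    out = m.with_values(m.values * sf)
    return out, NormalizationFactors(sample_factors=sf)


def _replicate_groups(m: AbundanceMatrix):
    """Sample ids grouped by (dataset, replicate)."""
    return {key: list(grp.index) for key, grp in
            m.sample_meta.groupby(["dataset", "replicate"], sort=True)}


def ars_normalize(m: AbundanceMatrix, reference: str = "mean",
                  ) -> tuple[AbundanceMatrix, NormalizationFactors]:
    """Artificial-internal-reference-standard normalization.

    Equalizes, per feature, the total abundance across the conditions
    of each biological replicate (grouping samples by dataset and
    replicate). ``reference`` chooses how per-replicate ARS values are
    aggregated into the dataset-wide reference: ``"mean"`` (default) or
    the literal ``"sum"``.
    """
    if reference not in ("mean", "sum"):
        raise ValueError("reference must be 'mean' or 'sum'")
    groups = _replicate_groups(m)
    ars = pd.DataFrame(
        {f"{ds}_rep{rep}": m.values[cols].sum(axis=1)
         for (ds, rep), cols in groups.items()})
    bad = ars.le(0)
    if bad.any().any():
        j = bad.any(axis=1).idxmax()
        i = bad.loc[j][bad.loc[j]].index[0]
        raise ValueError(f"zero ARS for feature {j!r} in replicate {i!r}")
    ref = ars.mean(axis=1) if reference == "mean" else ars.sum(axis=1)
    ref.name = "ars_reference"
    arssf = ref.to_numpy()[:, None] / ars
    values = m.values.copy()
    for (ds, rep), cols in groups.items():
        values[cols] = values[cols].mul(arssf[f"{ds}_rep{rep}"], axis=0)
    out = m.with_values(values)
    return out, NormalizationFactors(ars_factors=arssf, ars_reference=ref)


def normalize(m: AbundanceMatrix, reference: str = "mean",
              ) -> tuple[AbundanceMatrix, NormalizationFactors]:
    """Full two-step normalization: sample loading, then ARS."""
    step1, f1 = sample_loading_normalize(m)
    step2, f2 = ars_normalize(step1, reference=reference)
    return step2, NormalizationFactors(sample_factors=f1.sample_factors,
                                       ars_factors=f2.ars_factors,
                                       ars_reference=f2.ars_reference)


def protein_correct(phospho: AbundanceMatrix, protein: AbundanceMatrix,
                    ) -> tuple[AbundanceMatrix, pd.Series]:
    """Correct phospho profiles for total protein abundance changes.

    For features whose accession is quantified at the protein level,
    divides by the protein's sample profile normalized to its own mean
    (log2 phospho minus mean-centered log2 protein, re-exponentiated)
    so flat proteins leave profiles untouched. Returns the corrected
    matrix and a boolean per-feature ``corrected`` flag; unmatched
    features pass through unchanged.
    """
    if list(phospho.values.columns) != list(protein.values.columns):
        raise ValueError("phospho and protein matrices have different "
                         "sample columns")
    if phospho.feature_meta is None or "accession" not in \
            phospho.feature_meta.columns:
        raise ValueError("phospho feature metadata must carry accessions")
    log_prot = np.log2(protein.values.where(protein.values > 0))
    log_prot = log_prot.sub(log_prot.mean(axis=1), axis=0)  # centered
    acc = phospho.feature_meta["accession"]
    matched = acc.isin(log_prot.index)
    corr = np.log2(phospho.values.where(phospho.values > 0))
    adj = log_prot.reindex(acc[matched]).to_numpy()
    corr.loc[matched] = corr.loc[matched] - adj
    out_values = (2.0 ** corr).fillna(0.0)
    out = phospho.with_values(out_values)
    flags = pd.Series(matched.to_numpy(), index=phospho.values.index,
                      name="corrected")
    return out, flags


def adjusted_zscore(profile: pd.Series | np.ndarray,
                    mode: str = "baseline_zero",
                    baseline_index=None):
    """Shift a standardized profile for display.

    ``baseline_zero`` subtracts the first (or ``baseline_index``) value
    so the series starts at zero; ``min_shift`` subtracts the minimum
    so the smallest value is zero.
    """
    arr = pd.Series(profile).astype(float)
    if arr.empty:
        raise ValueError("empty profile")
    if mode == "baseline_zero":
        base = arr.iloc[0] if baseline_index is None else arr.loc[baseline_index]
        shifted = arr - base
    elif mode == "min_shift":
        shifted = arr - arr.min()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(profile, np.ndarray):
        return shifted.to_numpy()
    return shifted
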
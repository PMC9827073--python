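"""Empirical CDK-substrate prediction and motif comparisons.

A site is a *theoretical* CDK substrate when its calibrated PSSM
probability reaches the ROC cutoff for CDK1 or CDK2; it is an
*empirical* prediction when, in addition, its phosphorylation is
significantly increased (FDR < 0.05, positive fold change) and its
time profile falls in one of the two increasing ("fast"/"slow")
dynamics clusters. CDK1/CDK2 calls are merged into one list keeping
the larger probability.

Also: bootstrap comparison of flank residue frequencies between the
fast and slow clusters (normal null on the resampled frequency
differences), scanning for cyclin-docking Cy motifs ([R/K]-x-[L/V/I])
around phosphosites with Kolmogorov-Smirnov comparison of the
nearest-motif distance distributions, and hypergeometric gene-set
over-representation with BH correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AMINO_ACIDS, PAD
from .differential import bh_adjust

CY_FIRST = set("RK")
CY_THIRD = set("LVI")


def predict_empirical_cdk(probabilities: pd.DataFrame,
                          cutoffs: dict,
                          cluster_assignment: pd.Series,
                          dynamic_clusters: dict,
                          diff_results: pd.DataFrame,
                          fdr_cut: float = 0.05,
                          cdk_kinases: tuple = ("CDK1", "CDK2"),
                          ) -> pd.DataFrame:
    """Combine PSSM classification with empirical time-course filters.

    Parameters
    ----------
    probabilities
        site x kinase calibrated probabilities.
    cutoffs
        kinase -> probability cutoff (ROC-derived).
    cluster_assignment
        site -> hard FCM cluster; ``dynamic_clusters`` supplies the
        fast/slow cluster ids.
    diff_results
        long-format differential results (feature_id, time_min, log_fc,
        fdr); a site is significantly up if any time point passes.

    Returns a ranked table with per-site flags; raises when the three
    inputs disagree on site identifiers.
    """
    sites = probabilities.index
    orphans = [s for s in sites if s not in cluster_assignment.index]
    orphans += [s for s in sites
                if s not in set(diff_results["feature_id"])]
    if orphans:
        raise ValueError(f"site identifiers missing from upstream results: "
                         f"{sorted(set(orphans))[:10]}")
    kinases = [k for k in cdk_kinases if k in probabilities.columns]
    if not kinases:
        raise ValueError(f"none of {cdk_kinases} present in probabilities")

    theo = pd.Series(False, index=sites)
    for k in kinases:
        theo |= probabilities[k] >= cutoffs[k]
    merged_prob = probabilities[kinases].max(axis=1)
    best_kinase = probabilities.idxmax(axis=1)

    up = diff_results[(diff_results["fdr"] < fdr_cut)
                      & (diff_results["log_fc"] > 0)]
    sig_up = pd.Series(sites.isin(set(up["feature_id"])), index=sites)

    fast, slow = dynamic_clusters.get("fast"), dynamic_clusters.get("slow")
    in_dyn = cluster_assignment.reindex(sites).isin(
        [c for c in (fast, slow) if c is not None])

    out = pd.DataFrame({
        "cdk_probability": merged_prob,
        "best_kinase": best_kinase,
        "theoretical": theo,
        "cluster": cluster_assignment.reindex(sites),
        "in_dynamic_cluster": in_dyn,
        "significant_up": sig_up,
    })
    out["empirical"] = out["theoretical"] & out["in_dynamic_cluster"] \
        & out["significant_up"]
    out = out.sort_values("cdk_probability", ascending=False)
    out.index.name = "site_id"
    return out


def compare_cluster_frequencies(fast_flanks: list, slow_flanks: list,
                                n_resamples: int = 100,
                                positions: tuple = tuple(range(-7, 8)),
                                residues: tuple = ("S", "T", "K"),
                                seed: int = 0) -> pd.DataFrame:
    """Bootstrap fast-minus-slow flank residue frequency differences.

    Each cluster is resampled with replacement at its own size
    ``n_resamples`` times; per resample the residue frequency at each
    flank position (pads excluded from the denominator) is computed and
    the slow frequency subtracted from the fast. Reports the mean and
    SD of the differences and a two-sided p value of the mean under a
    normal null centered at 0 with that cell's SD (NaN when SD is 0).
    """
    if n_resamples < 2:
        raise ValueError("n_resamples must be >= 2")
    if not fast_flanks or not slow_flanks:
        raise ValueError("both clusters must be nonempty")
    rng = np.random.default_rng(seed)
    offset = {p: p + 10 for p in positions}

    def freqs(flanks) -> np.ndarray:
        # positions x residues frequency table for one resample
        table = np.zeros((len(positions), len(residues)))
        for pi, p in enumerate(positions):
            col = [f[offset[p]] for f in flanks if f[offset[p]] != PAD]
            denom = len(col)
            if denom == 0:
                continue
            for ri, r in enumerate(residues):
                table[pi, ri] = sum(ch == r for ch in col) / denom
        return table

    diffs = np.empty((n_resamples, len(positions), len(residues)))
    fast_arr, slow_arr = list(fast_flanks), list(slow_flanks)
    for b in range(n_resamples):
        fb = [fast_arr[i] for i in
              rng.integers(len(fast_arr), size=len(fast_arr))]
        sb = [slow_arr[i] for i in
              rng.integers(len(slow_arr), size=len(slow_arr))]
        diffs[b] = freqs(fb) - freqs(sb)

    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 2.0 * stats.norm.sf(np.abs(mean) / sd)
    p = np.where(sd == 0, np.nan, p)
    rows = []
    for pi, pos in enumerate(positions):
        for ri, r in enumerate(residues):
            rows.append((pos, r, mean[pi, ri], sd[pi, ri], p[pi, ri]))
    return pd.DataFrame(rows, columns=["position", "residue", "mean_diff",
                                       "sd", "p_value"])


def find_cy_motifs(sequence: str, site_pos: int) -> dict:
    """All Cy-motif ([R/K]-x-[L/V/I]) matches and nearest distances.

    Matches may overlap; the wildcard x matches any of the 20 residues
    (never a pad/unknown character). Distances are |motif start -
    site_pos| in residues, reported separately for the nearest match on
    each side of the (1-based) phosphosite position; ``None`` when a
    side has no match.
    """
    if not 1 <= site_pos <= len(sequence):
        raise ValueError(f"site position {site_pos} outside sequence")
    matches = []
    for i in range(len(sequence) - 2):
        a, x, c = sequence[i], sequence[i + 1], sequence[i + 2]
        if a in CY_FIRST and c in CY_THIRD and x in AMINO_ACIDS:
            matches.append(i + 1)   # 1-based motif start
    left = [m for m in matches if m < site_pos]
    right = [m for m in matches if m > site_pos]
    return {
        "matches": matches,
        "left_distance": (site_pos - max(left)) if left else None,
        "right_distance": (min(right) - site_pos) if right else None,
    }


def cy_distance_table(sequences: dict, sites: pd.DataFrame) -> pd.DataFrame:
    """Nearest Cy-motif distances for a table of (accession, position)."""
    rows = []
    for sid, row in sites.iterrows():
        seq = sequences[row["accession"]]
        res = find_cy_motifs(seq, int(row["position"]))
        rows.append((sid, res["left_distance"], res["right_distance"],
                     len(res["matches"])))
    return pd.DataFrame(rows, columns=["site_id", "left_distance",
                                       "right_distance", "n_matches"]
                        ).set_index("site_id")


def compare_distance_distributions(dist_a, dist_b) -> dict:
    """Two-sample Kolmogorov-Smirnov test on nearest-motif distances."""
    a = np.asarray([d for d in dist_a if d is not None], dtype=float)
    b = np.asarray([d for d in dist_b if d is not None], dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(a, b, method="asymp")
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "n_a": len(a), "n_b": len(b)}


def ora_hypergeometric(hit_set, gene_sets: dict, background) -> pd.DataFrame:
    """Hypergeometric over-representation of gene sets among hits.

    ``background`` is the universe (e.g. all detected phosphoproteins);
    gene sets are intersected with it and hits must be a subset of it.
    Upper-tail p per set, BH-adjusted across sets.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    hits = set(hit_set)
    if not hits <= background:
        raise ValueError("hit set must be a subset of the background")
    n_bg, n_hits = len(background), len(hits)
    rows = []
    for name, members in gene_sets.items():
        in_bg = set(members) & background
        overlap = len(in_bg & hits)
        # P(X >= overlap), X ~ Hypergeom(N=n_bg, K=len(in_bg), n=n_hits)
        p = float(stats.hypergeom.sf(overlap - 1, n_bg, len(in_bg), n_hits))
        rows.append((name, overlap, len(in_bg), min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["gene_set", "n_overlap", "n_set",
                                      "p_value"])
    out["fdr"] = bh_adjust(out["p_value"]) if len(out) else []
    return out
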
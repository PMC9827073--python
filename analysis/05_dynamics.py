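"""Phosphorylation dynamics: FCM clustering and kinetic modeling.

Clusters the regulated sites' scaled time profiles (8 clusters,
fuzzifier 2) and fits the Michaelis-Menten curve to each increasing
cluster; the smallest and largest half-times define the "fast" and
"slow" dynamic classes.
"""

import json
from pathlib import Path

import pandas as pd

from phosdyn.containers import AbundanceMatrix
from phosdyn.differential import significant_sites
from phosdyn.dynamics import (fcm_cluster, fit_clusters,
                              label_dynamic_clusters, mean_time_profiles)
from phosdyn.kinase_activity import scale_peptidewise

BASE = Path(__file__).resolve().parent.parent / "results" / "analysis"
SEED = 1


def main() -> None:
    m = AbundanceMatrix.from_tsv(BASE / "normalized_abundance.tsv",
                                 BASE / "sample_design.tsv",
                                 BASE / "phospho_features.tsv")
    diff = pd.read_csv(BASE / "differential.tsv", sep="\t")
    scaled = scale_peptidewise(m)
    regulated = sorted(significant_sites(diff, 0.05)
                       & set(scaled.index))
    profiles = mean_time_profiles(scaled.loc[regulated], m.sample_meta)
    fcm = fcm_cluster(profiles, n_clusters=8, fuzzifier=2.0, seed=SEED)
    fits = fit_clusters(profiles, profiles.columns.to_numpy(float), fcm)
    labels = label_dynamic_clusters(fcm, fits)

    print(f"clustered {len(regulated)} regulated sites into 8 clusters")
    for name in ("fast", "slow"):
        c = labels[name]
        if c is not None:
            print(f"{name:>5}: {c} (K = {fits[c].K:.1f} min, "
                  f"Vm = {fits[c].Vm:.2f}, "
                  f"{int((fcm.hard_assignment == c).sum())} sites)")
    print("decreasing clusters:", labels["decreasing_set"])

    fcm.membership.rename_axis("site_id").to_csv(
        BASE / "fcm_membership.tsv", sep="\t")
    fcm.centroids.rename_axis("cluster").to_csv(
        BASE / "fcm_centroids.tsv", sep="\t")
    pd.DataFrame([(c, f.Vm, f.K, f.converged, f.rss, f.fallback or "")
                  for c, f in fits.items()],
                 columns=["cluster", "Vm", "K", "converged", "rss",
                          "fallback"]).to_csv(
        BASE / "cluster_kinetics.tsv", sep="\t", index=False)
    (BASE / "dynamic_clusters.json").write_text(
        json.dumps(labels, default=str, indent=1))


if __name__ == "__main__":
    main()
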
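"""Relative kinase activity (Stouffer Z over annotated substrates).

Expectation under the planted truth: CDK1/CDK2 activities rise after
WEE1 inhibition and clear the 1% normal threshold; the basophilic
control kinase (flat substrates) does not.
"""

from pathlib import Path

import pandas as pd

from phosdyn.containers import AbundanceMatrix
from phosdyn.kinase_activity import (compute_rka, rka_condition_means,
                                     rka_correlation, rka_shift,
                                     rka_threshold, scale_peptidewise)

BASE = Path(__file__).resolve().parent.parent / "results"
SIM, OUT = BASE / "simdata", BASE / "analysis"


def main() -> None:
    m = AbundanceMatrix.from_tsv(OUT / "normalized_abundance.tsv",
                                 OUT / "sample_design.tsv",
                                 OUT / "phospho_features.tsv")
    annotations = pd.read_csv(SIM / "annotations.tsv", sep="\t")
    scaled = scale_peptidewise(m)
    rka = compute_rka(scaled, annotations, m.feature_meta, min_sites=5)
    betas = rka_condition_means(rka, m.sample_meta)
    shifts = rka_shift(betas)
    thr = rka_threshold(0.01)

    print(f"1% activity significance threshold: {thr:.4f}")
    for _, row in shifts[shifts["time_min"] == 90].iterrows():
        flag = "significant" if row["shift"] > thr else "ns"
        print(f"{row['kinase']:>5}: shift at 90 min = "
              f"{row['shift']:+.2f} +/- {row['se_shift']:.2f} ({flag})")

    rka.to_csv(OUT / "rka_scores.tsv", sep="\t", index=False)
    betas.to_csv(OUT / "rka_condition_means.tsv", sep="\t", index=False)
    shifts.to_csv(OUT / "rka_shifts.tsv", sep="\t", index=False)
    rka_correlation(betas).to_csv(OUT / "rka_correlation.tsv", sep="\t")


if __name__ == "__main__":
    main()
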
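"""Two-step normalization and protein correction of the simulated data.

Sample-loading scaling equalizes column sums; ARS scaling equalizes
each site's within-replicate totals across biological replicates;
phospho profiles are then corrected for total protein abundance.
"""

from pathlib import Path

import numpy as np

from phosdyn.containers import AbundanceMatrix
from phosdyn.normalize import (normalize, protein_correct,
                               sample_loading_normalize)

BASE = Path(__file__).resolve().parent.parent / "results"
SIM, OUT = BASE / "simdata", BASE / "analysis"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    phospho = AbundanceMatrix.from_tsv(SIM / "phospho_abundance.tsv",
                                       SIM / "sample_design.tsv",
                                       SIM / "phospho_features.tsv")
    protein = AbundanceMatrix.from_tsv(SIM / "protein_abundance.tsv",
                                       SIM / "sample_design.tsv")
    phospho_n, factors = normalize(phospho)
    protein_n, _ = normalize(protein)
    corrected, flags = protein_correct(phospho_n, protein_n)

    step1, _ = sample_loading_normalize(phospho)
    col_sums = step1.values.sum(axis=0)
    print(f"column-sum spread after loading scaling: "
          f"{float(col_sums.max() / col_sums.min() - 1):.2e} (conserved)")
    reps = phospho_n.sample_meta["replicate"].unique()
    rep_sums = np.stack([
        phospho_n.values[phospho_n.samples_at(replicate=r)].sum(axis=1)
        for r in reps])
    rep_spread = float((rep_sums.max(axis=0) / rep_sums.min(axis=0)).max()
                       - 1)
    print(f"per-site within-replicate sum spread after ARS: "
          f"{rep_spread:.2e} (conserved)")
    sf = factors.sample_factors
    print(f"sample loading factors span {sf.min():.3f}..{sf.max():.3f}")
    print(f"protein-corrected sites: {int(flags.sum())}/{len(flags)}")

    corrected.to_tsv(OUT / "normalized_abundance.tsv",
                     OUT / "sample_design.tsv",
                     OUT / "phospho_features.tsv")
    factors.sample_factors.rename_axis("sample_id").to_csv(
        OUT / "sample_loading_factors.tsv", sep="\t")
    factors.ars_factors.rename_axis("feature_id").to_csv(
        OUT / "ars_factors.tsv", sep="\t")


if __name__ == "__main__":
    main()
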
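"""Per-time-point moderated differential testing against t = 0.

Empirical-Bayes moderated t per site and time point on log2
abundances, BH-corrected per contrast.
"""

from pathlib import Path

from phosdyn.containers import AbundanceMatrix
from phosdyn.differential import differential_timecourse, significant_sites

BASE = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main() -> None:
    m = AbundanceMatrix.from_tsv(BASE / "normalized_abundance.tsv",
                                 BASE / "sample_design.tsv",
                                 BASE / "phospho_features.tsv")
    diff = differential_timecourse(m)
    diff.to_csv(BASE / "differential.tsv", sep="\t", index=False)
    for t, grp in diff.groupby("time_min"):
        up = len(significant_sites(grp, 0.05, "up"))
        down = len(significant_sites(grp, 0.05, "down"))
        print(f"t = {t:>2g} min: {up:4d} up, {down:4d} down (FDR < 5%)")
    print(f"{len(significant_sites(diff, 0.05))} sites significant at "
          "any time point")


if __name__ == "__main__":
    main()
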
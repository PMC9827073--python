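"""Binomial-model PSSMs with disorder-adjusted background and
logistic calibration.

Builds a 21 x 20 scoring matrix per kinase from the planted substrate
flanks (curation effort > 2, >= 20 sites), calibrates raw scores into
probabilities on a balanced 80/20 split, and picks the probability
cutoff by Youden's J on the held-out split.
"""

import json
from pathlib import Path

import pandas as pd

from phosdyn.motif_pssm import (background_frequencies, build_pssm,
                                calibrate_models)
from phosdyn.synth import read_proteome

BASE = Path(__file__).resolve().parent.parent / "results"
SIM, OUT = BASE / "simdata", BASE / "analysis"
SEED = 1


def main() -> None:
    proteome = read_proteome(SIM / "proteome.fasta", SIM / "disorder.tsv")
    annotations = pd.read_csv(SIM / "annotations.tsv", sep="\t")
    features = pd.read_csv(OUT / "phospho_features.tsv", sep="\t",
                           index_col="feature_id")

    bg = background_frequencies(proteome, cutoff=0.4)
    print(f"background from {bg.n_residues_used} disordered residues; "
          f"most common: {bg.freq.idxmax()} ({bg.freq.max():.3f})")

    flank_of = {(r["accession"], r["position"]): r["flank"]
                for _, r in features.iterrows()}
    models = build_pssm(annotations, flank_of, bg, min_sites=20,
                        curation_min=2)
    annotated = set(zip(annotations["accession"], annotations["position"]))
    decoys = [r["flank"] for _, r in features.iterrows()
              if (r["accession"], r["position"]) not in annotated]
    positives = {k: [flank_of[(a, p)] for a, p in
                     zip(g["accession"], g["position"])
                     if (a, p) in flank_of]
                 for k, g in annotations.groupby("kinase") if k in models}
    calibrate_models(models, positives, decoys, seed=SEED)

    sidecar = {}
    for kinase, model in models.items():
        top = model.scores.drop(index=0).stack().idxmax()
        print(f"{kinase:>5}: {model.n_training_sites} training sites, "
              f"test AUC {model.auc:.3f}, cutoff {model.cutoff:.3f}, "
              f"strongest preference {top[1]} at {top[0]:+d}")
        model.to_tsv(OUT / f"pssm_{kinase}.tsv")
        sidecar[kinase] = {"beta0": model.beta0, "beta1": model.beta1,
                           "cutoff": model.cutoff, "auc": model.auc,
                           "n_training_sites": model.n_training_sites}
    (OUT / "pssm_models.json").write_text(json.dumps(sidecar, indent=1))


if __name__ == "__main__":
    main()
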
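"""Empirical CDK substrate prediction.

A site is called empirically when it (1) reaches the calibrated CDK1
or CDK2 probability cutoff, (2) falls in the fast or slow dynamics
cluster, and (3) is significantly up-regulated. Recovery against the
planted truth is reported.
"""

import json
from pathlib import Path

import pandas as pd

from phosdyn.cdk_predict import predict_empirical_cdk
from phosdyn.motif_pssm import (BackgroundFreqs, PssmModel, score_sites)

BASE = Path(__file__).resolve().parent.parent / "results"
SIM, OUT = BASE / "simdata", BASE / "analysis"


def _load_model(kinase, meta):
    scores = pd.read_csv(OUT / f"pssm_{kinase}.tsv", sep="\t",
                         index_col="position")
    freq = pd.Series(0.05, index=list(scores.columns))
    model = PssmModel(kinase=kinase, scores=scores,
                      n_training_sites=meta["n_training_sites"],
                      background=BackgroundFreqs(freq, 0),
                      beta0=meta["beta0"], beta1=meta["beta1"],
                      cutoff=meta["cutoff"])
    return model


def main() -> None:
    features = pd.read_csv(OUT / "phospho_features.tsv", sep="\t",
                           index_col="feature_id")
    diff = pd.read_csv(OUT / "differential.tsv", sep="\t")
    memb = pd.read_csv(OUT / "fcm_membership.tsv", sep="\t",
                       index_col="site_id")
    labels = json.loads((OUT / "dynamic_clusters.json").read_text())
    metas = json.loads((OUT / "pssm_models.json").read_text())

    models = {k: _load_model(k, m) for k, m in metas.items()}
    probs = pd.DataFrame({
        k: model.calibrated_probability(
            score_sites(features["flank"].tolist(), model))
        for k, model in models.items()}, index=features.index)
    assignment = memb.idxmax(axis=1).reindex(features.index).fillna(
        "unclustered")
    pred = predict_empirical_cdk(
        probs, {k: m.cutoff for k, m in models.items()}, assignment,
        labels, diff)
    pred.to_csv(OUT / "cdk_predictions.tsv", sep="\t")

    print(f"theoretical CDK sites: {int(pred['theoretical'].sum())}")
    print(f"empirical CDK sites:   {int(pred['empirical'].sum())}")
    truth = pd.read_csv(SIM / "truth_sites.tsv", sep="\t",
                        index_col="site_id")
    planted = set(truth.index[truth["true_kinase"].isin(
        ["CDK1", "CDK2"])])
    called = set(pred.index[pred["empirical"]])
    tp = len(called & planted)
    print(f"recovery vs planted truth: sensitivity "
          f"{tp / len(planted):.3f}, precision {tp / len(called):.3f}")


if __name__ == "__main__":
    main()
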
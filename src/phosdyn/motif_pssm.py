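"""Binomial-probability-model PSSMs for kinase-substrate prediction.

For each kinase with enough well-curated substrate sites, the +/-10
flanking sequences are summarized into a 21 x 20 position-specific
scoring matrix of binomial log-odds residue scores

    RS_a = -log10[ P(k >= K_a | N, p_a) / P(k <= K_a | N, p_a) ],

where K_a is the observed count of residue a at a position, N the
number of (non-padded) residues at that position, and p_a the
background frequency of a — computed from disordered protein regions
only (disorder > 0.4), since phosphosites concentrate in disordered
sequence whose composition is biased. Positive scores mark enrichment.

Candidate sites are scored by summing matrix entries over their flank
(S = sum RS(a, b)); raw scores are made comparable across kinases by
logistic calibration P(S) = 1 / (1 + exp(-(b0 + b1 S))) fitted on
class-balanced (down-sampled) training data, and a probability cutoff
is chosen on a ROC curve by Youden's J.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve

from .containers import AMINO_ACIDS, PAD, ProteinRecord

logger = logging.getLogger(__name__)

FLANK_POSITIONS = tuple(range(-10, 11))


@dataclass
class BackgroundFreqs:
    """Amino-acid background from disordered regions (pseudocounted)."""

    freq: pd.Series                 # indexed by the 20 residues, sums to 1
    n_residues_used: int
    disorder_cutoff: float = 0.4


def background_frequencies(proteome: list[ProteinRecord],
                           cutoff: float = 0.4) -> BackgroundFreqs:
    """F_i = A_i / T over residues with disorder score above ``cutoff``.

    One pseudocount per residue class avoids zero backgrounds.
    """
    if not proteome:
        raise ValueError("empty proteome")
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must be in [0, 1]")
    counts = dict.fromkeys(AMINO_ACIDS, 0)
    total = 0
    for p in proteome:
        mask = p.disorder > cutoff
        for ch, keep in zip(p.sequence, mask):
            if keep and ch in counts:
                counts[ch] += 1
                total += 1
    if total == 0:
        raise ValueError(f"no residues pass disorder cutoff {cutoff}")
    freq = pd.Series(counts, dtype=float) + 1.0
    freq = freq / freq.sum()
    return BackgroundFreqs(freq=freq, n_residues_used=total,
                           disorder_cutoff=cutoff)


def residue_score(k_a: int, n: int, p_a: float,
                  lower_tail_exclusive: bool = False) -> float:
    """Binomial log-odds of over- vs under-representation.

    RS = -log10[ P(k >= K_a) / P(k <= K_a) ] under Binomial(N, p_a).
    ``lower_tail_exclusive`` reproduces a variant lower tail that stops
    at K_a - 1. N = 0 returns 0 by convention.
    """
    if not 0 <= k_a <= n:
        raise ValueError(f"K_a={k_a} outside [0, N={n}]")
    if not 0 < p_a < 1:
        raise ValueError("p_a must be in (0, 1)")
    if n == 0:
        logger.info("residue_score called with N=0; returning 0")
        return 0.0
    upper = stats.binom.sf(k_a - 1, n, p_a)       # P(k >= K_a)
    if lower_tail_exclusive:
        lower = stats.binom.cdf(k_a - 1, n, p_a)  # P(k <= K_a - 1)
    else:
        lower = stats.binom.cdf(k_a, n, p_a)      # P(k <= K_a)
    if lower == 0:
        lower = np.finfo(float).tiny
    if upper == 0:
        upper = np.finfo(float).tiny
    return float(-np.log10(upper / lower))


@dataclass
class PssmModel:
    """Per-kinase scoring model with calibration and cutoff."""

    kinase: str
    scores: pd.DataFrame            # 21 positions (-10..+10) x 20 residues
    n_training_sites: int
    background: BackgroundFreqs
    beta0: float | None = None
    beta1: float | None = None
    cutoff: float | None = None
    auc: float | None = None
    extra: dict = field(default_factory=dict)

    def calibrated_probability(self, raw_scores):
        if self.beta0 is None or self.beta1 is None:
            raise ValueError(f"{self.kinase}: model not calibrated")
        s = np.asarray(raw_scores, dtype=float)
        return 1.0 / (1.0 + np.exp(-(self.beta0 + self.beta1 * s)))

    def to_tsv(self, path) -> None:
        self.scores.rename_axis("position").to_csv(path, sep="\t")


def count_matrix(flanks: list[str]) -> tuple[pd.DataFrame, pd.Series]:
    """Per-position residue counts K_a and non-pad totals N over flanks."""
    counts = pd.DataFrame(0, index=list(FLANK_POSITIONS),
                          columns=list(AMINO_ACIDS))
    totals = pd.Series(0, index=list(FLANK_POSITIONS))
    for flank in flanks:
        if len(flank) != 21:
            raise ValueError(f"flank {flank!r} is not 21 residues")
        for pos, ch in zip(FLANK_POSITIONS, flank):
            if ch == PAD:
                continue
            if ch not in counts.columns:
                raise ValueError(f"invalid residue {ch!r} at position {pos}")
            counts.loc[pos, ch] += 1
            totals.loc[pos] += 1
    return counts, totals


def build_pssm(annotations: pd.DataFrame, flank_of: dict,
               background: BackgroundFreqs, min_sites: int = 20,
               curation_min: int = 2,
               lower_tail_exclusive: bool = False) -> dict:
    """Build a PSSM per kinase from annotated sites.

    ``annotations`` needs (kinase, accession, position, curation_effort);
    ``flank_of`` maps (accession, position) -> 21-mer flank. Sites with
    curation effort strictly above ``curation_min`` qualify; kinases
    with fewer than ``min_sites`` qualifying flanks are skipped. Raises
    if no kinase survives.
    """
    models = {}
    skipped = {}
    kept = annotations[annotations["curation_effort"] > curation_min]
    for kinase, grp in kept.groupby("kinase"):
        flanks = [flank_of[(a, p)] for a, p in
                  zip(grp["accession"], grp["position"])
                  if (a, p) in flank_of]
        if len(flanks) < min_sites:
            skipped[kinase] = len(flanks)
            continue
        counts, totals = count_matrix(flanks)
        scores = pd.DataFrame(
            [[residue_score(int(counts.loc[pos, aa]), int(totals.loc[pos]),
                            float(background.freq[aa]),
                            lower_tail_exclusive=lower_tail_exclusive)
              if totals.loc[pos] > 0 else 0.0
              for aa in AMINO_ACIDS]
             for pos in FLANK_POSITIONS],
            index=list(FLANK_POSITIONS), columns=list(AMINO_ACIDS))
        models[kinase] = PssmModel(kinase=kinase, scores=scores,
                                   n_training_sites=len(flanks),
                                   background=background)
    if not models:
        raise ValueError(f"no kinase passed the filters; site counts after "
                         f"curation filter: {skipped}")
    if skipped:
        logger.info("kinases skipped (too few sites): %s", skipped)
    return models


def score_site(flank: str, model: PssmModel) -> float:
    """Raw PSSM score S = sum of matrix entries over the flank."""
    if len(flank) != 21:
        raise ValueError(f"flank {flank!r} is not 21 residues")
    total = 0.0
    for pos, ch in zip(FLANK_POSITIONS, flank):
        if ch == PAD:
            continue
        if ch not in model.scores.columns:
            raise ValueError(f"invalid residue {ch!r} at position {pos}")
        total += float(model.scores.loc[pos, ch])
    return total


def score_sites(flanks, model: PssmModel) -> np.ndarray:
    return np.array([score_site(f, model) for f in flanks])


def _downsample_balance(scores, labels, rng) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    n_pos, n_neg = labels.sum(), (~labels).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for calibration")
    minority = min(n_pos, n_neg)
    keep = np.zeros(len(labels), dtype=bool)
    for cls in (True, False):
        idx = np.where(labels == cls)[0]
        if len(idx) > minority:
            idx = rng.choice(idx, size=minority, replace=False)
        keep[idx] = True
    return scores[keep], labels[keep]


def calibrate_logistic(scores, labels, test_fraction: float = 0.2,
                       seed: int = 0, c_reg: float = 100.0) -> dict:
    """Fit the logistic calibration P(S) = 1/(1 + e^-(b0 + b1 S)).

    Splits sites 80/20 (stratified, seeded), down-samples the training
    majority class to balance, and fits a lightly L2-penalized logistic
    regression (penalty keeps separable fits finite). Returns beta0,
    beta1 and held-out test metrics (AUC on calibrated probabilities).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise ValueError("both classes required for calibration")
    rng = np.random.default_rng(seed)
    # stratified shuffle split
    test_mask = np.zeros(len(labels), dtype=bool)
    for cls in (True, False):
        idx = np.where(labels == cls)[0]
        rng.shuffle(idx)
        n_test = max(1, int(round(test_fraction * len(idx))))
        test_mask[idx[:n_test]] = True
    s_train, y_train = _downsample_balance(scores[~test_mask],
                                           labels[~test_mask], rng)
    clf = LogisticRegression(C=c_reg, solver="lbfgs", max_iter=5000)
    clf.fit(s_train[:, None], y_train)
    beta0 = float(clf.intercept_[0])
    beta1 = float(clf.coef_[0, 0])
    prob_test = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * scores[test_mask])))
    test_auc = (roc_auc_score(labels[test_mask], prob_test)
                if 0 < labels[test_mask].sum() < test_mask.sum() else np.nan)
    return {"beta0": beta0, "beta1": beta1, "test_auc": float(test_auc),
            "test_mask": test_mask,
            "n_train_balanced": int(len(y_train))}


def roc_analysis(probabilities, labels) -> dict:
    """ROC AUC (rank formulation) and Youden's-J probability cutoff.

    Ties in J are broken toward the higher threshold (higher
    specificity). Raises when only one class is present.
    """
    labels = np.asarray(labels, dtype=bool)
    probabilities = np.asarray(probabilities, dtype=float)
    if labels.all() or (~labels).all():
        raise ValueError("both classes required for ROC analysis")
    auc = float(roc_auc_score(labels, probabilities))
    fpr, tpr, thresholds = roc_curve(labels, probabilities)
    j = tpr - fpr
    # roc_curve thresholds are decreasing; among ties pick the largest
    best = int(np.argmax(j))
    cutoff = float(min(thresholds[best], 1.0))
    return {"auc": auc, "cutoff": cutoff, "fpr": fpr, "tpr": tpr,
            "thresholds": thresholds, "youden_j": float(j[best])}


def calibrate_models(models: dict, positive_flanks: dict,
                     negative_flanks: list, seed: int = 0) -> dict:
    """Calibrate every PSSM against a shared decoy flank pool.

    ``positive_flanks`` maps kinase -> list of substrate flanks;
    ``negative_flanks`` is the decoy pool. Sets beta0/beta1/cutoff/auc
    on each model in place and returns the models dict.
    """
    rng = np.random.default_rng(seed)
    for kinase, model in models.items():
        pos = positive_flanks.get(kinase, [])
        if not pos:
            raise ValueError(f"{kinase}: no positive flanks for calibration")
        flanks = list(pos) + list(negative_flanks)
        labels = np.r_[np.ones(len(pos), bool),
                       np.zeros(len(negative_flanks), bool)]
        raw = score_sites(flanks, model)
        cal = calibrate_logistic(raw, labels,
                                 seed=int(rng.integers(2 ** 31)))
        model.beta0, model.beta1 = cal["beta0"], cal["beta1"]
        probs = model.calibrated_probability(raw[cal["test_mask"]])
        roc = roc_analysis(probs, labels[cal["test_mask"]])
        model.cutoff = roc["cutoff"]
        model.auc = roc["auc"]
        model.extra["n_test"] = int(cal["test_mask"].sum())
    return models
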
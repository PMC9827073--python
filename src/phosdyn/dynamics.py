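"""Phosphorylation dynamics: fuzzy c-means clustering and
Michaelis-Menten kinetics.

Peptide-wise-scaled time profiles are soft-clustered with fuzzy
c-means (FCM): memberships u_ij and centroids c_j are updated
alternately,

    u_ij = 1 / sum_k (d_ij / d_ik)^(2/(m-1)),
    c_j  = sum_i u_ij^m x_i / sum_i u_ij^m,

with Euclidean distances d and fuzzifier m > 1, until the maximum
centroid shift falls below a tolerance. The objective
J = sum u^m d^2 is non-increasing across iterations.

Increasing clusters (and individual sites) are then modeled with the
Michaelis-Menten saturation curve y = Vm * x / (K + x), fitted by
nonlinear least squares from several starting half-times; "fast" and
"slow" dynamics are the increasing clusters with the smallest and
largest fitted K.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class FcmResult:
    """Fuzzy c-means output: centroids, soft memberships, parameters."""

    centroids: pd.DataFrame          # clusters x timepoints
    membership: pd.DataFrame         # features x clusters, rows sum to 1
    params: dict = field(default_factory=dict)
    objective_path: list = field(default_factory=list)

    @property
    def hard_assignment(self) -> pd.Series:
        return self.membership.idxmax(axis=1).rename("cluster")


def _fcm_membership(dist_sq: np.ndarray, m: float) -> np.ndarray:
    """u_ij from squared distances; exact singleton membership at d=0."""
    u = np.zeros_like(dist_sq)
    zero = dist_sq <= _EPS
    any_zero = zero.any(axis=1)
    power = dist_sq[~any_zero] ** (-1.0 / (m - 1.0))
    u[~any_zero] = power / power.sum(axis=1, keepdims=True)
    if any_zero.any():
        rows = np.where(any_zero)[0]
        u[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
    return u


def fcm_cluster(profiles: pd.DataFrame, n_clusters: int = 8,
                fuzzifier: float = 2.0, tol: float = 1e-6,
                max_iter: int = 200, seed: int = 0,
                n_init: int = 10) -> FcmResult:
    """Fuzzy c-means on a features x timepoints profile matrix.

    Runs ``n_init`` restarts (seeds forked from ``seed``) and keeps
    the solution with the lowest final objective; deterministic given
    the seed. Raises if the objective ever increases (it cannot, up to
    round-off, for a correct implementation).
    """
    root = np.random.SeedSequence(seed)
    best = None
    for child in root.spawn(max(n_init, 1)):
        sub = int(child.generate_state(1)[0] % (2 ** 31))
        res = _fcm_single(profiles, n_clusters, fuzzifier, tol, max_iter,
                          sub)
        if best is None or res.objective_path[-1] \
                < best.objective_path[-1]:
            best = res
    best.params.update({"seed": seed, "n_init": n_init})
    return best


def _fcm_single(profiles: pd.DataFrame, n_clusters: int,
                fuzzifier: float, tol: float, max_iter: int,
                seed: int) -> FcmResult:
    """One FCM run from a k-means++-style seeded initialization
    (first centroid at random, the rest with probability proportional
    to squared distance from the nearest chosen centroid)."""
    if fuzzifier <= 1:
        raise ValueError("fuzzifier must be > 1")
    x = profiles.to_numpy(dtype=float)
    n, _ = x.shape
    if n_clusters < 2 or n_clusters > n:
        raise ValueError(f"n_clusters must be in [2, {n}]")
    rng = np.random.default_rng(seed)
    chosen = [int(rng.integers(n))]
    d2 = ((x - x[chosen[0]]) ** 2).sum(axis=1)
    for _ in range(n_clusters - 1):
        probs = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
        nxt = int(rng.choice(n, p=probs))
        chosen.append(nxt)
        d2 = np.minimum(d2, ((x - x[nxt]) ** 2).sum(axis=1))
    centroids = x[chosen].copy()
    # nudge duplicate initial centroids apart
    centroids += 1e-9 * rng.standard_normal(centroids.shape)

    objective_path = []
    for _ in range(max_iter):
        dist_sq = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        u = _fcm_membership(dist_sq, fuzzifier)
        um = u ** fuzzifier
        objective_path.append(float((um * dist_sq).sum()))
        new_centroids = (um.T @ x) / um.sum(axis=0)[:, None]
        shift = np.abs(new_centroids - centroids).max()
        centroids = new_centroids
        if shift < tol:
            break
    dist_sq = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    u = _fcm_membership(dist_sq, fuzzifier)
    objective_path.append(float((u ** fuzzifier * dist_sq).sum()))
    if any(b > a + 1e-8 * max(a, 1.0)
           for a, b in zip(objective_path, objective_path[1:])):
        raise RuntimeError("FCM objective increased; implementation error")

    clusters = [f"cluster_{j + 1}" for j in range(n_clusters)]
    return FcmResult(
        centroids=pd.DataFrame(centroids, index=clusters,
                               columns=profiles.columns),
        membership=pd.DataFrame(u, index=profiles.index, columns=clusters),
        params={"n_clusters": n_clusters, "fuzzifier": fuzzifier,
                "tol": tol, "max_iter": max_iter, "seed": seed},
        objective_path=objective_path)


@dataclass
class MmFit:
    """Michaelis-Menten fit y = Vm * x / (K + x); straight-line fallback."""

    Vm: float
    K: float
    converged: bool
    rss: float
    fallback: str | None = None     # "line" when the MM fit failed
    slope: float | None = None      # fallback line parameters
    intercept: float | None = None

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        if self.fallback == "line":
            return self.intercept + self.slope * x
        return self.Vm * x / (self.K + x)


def michaelis_menten(x, vm, k):
    return vm * x / (k + x)


def fit_michaelis_menten(time, values,
                         k_starts=(5.0, 20.0, 60.0, 200.0)) -> MmFit:
    """Nonlinear least-squares MM fit with multiple K starting values.

    ``time`` in minutes must include >= 3 distinct points with t = 0;
    values should be min-shifted so the curve can start near zero. If
    no start converges (or the response is constant) a straight line is
    fitted instead and flagged.
    """
    x = np.asarray(time, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(x) != len(y):
        raise ValueError("time and value lengths differ")
    if len(np.unique(x)) < 3:
        raise ValueError("need >=3 distinct time points")
    if 0 not in np.unique(x):
        raise ValueError("time grid must include 0")

    def line_fallback() -> MmFit:
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (intercept + slope * x)
        return MmFit(Vm=np.nan, K=np.nan, converged=False,
                     rss=float(resid @ resid), fallback="line",
                     slope=float(slope), intercept=float(intercept))

    if np.ptp(y) == 0:
        return line_fallback()
    vm0 = float(y.max()) if y.max() > 0 else 1.0
    best = None
    for k0 in k_starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(michaelis_menten, x, y, p0=(vm0, k0),
                                    bounds=([-np.inf, 1e-6], [np.inf, np.inf]),
                                    maxfev=10000)
        except RuntimeError:
            continue
        resid = y - michaelis_menten(x, *popt)
        rss = float(resid @ resid)
        if best is None or rss < best.rss:
            best = MmFit(Vm=float(popt[0]), K=float(popt[1]),
                         converged=True, rss=rss)
    return best if best is not None else line_fallback()


def fit_clusters(profiles: pd.DataFrame, times: np.ndarray,
                 fcm: FcmResult, mode: str = "pooled") -> dict:
    """MM fit per cluster, after min-shifting so each series starts at 0.

    ``mode="pooled"`` fits all member profiles' (time, value) points
    jointly (members by hard assignment); ``"centroid"`` fits the
    cluster centroid only.
    """
    if mode not in ("pooled", "centroid"):
        raise ValueError("mode must be 'pooled' or 'centroid'")
    times = np.asarray(times, dtype=float)
    hard = fcm.hard_assignment
    fits = {}
    for cluster in fcm.centroids.index:
        if mode == "centroid":
            y = fcm.centroids.loc[cluster].to_numpy()
            y = y - y.min()
            fits[cluster] = fit_michaelis_menten(times, y)
        else:
            members = hard.index[hard == cluster]
            if len(members) == 0:
                centroid = fcm.centroids.loc[cluster].to_numpy()
                fits[cluster] = fit_michaelis_menten(
                    times, centroid - centroid.min())
                continue
            block = profiles.loc[members].to_numpy()
            block = block - block.min(axis=1, keepdims=True)
            xx = np.tile(times, len(members))
            fits[cluster] = fit_michaelis_menten(xx, block.ravel())
    return fits


def label_dynamic_clusters(fcm: FcmResult, fits: dict) -> dict:
    """Identify the fast/slow increasing clusters and decreasing ones.

    Increasing clusters have positive net centroid change (last minus
    first time point); among those with converged MM fits, "fast" has
    the smallest half-time K and "slow" the largest (ties broken toward
    larger Vm). Returns {fast, slow, increasing_set, decreasing_set}.
    """
    net = (fcm.centroids.iloc[:, -1] - fcm.centroids.iloc[:, 0])
    increasing = [c for c in fcm.centroids.index if net.loc[c] > 0]
    decreasing = [c for c in fcm.centroids.index if net.loc[c] < 0]
    converged = [c for c in increasing
                 if c in fits and fits[c].converged]
    if len(converged) < 2:
        warnings.warn("fewer than 2 increasing clusters with converged "
                      "kinetic fits; partial labeling")
    fast = slow = None
    if len(converged) == 1:
        fast = converged[0]
    elif converged:
        # tie-break on K by larger Vm (more pronounced activation)
        fast = min(converged, key=lambda c: (fits[c].K, -fits[c].Vm))
        slow = max(converged, key=lambda c: (fits[c].K, fits[c].Vm))
    return {"fast": fast, "slow": slow,
            "increasing_set": increasing, "decreasing_set": decreasing}


def mean_time_profiles(scaled: pd.DataFrame,
                       sample_meta: pd.DataFrame) -> pd.DataFrame:
    """Collapse scaled sample columns to per-time-point means."""
    times = sample_meta.loc[scaled.columns, "time_min"]
    return scaled.T.groupby(times.to_numpy()).mean().T.sort_index(axis=1)
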
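"""K-means cluster-number selection and the two-level waveform hierarchy.

Two criteria choose the number of clusters K:

* the elbow of the within-cluster sum of squares (WCSS) curve
  S_K = sum_j sum_{x in C_j} ||x - mu_j||^2, reported normalised by S_1
  and operationalised as the K of maximum discrete curvature
  (second difference) of the normalised curve; and
* the distortion-ratio density function

      f(K) = S_K / (alpha_K * S_{K-1})   (f(1) = 1; f(K) = 1 if S_{K-1} = 0)
      alpha_2 = 1 - 3/(4 N_d),  alpha_K = alpha_{K-1} + (1 - alpha_{K-1})/6

  with N_d the feature dimension; K is the argmin of f, falling back to
  K = 1 when min f(K) >= 0.85 (f stays close to 1 on uniform data).

The two-level hierarchy first clusters standardized one-channel features
(TPW, REP) — the cluster with the smaller mean TPW is FS, the other RS —
then, within each class, clusters standardized multi-channel features
(1/V_below, 1/V_above) into sub-clusters.  Sub-cluster names are canonical:
FS sub-clusters are ordered by ascending mean symmetry index (FS1 the most
symmetric) and RS sub-clusters by ascending mean |1/V_below|.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .errors import ParameterError

__all__ = [
    "ClusterSolution",
    "KSelection",
    "KSelectingKMeans",
    "TwoLevelWaveformClusterer",
    "wcss_curve",
    "density_fk",
    "select_k",
    "alpha_weights",
]


def wcss_curve(
    X: np.ndarray,
    k_max: int,
    n_restarts: int = 1000,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, list]:
    """Best-of-restarts K-means distortions for K = 1..k_max.

    Returns ``(s, s_norm, labels)`` where ``s[K-1]`` is the raw WCSS S_K,
    ``s_norm`` the curve normalised by S_1, and ``labels[K-1]`` the best
    partition found for K.  K values exceeding the number of distinct
    points are skipped (NaN) with a warning.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ParameterError("features must be finite")
    n = X.shape[0]
    if n <= k_max:
        raise ParameterError("need more points than k_max")
    n_distinct = np.unique(X, axis=0).shape[0]

    s = np.full(k_max, np.nan)
    labels: list = [None] * k_max
    mu = X.mean(axis=0)
    s[0] = float(np.sum((X - mu) ** 2))
    labels[0] = np.zeros(n, dtype=int)
    for k in range(2, k_max + 1):
        if n_distinct < k:
            warnings.warn(f"K={k} skipped: only {n_distinct} distinct points")
            continue
        km = KMeans(
            n_clusters=k,
            init="random",
            n_init=n_restarts,
            random_state=None if seed is None else seed + k,
        ).fit(X)
        s[k - 1] = float(km.inertia_)
        labels[k - 1] = km.labels_
    s_norm = s / s[0] if s[0] > 0 else s
    return s, s_norm, labels


def alpha_weights(k_max: int, n_d: int) -> np.ndarray:
    """Recursion weights alpha_K for K = 1..k_max (alpha_1 unused, NaN)."""
    if n_d <= 1:
        raise ParameterError("density function requires feature dimension > 1")
    a = np.full(k_max, np.nan)
    if k_max >= 2:
        a[1] = 1.0 - 3.0 / (4.0 * n_d)
    for k in range(3, k_max + 1):
        a[k - 1] = a[k - 2] + (1.0 - a[k - 2]) / 6.0
    return a


def density_fk(s: np.ndarray, n_d: int) -> np.ndarray:
    """Density function f(K) from the distortion sequence S_1..S_Kmax."""
    s = np.asarray(s, dtype=float)
    k_max = s.size
    a = alpha_weights(k_max, n_d)
    f = np.ones(k_max)
    for k in range(2, k_max + 1):
        prev = s[k - 2]
        if np.isnan(s[k - 1]) or np.isnan(prev):
            f[k - 1] = np.nan
        elif prev != 0:
            f[k - 1] = s[k - 1] / (a[k - 1] * prev)
        else:
            f[k - 1] = 1.0
    return f


@dataclass
class KSelection:
    k: int | None
    method: str
    elbow_k: int | None = None
    density_k: int | None = None
    agreed: bool | None = None


def _elbow_k(wcss_norm: np.ndarray) -> int:
    # discrete curvature: S_{K-1} - 2 S_K + S_{K+1}, defined for interior K
    s = np.asarray(wcss_norm, dtype=float)
    curv = s[:-2] - 2 * s[1:-1] + s[2:]
    # ties broken toward smaller K (argmax returns the first maximum)
    return int(np.nanargmax(curv)) + 2


def _density_k(fk: np.ndarray, fallback: float) -> int:
    f = np.asarray(fk, dtype=float)
    sub = f[1:]
    if np.all(np.isnan(sub)):
        return 1
    kmin = int(np.nanargmin(sub)) + 2
    if f[kmin - 1] >= fallback:
        return 1
    return kmin


def select_k(
    wcss_norm: np.ndarray,
    fk: np.ndarray,
    method: str = "density",
    fallback_threshold: float = 0.85,
) -> KSelection:
    """Select the number of clusters from the two criteria.

    ``density``: argmin f(K) over K >= 2, falling back to K = 1 when the
    minimum is >= ``fallback_threshold``.  ``elbow``: K of maximum discrete
    curvature of the normalised WCSS curve.  ``joint``: both must agree;
    disagreement is returned explicitly (k = None, agreed = False).
    """
    if len(wcss_norm) != len(fk) or len(fk) < 3:
        raise ParameterError("curves must have equal length >= 3")
    if method == "elbow":
        return KSelection(k=_elbow_k(wcss_norm), method=method)
    if method == "density":
        return KSelection(k=_density_k(fk, fallback_threshold), method=method)
    if method == "joint":
        ke = _elbow_k(wcss_norm)
        kd = _density_k(fk, fallback_threshold)
        agreed = ke == kd
        return KSelection(
            k=ke if agreed else None, method=method,
            elbow_k=ke, density_k=kd, agreed=agreed,
        )
    raise ParameterError(f"unknown selection method {method!r}")


@dataclass
class ClusterSolution:
    k_selected: int
    labels: np.ndarray
    centroids: np.ndarray
    wcss_curve: np.ndarray  # S_K / S_1
    fk_curve: np.ndarray
    selection: KSelection
    n_restarts: int
    seed: int | None


class KSelectingKMeans(BaseEstimator, ClusterMixin):
    """K-means whose K is chosen by the WCSS-elbow and/or f(K) criteria.

    Parameters
    ----------
    k_max : int
        Largest K evaluated.
    n_restarts : int
        Random initialisations per K; the best (lowest-WCSS) partition is
        kept.
    method : {"density", "elbow", "joint"}
        Cluster-number criterion; "joint" requires both to agree.
    standardize : bool
        Z-score each feature before clustering.
    fallback_threshold : float
        min f(K) >= this value selects K = 1.
    random_state : int or None
    """

    def __init__(
        self,
        k_max: int = 6,
        n_restarts: int = 1000,
        method: str = "density",
        standardize: bool = True,
        fallback_threshold: float = 0.85,
        random_state: int | None = None,
    ):
        self.k_max = k_max
        self.n_restarts = n_restarts
        self.method = method
        self.standardize = standardize
        self.fallback_threshold = fallback_threshold
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ParameterError("X must be 2-D")
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            sd = X.std(axis=0, ddof=0)
            self.scale_ = np.where(sd > 0, sd, 1.0)
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        Z = (X - self.mean_) / self.scale_

        s, s_norm, labels = wcss_curve(
            Z, self.k_max, n_restarts=self.n_restarts, seed=self.random_state
        )
        fk = density_fk(s, n_d=X.shape[1])
        sel = select_k(s_norm, fk, self.method, self.fallback_threshold)
        if sel.k is None:
            raise ParameterError(
                f"joint selection disagrees: elbow={sel.elbow_k}, density={sel.density_k}"
            )
        self.k_ = sel.k
        self.labels_ = labels[sel.k - 1]
        self.wcss_curve_ = s_norm
        self.wcss_raw_ = s
        self.fk_curve_ = fk
        self.selection_ = sel
        self.centroids_ = np.vstack(
            [Z[self.labels_ == j].mean(axis=0) for j in range(sel.k)]
        ) * self.scale_ + self.mean_
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def solution(self) -> ClusterSolution:
        return ClusterSolution(
            k_selected=self.k_,
            labels=self.labels_,
            centroids=self.centroids_,
            wcss_curve=self.wcss_curve_,
            fk_curve=self.fk_curve_,
            selection=self.selection_,
            n_restarts=self.n_restarts,
            seed=self.random_state,
        )


class TwoLevelWaveformClusterer(BaseEstimator):
    """Two-level clustering: one-channel FS/RS, then multi-channel sub-clusters.

    ``fit`` expects a DataFrame with columns ``tpw``, ``rep``,
    ``inv_v_below``, ``inv_v_above`` and ``symmetry_index``.  Units with
    undefined (NaN) multi-channel features are excluded from level 2 and
    flagged in ``excluded_level2_``.

    Fitted attributes: ``level1_labels_`` ('FS'/'RS' per unit),
    ``level2_labels_`` ('FS1'.., 'RS1'.., or None), ``level1_solution_``,
    ``level2_solutions_`` (dict per class).
    """

    LEVEL1_FEATURES = ("tpw", "rep")
    LEVEL2_FEATURES = ("inv_v_below", "inv_v_above")

    def __init__(
        self,
        k_max: int = 6,
        n_restarts: int = 1000,
        method_level1: str = "density",
        method_level2: str = "density",
        standardize: bool = True,
        fallback_threshold: float = 0.85,
        random_state: int | None = None,
    ):
        self.k_max = k_max
        self.n_restarts = n_restarts
        self.method_level1 = method_level1
        self.method_level2 = method_level2
        self.standardize = standardize
        self.fallback_threshold = fallback_threshold
        self.random_state = random_state

    def _km(self, method: str, seed_offset: int) -> KSelectingKMeans:
        rs = None if self.random_state is None else self.random_state + seed_offset
        return KSelectingKMeans(
            k_max=self.k_max,
            n_restarts=self.n_restarts,
            method=method,
            standardize=self.standardize,
            fallback_threshold=self.fallback_threshold,
            random_state=rs,
        )

    def fit(self, features: pd.DataFrame, y=None):
        df = features
        for col in self.LEVEL1_FEATURES:
            if col not in df.columns:
                raise ParameterError(f"missing feature column {col!r}")
        X1 = df.loc[:, list(self.LEVEL1_FEATURES)].to_numpy(dtype=float)
        if not np.all(np.isfinite(X1)):
            raise ParameterError("one-channel features must be finite for all units")

        km1 = self._km(self.method_level1, 0).fit(X1)
        self.level1_solution_ = km1.solution()
        # name clusters by ascending mean TPW: the narrowest is FS
        order = np.argsort(
            [X1[km1.labels_ == j, 0].mean() for j in range(km1.k_)]
        )
        if km1.k_ == 2:
            names = ["FS", "RS"]
        else:
            names = [f"C{i + 1}" for i in range(km1.k_)]
        name_of = {int(cl): names[rank] for rank, cl in enumerate(order)}
        level1 = np.array([name_of[int(l)] for l in km1.labels_], dtype=object)
        self.level1_labels_ = level1

        X2 = df.loc[:, list(self.LEVEL2_FEATURES)].to_numpy(dtype=float)
        finite2 = np.all(np.isfinite(X2), axis=1)
        self.excluded_level2_ = ~finite2
        level2 = np.full(len(df), None, dtype=object)
        self.level2_solutions_ = {}
        for off, cls in enumerate(sorted(set(level1.tolist()))):
            mask = (level1 == cls) & finite2
            if mask.sum() <= self.k_max:
                warnings.warn(f"class {cls}: too few units for level-2 clustering")
                continue
            km2 = self._km(self.method_level2, 100 + off).fit(X2[mask])
            self.level2_solutions_[cls] = km2.solution()
            sub = km2.labels_
            if cls == "FS":
                # FS1 = most symmetric: ascending mean symmetry index
                si = df.loc[mask, "symmetry_index"].to_numpy(dtype=float)
                keys = [si[sub == j].mean() for j in range(km2.k_)]
            else:
                # RS ordered by ascending mean |1/V_below|
                below = np.abs(X2[mask, 0])
                keys = [below[sub == j].mean() for j in range(km2.k_)]
            order2 = np.argsort(keys)
            sub_name = {int(cl): f"{cls}{rank + 1}" for rank, cl in enumerate(order2)}
            level2[np.flatnonzero(mask)] = [sub_name[int(l)] for l in sub]
        self.level2_labels_ = level2
        return self


def hierarchical_cluster(
    features: pd.DataFrame, **config
) -> tuple[np.ndarray, np.ndarray]:
    """Functional wrapper around :class:`TwoLevelWaveformClusterer`."""
    model = TwoLevelWaveformClusterer(**config).fit(features)
    return model.level1_labels_, model.level2_labels_
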
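"""Fuzzy C-means clustering of voxel intensities and enhancing-class selection.

The initial uterus candidate is obtained by unsupervised fuzzy C-means
(FCM) clustering of the contrast-enhanced T1W intensities into ``c``
classes (default 3, fuzzifier ``m = 2``).  Gadolinium-perfused uterine
tissue enhances strongly, so the candidate is the class with the
brightest prototype (class centre).

:class:`FuzzyCMeans` is a scikit-learn compatible estimator; the
module-level :func:`fcm_cluster` / :func:`select_enhanced_class`
functions wrap it with the pipeline's volume/mask containers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils import check_random_state
from sklearn.utils.validation import check_array, check_is_fitted

from .core import BinaryMask, DegenerateInputError, IntensityVolume, PipelineConfig

__all__ = [
    "FuzzyCMeans",
    "MembershipMatrix",
    "ClusterModel",
    "fcm_cluster",
    "select_enhanced_class",
]


def _memberships(X: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    """Membership update u_ik = 1 / sum_j (d_ik / d_jk)^(2/(m-1)).

    Samples coinciding with a centre get crisp membership in that class
    (the limit of the formula); coincident centres tie-break to the
    lowest centre index.  Returns an (n_samples, c) row-stochastic array.
    """
    d = np.linalg.norm(X[:, None, :] - centers[None, :, :], axis=2)  # (n, c)
    zero_rows = np.min(d, axis=1) == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d ** (-2.0 / (m - 1.0))
        U = inv / np.sum(inv, axis=1, keepdims=True)
    if np.any(zero_rows):
        U[zero_rows] = 0.0
        hit = np.argmax(d[zero_rows] == 0.0, axis=1)  # first zero-distance centre
        U[np.flatnonzero(zero_rows), hit] = 1.0
    return U


def _objective(X, centers, U, m) -> float:
    d2 = np.sum((X[:, None, :] - centers[None, :, :]) ** 2, axis=2)
    return float(np.sum((U**m) * d2))


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Fuzzy C-means clustering (Bezdek's alternating optimization).

    Minimizes ``J_m = sum_i sum_k u_ik^m ||x_k - v_i||^2`` subject to
    column-stochastic memberships, by alternating the membership and
    centre updates until the largest centre shift drops below ``tol``.

    Parameters
    ----------
    n_clusters : int, default=3
        Number of classes ``c``.
    m : float, default=2.0
        Fuzzifier; must be > 1.  ``m -> 1`` approaches hard k-means.
    tol : float, default=1e-5
        Convergence threshold on the max absolute centre shift.
    max_iter : int, default=300
        Iteration cap.
    init : {"quantile", "random"}, default="quantile"
        ``"quantile"`` places initial centres at the (2i+1)/(2c)
        intensity quantiles (deterministic, ordered — only for 1-D
        features); ``"random"`` samples distinct training points.
    random_state : int, RandomState or None
        Seed for ``init="random"``.

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (n_clusters, n_features)
    memberships_ : ndarray of shape (n_samples, n_clusters)
        Row-stochastic membership degrees of the training data.
    labels_ : ndarray of shape (n_samples,)
        Hard (max-membership) labels of the training data.
    objective_trace_ : ndarray
        ``J_m`` after each alternating step; non-increasing.
    n_iter_ : int
    converged_ : bool
    """

    def __init__(
        self,
        n_clusters: int = 3,
        m: float = 2.0,
        tol: float = 1e-5,
        max_iter: int = 300,
        init: str = "quantile",
        random_state=None,
    ):
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.init = init
        self.random_state = random_state

    def _init_centers(self, X: np.ndarray, rng) -> np.ndarray:
        c = self.n_clusters
        if self.init == "quantile":
            if X.shape[1] != 1:
                raise ValueError("quantile init requires 1-D features")
            qs = (2 * np.arange(c) + 1) / (2 * c)
            centers = np.quantile(X[:, 0], qs)[:, None]
            # quantiles of clumped data may coincide; fall back to
            # evenly spaced distinct values
            if len(np.unique(centers)) < c:
                uniq = np.unique(X[:, 0])
                idx = np.linspace(0, len(uniq) - 1, c).round().astype(int)
                centers = uniq[idx][:, None]
            return centers.astype(float)
        if self.init == "random":
            uniq = np.unique(X, axis=0)
            pick = rng.choice(len(uniq), size=c, replace=False)
            return uniq[pick].astype(float)
        raise ValueError(f"unknown init {self.init!r}")

    def fit(self, X, y=None):
        if self.n_clusters < 2:
            raise ValueError(f"n_clusters must be >= 2, got {self.n_clusters}")
        if self.m <= 1:
            raise ValueError(f"fuzzifier m must be > 1, got {self.m}")
        X = check_array(X, ensure_2d=False, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        if len(np.unique(X, axis=0)) < self.n_clusters:
            raise DegenerateInputError(
                f"need >= {self.n_clusters} distinct samples to form "
                f"{self.n_clusters} clusters"
            )
        rng = check_random_state(self.random_state)
        centers = self._init_centers(X, rng)

        trace = []
        n_iter = 0
        converged = False
        for n_iter in range(1, self.max_iter + 1):
            U = _memberships(X, centers, self.m)
            w = U**self.m
            new_centers = (w.T @ X) / np.sum(w, axis=0)[:, None]
            trace.append(_objective(X, new_centers, U, self.m))
            shift = float(np.max(np.abs(new_centers - centers)))
            centers = new_centers
            if shift < self.tol:
                converged = True
                break
        # final membership update so U is consistent with the final centres
        U = _memberships(X, centers, self.m)
        trace.append(_objective(X, centers, U, self.m))

        if len(np.unique(np.round(centers, 9), axis=0)) < self.n_clusters:
            warnings.warn(
                "coincident cluster centres at convergence; "
                "ties broken by centre index",
                stacklevel=2,
            )
        self.cluster_centers_ = centers
        self.memberships_ = U
        self.labels_ = np.argmax(U, axis=1)
        self.objective_trace_ = np.asarray(trace)
        self.n_iter_ = n_iter
        self.converged_ = converged
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "cluster_centers_")
        X = check_array(X, ensure_2d=False, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        return _memberships(X, self.cluster_centers_, self.m)

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)


# ---------------------------------------------------------------------------
# pipeline-facing wrappers


@dataclass(frozen=True)
class MembershipMatrix:
    """FCM membership degrees as a (c x n) column-stochastic matrix.

    Column ``k`` corresponds to the voxel ``np.unravel_index(k,
    grid_shape)`` (C order), so masks can be reshaped straight back onto
    the image grid.
    """

    U: np.ndarray  # (c, n)
    grid_shape: tuple[int, int, int]

    def __post_init__(self):
        if self.U.shape[1] != int(np.prod(self.grid_shape)):
            raise ValueError("membership columns do not match grid size")


@dataclass(frozen=True)
class ClusterModel:
    """Converged FCM state: centres, hyper-parameters and trace."""

    V: np.ndarray  # (c,) class-centre intensities, original units
    c: int
    m: float
    objective_trace: np.ndarray
    n_iter: int
    converged: bool


def fcm_cluster(
    volume: IntensityVolume, config: PipelineConfig
) -> tuple[MembershipMatrix, ClusterModel]:
    """Cluster voxel intensities into ``config.c`` fuzzy classes.

    Intensities are min-max rescaled to [0, 1] before clustering so the
    convergence tolerance is comparable across scanners; the reported
    class centres are mapped back to original intensity units.
    """
    x = volume.data.reshape(-1).astype(np.float64)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise DegenerateInputError("constant-intensity volume cannot be clustered")
    xs = (x - lo) / (hi - lo)
    est = FuzzyCMeans(
        n_clusters=config.c,
        m=config.m,
        tol=config.fcm_tol,
        max_iter=config.fcm_max_iter,
        init=config.fcm_init,
        random_state=config.rng_seed,
    ).fit(xs[:, None])
    centers = est.cluster_centers_[:, 0] * (hi - lo) + lo
    U = est.memberships_.T  # (c, n)
    return (
        MembershipMatrix(U=U, grid_shape=volume.shape),
        ClusterModel(
            V=centers,
            c=config.c,
            m=config.m,
            objective_trace=est.objective_trace_,
            n_iter=est.n_iter_,
            converged=est.converged_,
        ),
    )


def select_enhanced_class(
    U: MembershipMatrix, model: ClusterModel, spacing
) -> BinaryMask:
    """Return the hard-assignment mask of the brightest-centre class.

    Each voxel goes to its maximum-membership class; membership ties are
    broken toward the brighter centre, matching the enhancing-tissue
    reading of the last (brightest) class.
    """
    bright = int(np.argmax(model.V))
    row_max = U.U.max(axis=0)
    mask = (U.U[bright] >= row_max).reshape(U.grid_shape)
    return BinaryMask(data=mask, spacing=spacing)
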
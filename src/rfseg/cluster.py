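"""Robust rough-fuzzy c-means (rRFCM) clustering.

Each cluster beta_i is described by a centroid v_i, a *lower approximation*
(objects certainly in the cluster) and a *boundary region* (objects possibly
shared with other clusters).  Objects in a lower approximation carry
possibilistic (PCM-style) memberships nu — typicalities in (0, 1] that depend
only on the distance to that one centroid and the cluster's scale eta —
while boundary objects carry probabilistic (FCM-style) memberships mu that
sum to one across clusters.  Two data-driven thresholds govern the split:
delta_1 is the average gap between each object's two highest possibilistic
memberships (an object whose own gap exceeds delta_1 is confidently placed in
a lower approximation), and delta_2 is the average top membership of the
remaining, ambiguous objects (a boundary object also joins the boundary of
any other cluster whose membership clears delta_2).

Centroids are the omega-weighted average of the possibilistic lower mean and
the probabilistic boundary mean; with omega near 1 the certain objects
dominate, which is what makes the algorithm robust to noise relative to
plain FCM while avoiding the coincident-cluster failure of plain PCM.

Distances are squared Euclidean throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted, validate_data

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterResult",
    "hcm",
    "fcm_membership",
    "pcm_membership",
    "scale_parameters",
    "thresholds",
    "assign_regions",
    "update_centroids",
    "objective",
    "rrfcm",
    "RobustRoughFuzzyCMeans",
]


def _sq_dist(X: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances, shape (c, n)."""
    return np.maximum(cdist(V, X, metric="sqeuclidean"), 0.0)


# ---------------------------------------------------------------------------
# hard c-means (initialization)
# ---------------------------------------------------------------------------


def hcm(
    X: np.ndarray,
    c: int,
    seed: int | np.random.Generator | None = None,
    max_iter: int = 100,
    tol: float = 1e-5,
) -> np.ndarray:
    """Hard c-means (Lloyd iterations) from c distinct random objects.

    An empty cluster is re-seeded at the object farthest from its nearest
    centroid.  Returns the converged (c, m) centroid array; used to
    initialize the rough-fuzzy clustering.
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    if n < c:
        raise ValueError(f"need at least c={c} objects, got n={n}")
    rng = np.random.default_rng(seed)
    V = X[rng.choice(n, size=c, replace=False)].astype(float).copy()
    for _ in range(max_iter):
        d2 = _sq_dist(X, V)
        labels = d2.argmin(axis=0)
        newV = V.copy()
        nearest = d2.min(axis=0)
        for i in range(c):
            members = labels == i
            if members.any():
                newV[i] = X[members].mean(axis=0)
            else:
                far = int(nearest.argmax())
                newV[i] = X[far]
                logger.debug("empty cluster %d re-seeded at object %d", i, far)
        shift = float(np.abs(newV - V).max())
        V = newV
        if shift < tol:
            break
    return V


# ---------------------------------------------------------------------------
# membership machinery
# ---------------------------------------------------------------------------


def fcm_membership(X: np.ndarray, V: np.ndarray, m1: float = 2.0) -> np.ndarray:
    """Probabilistic (FCM) memberships, shape (c, n); columns sum to one.

    An object coinciding with a centroid gets membership 1 there (lowest
    centroid index on multiple coincidences) and 0 elsewhere.
    """
    X = np.atleast_2d(np.asarray(X, float))
    V = np.atleast_2d(np.asarray(V, float))
    d2 = _sq_dist(X, V)
    mu = np.empty_like(d2)
    zero_cols = (d2 == 0.0).any(axis=0)
    safe = d2[:, ~zero_cols]
    power = 1.0 / (m1 - 1.0)
    # mu_ij = 1 / sum_k (d_ij / d_kj)^power  =  d_ij^-p / sum_k d_kj^-p
    inv = safe ** (-power)
    mu[:, ~zero_cols] = inv / inv.sum(axis=0, keepdims=True)
    if zero_cols.any():
        sub = np.zeros((V.shape[0], int(zero_cols.sum())))
        sub[d2[:, zero_cols].argmin(axis=0), np.arange(sub.shape[1])] = 1.0
        mu[:, zero_cols] = sub
    return mu


def pcm_membership(
    X: np.ndarray, V: np.ndarray, eta: np.ndarray, m2: float = 2.0
) -> np.ndarray:
    """Possibilistic (PCM) memberships, shape (c, n), each in (0, 1].

    nu_ij depends only on the distance of object j to centroid i and the
    cluster's zone of influence eta_i — never on the other centroids.
    """
    eta = np.asarray(eta, float)
    if np.any(eta <= 0):
        raise ValueError(f"scale parameters must be positive, got {eta}")
    d2 = _sq_dist(np.atleast_2d(np.asarray(X, float)), np.atleast_2d(V))
    return 1.0 / (1.0 + (d2 / eta[:, None]) ** (1.0 / (m2 - 1.0)))


def scale_parameters(
    X: np.ndarray,
    V: np.ndarray,
    weights: np.ndarray,
    m2: float = 2.0,
    K: float = 1.0,
) -> np.ndarray:
    """Per-cluster zone of influence eta_i (c values).

    ``eta_i = K * sum_j w_ij^m2 d2_ij / sum_j w_ij^m2`` with the supplied
    membership weights.  At startup the weights are FCM memberships from the
    initial centroids (the possibilistic memberships need eta and vice
    versa); afterwards the possibilistic memberships are used.
    """
    d2 = _sq_dist(np.atleast_2d(np.asarray(X, float)), np.atleast_2d(V))
    w = np.asarray(weights, float) ** m2
    denom = w.sum(axis=1)
    if np.any(denom <= 0):
        raise ValueError("zero membership mass for some cluster")
    return K * (w * d2).sum(axis=1) / denom


def thresholds(nu: np.ndarray) -> tuple[float, float]:
    """Data-driven rough thresholds (delta_1, delta_2) from nu (c, n).

    delta_1 is the mean gap between each object's two highest possibilistic
    memberships; delta_2 is the mean top membership over the objects whose
    gap is <= delta_1 (the objects that land in no lower approximation), or
    0 when every object clears the gap.
    """
    nu = np.asarray(nu, float)
    if nu.shape[0] < 2:
        raise ValueError("thresholds need at least two clusters")
    part = np.sort(nu, axis=0)
    top, second = part[-1], part[-2]
    gap = top - second
    delta1 = float(gap.mean())
    ambiguous = gap <= delta1
    delta2 = float(top[ambiguous].mean()) if ambiguous.any() else 0.0
    return delta1, delta2


def assign_regions(
    nu: np.ndarray, delta1: float, delta2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Split objects into lower approximations and boundary regions.

    Returns ``(lower_label, boundary)`` where ``lower_label[j]`` is the
    cluster whose lower approximation holds object j, or -1 if it is a
    boundary object; ``boundary`` is a (c, n) boolean matrix marking
    boundary membership.  A boundary object belongs to the boundary of its
    argmax cluster plus every other cluster whose membership exceeds
    delta_2.  Ties in the argmax break toward the lowest cluster index.
    """
    nu = np.asarray(nu, float)
    c, n = nu.shape
    best = nu.argmax(axis=0)
    part = np.sort(nu, axis=0)
    gap = part[-1] - part[-2]
    in_lower = gap > delta1

    lower_label = np.where(in_lower, best, -1)
    boundary = np.zeros((c, n), dtype=bool)
    amb = ~in_lower
    boundary[best[amb], np.flatnonzero(amb)] = True
    others = (nu > delta2) & amb[None, :]
    others[best[amb], np.flatnonzero(amb)] = False
    boundary |= others
    return lower_label, boundary


def update_centroids(
    X: np.ndarray,
    nu: np.ndarray,
    mu: np.ndarray,
    lower_label: np.ndarray,
    boundary: np.ndarray,
    prev_V: np.ndarray,
    omega: float = 0.99,
    m1: float = 2.0,
    m2: float = 2.0,
) -> np.ndarray:
    """New centroids as the omega-weighted lower/boundary averages.

    For each cluster: ``v_i = omega*C1 + (1-omega)*D1`` when both its lower
    approximation and boundary are nonempty, where C1 is the nu^m2-weighted
    mean of the lower objects and D1 the mu^m1-weighted mean of the boundary
    objects; C1 alone when the boundary is empty, D1 alone when the lower
    approximation is empty.  A cluster with both empty keeps its previous
    centroid (logged).
    """
    X = np.asarray(X, float)
    c = nu.shape[0]
    V = np.asarray(prev_V, float).copy()
    for i in range(c):
        low = lower_label == i
        bnd = boundary[i]
        C1 = D1 = None
        if low.any():
            w = nu[i, low] ** m2
            C1 = (w[:, None] * X[low]).sum(axis=0) / w.sum()
        if bnd.any():
            w = mu[i, bnd] ** m1
            ws = w.sum()
            if ws > 0:
                D1 = (w[:, None] * X[bnd]).sum(axis=0) / ws
        if C1 is not None and D1 is not None:
            V[i] = omega * C1 + (1.0 - omega) * D1
        elif C1 is not None:
            V[i] = C1
        elif D1 is not None:
            V[i] = D1
        else:
            logger.debug("cluster %d has empty lower and boundary; centroid kept", i)
    return V


def objective(
    X: np.ndarray,
    V: np.ndarray,
    nu: np.ndarray,
    mu: np.ndarray,
    eta: np.ndarray,
    lower_label: np.ndarray,
    boundary: np.ndarray,
    omega: float = 0.99,
    m1: float = 2.0,
    m2: float = 2.0,
) -> float:
    """rRFCM objective J.

    ``J = omega*A1 + (1-omega)*B1`` when both region classes are globally
    nonempty; the bare possibilistic term A1 when no boundary object exists;
    the bare probabilistic term B1 when no lower object exists.
    """
    X = np.asarray(X, float)
    d2 = _sq_dist(X, np.atleast_2d(V))
    c = d2.shape[0]
    A1 = 0.0
    for i in range(c):
        low = lower_label == i
        if low.any():
            A1 += float((nu[i, low] ** m2 * d2[i, low]).sum())
            A1 += float(eta[i] * ((1.0 - nu[i, low]) ** m2).sum())
    B1 = 0.0
    for i in range(c):
        bnd = boundary[i]
        if bnd.any():
            B1 += float((mu[i, bnd] ** m1 * d2[i, bnd]).sum())
    any_lower = bool((lower_label >= 0).any())
    any_boundary = bool(boundary.any())
    if any_lower and any_boundary:
        return omega * A1 + (1.0 - omega) * B1
    if any_lower:
        return A1
    return B1


def _check_state(nu: np.ndarray, mu: np.ndarray, boundary: np.ndarray) -> None:
    """Invariants of the membership algebra, asserted every iteration."""
    assert np.all(nu > 0) and np.all(nu <= 1), "nu out of (0, 1]"
    assert np.all(nu.max(axis=0) > 0), "an object has no positive typicality"
    obj_in_boundary = boundary.any(axis=0)
    if obj_in_boundary.any():
        sums = mu[:, obj_in_boundary].sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-9), "mu does not sum to 1 on boundary"


@dataclass
class ClusterResult:
    """Converged state of the rough-fuzzy clustering."""

    centroids: np.ndarray  # (c, m)
    eta: np.ndarray  # (c,)
    nu: np.ndarray  # (c, n) possibilistic memberships
    mu: np.ndarray  # (c, n) probabilistic memberships (meaningful on boundary)
    delta1: float
    delta2: float
    lower_label: np.ndarray  # (n,) cluster index or -1
    boundary: np.ndarray  # (c, n) bool
    labels: np.ndarray  # (n,) hard labels
    n_iter: int
    objective: float
    objective_trace: list[float] = field(default_factory=list)
    centroid_trace: list[np.ndarray] = field(default_factory=list)

    def report(self) -> dict:
        """JSON-serializable cluster report."""
        return {
            "centroids": self.centroids.tolist(),
            "eta": self.eta.tolist(),
            "delta1": self.delta1,
            "delta2": self.delta2,
            "n_iter": self.n_iter,
            "objective": self.objective,
            "lower_sizes": [
                int((self.lower_label == i).sum()) for i in range(len(self.centroids))
            ],
            "boundary_sizes": [int(b.sum()) for b in self.boundary],
            "objective_trace": list(self.objective_trace),
        }


def _hard_labels(
    nu: np.ndarray, lower_label: np.ndarray, boundary: np.ndarray
) -> np.ndarray:
    """Lower-region cluster if any, else argmax nu among boundary clusters."""
    labels = lower_label.copy()
    amb = lower_label < 0
    if amb.any():
        restricted = np.where(boundary[:, amb], nu[:, amb], -np.inf)
        labels[amb] = restricted.argmax(axis=0)
    return labels


def rrfcm(
    X: np.ndarray,
    c: int,
    m1: float = 2.0,
    m2: float = 2.0,
    omega: float = 0.99,
    K: float = 1.0,
    max_iter: int = 100,
    tol: float = 1e-5,
    seed: int | np.random.Generator | None = None,
    init_centroids: np.ndarray | None = None,
    freeze_eta: bool = False,
    eta_floor: float = 1e-3,
    delta1_override: float | None = None,
    delta2_override: float | None = None,
    record_trace: bool = False,
) -> ClusterResult:
    """Run robust rough-fuzzy c-means.

    Centroids are initialized by hard c-means (or ``init_centroids``); the
    scale parameters eta are bootstrapped from the FCM memberships of the
    initial centroids (the possibilistic memberships need eta and eta needs
    memberships, so the probabilistic ones break the circularity once).
    Each iteration then computes nu, the thresholds delta_1/delta_2, the
    region split, mu on the boundary objects, the new centroids, and a
    refreshed eta.  Iteration stops when the region assignment is unchanged
    and the maximum centroid shift falls below ``tol``, or at ``max_iter``.

    ``delta1_override``/``delta2_override`` pin the thresholds (used to
    study the FCM and PCM limiting regimes); ``freeze_eta`` keeps the
    bootstrap eta for the whole run, as classical PCM would.

    Refitting eta from the possibilistic memberships has a known collapse
    mode: once a centroid locks onto its single nearest object, eta tracks
    the shrinking nearest distance and decays superexponentially to zero.
    ``eta_floor`` guards against it by never letting a refreshed eta_i drop
    below ``eta_floor`` times its bootstrap value.
    """
    X = np.asarray(X, float)
    if X.ndim != 2:
        raise ValueError(f"expected an (n, m) matrix, got shape {X.shape}")
    n = X.shape[0]
    if c < 2:
        raise ValueError(f"need c >= 2 clusters, got {c}")
    if n < c:
        raise ValueError(f"need at least c={c} objects, got n={n}")
    if not 0 < omega <= 1:
        raise ValueError(f"omega must be in (0, 1], got {omega}")
    if m1 <= 1 or m2 <= 1:
        raise ValueError("fuzzifiers m1, m2 must be > 1")

    if init_centroids is None:
        V = hcm(X, c, seed=seed, max_iter=max_iter, tol=tol)
    else:
        V = np.asarray(init_centroids, float).copy()
        if V.shape != (c, X.shape[1]):
            raise ValueError(f"init_centroids shape {V.shape} != {(c, X.shape[1])}")

    eta = scale_parameters(X, V, fcm_membership(X, V, m1), m2=m2, K=K)
    eta = np.maximum(eta, np.finfo(float).tiny)
    eta_min = eta_floor * eta

    prev_lower = prev_boundary = None
    obj_trace: list[float] = []
    V_trace: list[np.ndarray] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        nu = pcm_membership(X, V, eta, m2)
        if delta1_override is None or delta2_override is None:
            d1, d2 = thresholds(nu)
        else:
            d1 = d2 = 0.0
        if delta1_override is not None:
            d1 = delta1_override
        if delta2_override is not None:
            d2 = delta2_override
        lower_label, boundary = assign_regions(nu, d1, d2)
        mu = fcm_membership(X, V, m1)
        _check_state(nu, mu, boundary)
        newV = update_centroids(
            X, nu, mu, lower_label, boundary, V, omega=omega, m1=m1, m2=m2
        )
        shift = float(np.abs(newV - V).max())
        V = newV
        if not freeze_eta:
            eta = scale_parameters(X, V, nu, m2=m2, K=K)
            eta = np.maximum(eta, eta_min)
        if record_trace:
            V_trace.append(V.copy())
        obj_trace.append(
            objective(X, V, nu, mu, eta, lower_label, boundary, omega, m1, m2)
        )
        regions_stable = (
            prev_lower is not None
            and np.array_equal(lower_label, prev_lower)
            and np.array_equal(boundary, prev_boundary)
        )
        prev_lower, prev_boundary = lower_label, boundary
        if regions_stable and shift < tol:
            break

    labels = _hard_labels(nu, lower_label, boundary)
    return ClusterResult(
        centroids=V,
        eta=eta,
        nu=nu,
        mu=mu,
        delta1=d1,
        delta2=d2,
        lower_label=lower_label,
        boundary=boundary,
        labels=labels,
        n_iter=n_iter,
        objective=obj_trace[-1],
        objective_trace=obj_trace,
        centroid_trace=V_trace,
    )


class RobustRoughFuzzyCMeans(ClusterMixin, BaseEstimator):
    """Robust rough-fuzzy c-means clusterer (scikit-learn interface).

    Parameters
    ----------
    n_clusters : int, default=3
    m1, m2 : float, default=2.0
        Probabilistic and possibilistic fuzzifiers (> 1).
    omega : float, default=0.99
        Relative weight of the lower approximations in the objective and in
        the centroid update; (1 - omega) weighs the boundary regions.
    K : float, default=1.0
        Multiplier of the per-cluster scale parameters eta.
    max_iter : int, default=100
    tol : float, default=1e-5
        Centroid-shift convergence tolerance.
    random_state : int or None
        Seeds the hard c-means initialization.
    freeze_eta : bool, default=False
        Keep the bootstrap eta for the whole run (classical PCM behaviour).
    eta_floor : float, default=1e-3
        Lower bound on each refreshed eta_i, relative to its bootstrap
        value; guards against possibilistic scale collapse.

    Attributes
    ----------
    cluster_centers_ : (n_clusters, m) ndarray
    labels_ : (n,) ndarray of hard labels
    result_ : ClusterResult with memberships, regions, thresholds and trace
    """

    def __init__(
        self,
        n_clusters: int = 3,
        m1: float = 2.0,
        m2: float = 2.0,
        omega: float = 0.99,
        K: float = 1.0,
        max_iter: int = 100,
        tol: float = 1e-5,
        random_state: int | None = None,
        freeze_eta: bool = False,
        eta_floor: float = 1e-3,
    ):
        self.n_clusters = n_clusters
        self.m1 = m1
        self.m2 = m2
        self.omega = omega
        self.K = K
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.freeze_eta = freeze_eta
        self.eta_floor = eta_floor

    def fit(self, X, y=None):
        X = validate_data(self, X, dtype=float, ensure_min_samples=self.n_clusters)
        result = rrfcm(
            X,
            c=self.n_clusters,
            m1=self.m1,
            m2=self.m2,
            omega=self.omega,
            K=self.K,
            max_iter=self.max_iter,
            tol=self.tol,
            seed=self.random_state,
            freeze_eta=self.freeze_eta,
            eta_floor=self.eta_floor,
        )
        self.result_ = result
        self.cluster_centers_ = result.centroids
        self.labels_ = result.labels
        self.n_iter_ = result.n_iter
        return self

    def predict(self, X):
        """Assign new objects to the cluster of highest typicality."""
        check_is_fitted(self)
        X = validate_data(self, X, reset=False, dtype=float)
        nu = pcm_membership(X, self.cluster_centers_, self.result_.eta, self.m2)
        return nu.argmax(axis=0)
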
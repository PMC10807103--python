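"""ADMM solver for prior-constrained hierarchical fusion clustering.

The objective couples a least-squares fit of per-sample centers (beta for
the rough-level features X, gamma for the refined-level features Z) with
two concave fusion penalties over all sample pairs: a group MCP on the
joint (beta, gamma) difference and an MCP on the beta difference alone.
Must-link prior pairs are removed from the penalized pair set and enforced
as exact equalities by parametrizing (beta, gamma) over the prior blocks.

ADMM splitting introduces per-pair fusion variables (omega, eta) with duals
(v, u) and penalty parameter theta.  One iteration is: an exact quadratic
minimization over block centers, the hierarchical groupwise prox per pair,
and a dual ascent step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

from .penalty import PenaltySpec, mcp_value, prox_pairs
from .prior import PairIndex, PriorPairSet, PriorPartition, build_pair_index, to_partition


@dataclass(frozen=True)
class HierarchicalDataset:
    """Two aligned feature blocks, columns are samples.

    ``X`` is q x n (rough-level features), ``Z`` is p x n (refined-level
    features); ``sample_ids`` labels the shared columns.
    """

    X: np.ndarray
    Z: np.ndarray
    sample_ids: tuple = None

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        Z = np.asarray(self.Z, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Z", Z)
        if X.ndim != 2 or Z.ndim != 2 or X.shape[1] != Z.shape[1]:
            raise ValueError("X and Z must be 2-D with equal sample counts")
        if not (np.isfinite(X).all() and np.isfinite(Z).all()):
            raise ValueError("missing or non-finite feature values")
        if self.sample_ids is None:
            object.__setattr__(
                self, "sample_ids", tuple(f"S{i + 1}" for i in range(X.shape[1]))
            )
        elif len(self.sample_ids) != X.shape[1]:
            raise ValueError("sample_ids length mismatch")

    @property
    def n(self):
        return self.X.shape[1]

    @property
    def q(self):
        return self.X.shape[0]

    @property
    def p(self):
        return self.Z.shape[0]


@dataclass(frozen=True)
class SolverConfig:
    """ADMM and initialization settings.

    ``tol_primal`` is a per-coordinate tolerance; convergence is declared
    when the primal residual norm falls below
    ``tol_primal * sqrt(n_pairs * (q + p))``.
    """

    theta: float = 1.0
    a: float = 3.0
    max_iter: int = 500
    tol_primal: float = 1e-4
    init_k_min: int = 2
    init_k_max: int = 10
    kmeans_restarts: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.theta <= 0 or self.max_iter < 1 or self.tol_primal <= 0:
            raise ValueError("theta, max_iter and tol_primal must be positive")
        if not (2 <= self.init_k_min <= self.init_k_max):
            raise ValueError("invalid initialization cluster range")


@dataclass
class PCHState:
    """All ADMM variables plus tuning values and convergence diagnostics."""

    beta: np.ndarray  # q x n
    gamma: np.ndarray  # p x n
    omega: np.ndarray  # q x n_pairs
    eta: np.ndarray  # p x n_pairs
    v: np.ndarray  # q x n_pairs
    u: np.ndarray  # p x n_pairs
    lambda1: float
    lambda2: float
    theta: float
    a: float
    iteration: int = 0
    residuals: list = field(default_factory=list)
    converged: bool = False


def objective_Q(state: PCHState, data: HierarchicalDataset, pairs: PairIndex) -> float:
    """Penalized objective: least-squares fit plus the two MCP fusion sums
    over non-prior pairs, evaluated at the current (beta, gamma)."""
    loss = 0.5 * (
        np.sum((data.X - state.beta) ** 2) + np.sum((data.Z - state.gamma) ** 2)
    )
    free = ~pairs.is_prior
    db = state.beta[:, pairs.j_idx[free]] - state.beta[:, pairs.m_idx[free]]
    dg = state.gamma[:, pairs.j_idx[free]] - state.gamma[:, pairs.m_idx[free]]
    nb = np.linalg.norm(db, axis=0)
    joint = np.sqrt(nb**2 + np.sum(dg**2, axis=0))
    p1 = mcp_value(joint, PenaltySpec(state.lambda1, state.a))
    p2 = mcp_value(nb, PenaltySpec(state.lambda2, state.a))
    return float(loss + np.sum(p1) + np.sum(p2))


class _Workspace:
    """Per-(data, prior, theta) precomputations shared across lambda values.

    Holds the pair enumeration, the transposed incidence matrix D^T, the
    prior block labels/sizes, and the closed-form inverse of the K x K
    system L^T L + theta L^T D^T D L.  Because D^T D = n I - 11^T, that
    system is c*diag(s) - theta*s s^T with c = 1 + theta*n and s the block
    sizes, whose inverse is diag(1/(c s)) + (theta/c) 11^T by
    Sherman-Morrison; no factorization is needed.
    """

    def __init__(self, data, partition: PriorPartition, pairs: PairIndex, theta):
        self.pairs = pairs
        self.labels = partition.labels
        self.sizes = partition.sizes.astype(float)
        self.K = partition.K
        self.n = data.n
        self.theta = theta
        self.c = 1.0 + theta * self.n
        self.DT = pairs.D.T.tocsr()
        self.W = np.vstack([data.X, data.Z])

    def solve_centers(self, P):
        """Exact minimizer of the quadratic Lagrangian over block centers.

        ``P`` is the stacked (theta*omega - v; theta*eta - u), (q+p) x n_pairs.
        Returns the (q+p) x K block-center matrix T.
        """
        PD = (self.DT @ P.T).T  # (q+p) x n
        M = self.W + PD
        G = np.zeros((M.shape[0], self.K))
        np.add.at(G.T, self.labels, M.T)
        T = G / (self.c * self.sizes)[None, :] + (self.theta / self.c) * G.sum(
            axis=1, keepdims=True
        )
        return T


def _ch_kmeans(F, k_min, k_max, restarts, seed):
    """K-means with the cluster count picked by the Calinski-Harabasz index.

    ``F`` is samples x features.  Returns labels (0-based, contiguous).
    """
    n = F.shape[0]
    k_hi = min(k_max, n - 1)
    if n < 3 or k_hi < 2:
        return np.zeros(n, dtype=np.int64)
    best_score, best_labels = -np.inf, None
    for k in range(k_min, k_hi + 1):
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
        labels = km.fit_predict(F)
        if len(np.unique(labels)) < 2:
            continue
        score = calinski_harabasz_score(F, labels)
        if score > best_score:
            best_score, best_labels = score, labels
    if best_labels is None:
        return np.zeros(n, dtype=np.int64)
    return best_labels.astype(np.int64)


def _majority_adjust(labels, partition: PriorPartition):
    """Reassign every prior block to its majority label (ties -> lowest)."""
    labels = labels.copy()
    for block in partition.blocks:
        if len(block) < 2:
            continue
        idx = np.array(block)
        vals, counts = np.unique(labels[idx], return_counts=True)
        labels[idx] = vals[np.argmax(counts)]  # np.unique sorts: ties -> lowest
    return _relabel(labels)


def _relabel(labels):
    """Contiguous 0-based labels ordered by first occurrence."""
    out = np.empty_like(labels)
    mapping = {}
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def _centers_from_labels(F, labels):
    """Per-sample center columns: each sample gets its cluster mean."""
    d, n = F.shape
    out = np.empty((d, n))
    for lab in np.unique(labels):
        idx = labels == lab
        out[:, idx] = F[:, idx].mean(axis=1, keepdims=True)
    return out


def initialize(
    data: HierarchicalDataset,
    partition: PriorPartition,
    config: SolverConfig,
    pairs: PairIndex = None,
) -> PCHState:
    """Two-step K-means initialization with prior adjustment.

    Rough labels come from K-means on X with the cluster count maximizing
    the Calinski-Harabasz index; refined labels from K-means on Z inside
    each rough cluster (one refined cluster when the rough cluster has
    fewer than 3 members).  Every prior block is then reassigned to its
    majority cluster at each level so the initial centers satisfy the
    equality constraints exactly.  Fusion variables start at the initial
    pairwise differences, duals at zero.
    """
    n = data.n
    if n < 2:
        raise ValueError("need at least two samples")
    if pairs is None:
        pairs = build_pair_index(n)
    rough = _ch_kmeans(
        data.X.T, config.init_k_min, config.init_k_max, config.kmeans_restarts,
        config.seed,
    )
    rough = _majority_adjust(rough, partition)
    refined = np.zeros(n, dtype=np.int64)
    offset = 0
    for lab in np.unique(rough):
        idx = np.flatnonzero(rough == lab)
        sub = _ch_kmeans(
            data.Z[:, idx].T, config.init_k_min, config.init_k_max,
            config.kmeans_restarts, config.seed,
        )
        refined[idx] = offset + sub
        offset += sub.max() + 1
    refined = _majority_adjust(refined, partition)
    beta0 = _centers_from_labels(data.X, rough)
    gamma0 = _centers_from_labels(data.Z, refined)
    omega0 = beta0[:, pairs.j_idx] - beta0[:, pairs.m_idx]
    eta0 = gamma0[:, pairs.j_idx] - gamma0[:, pairs.m_idx]
    return PCHState(
        beta=beta0, gamma=gamma0, omega=omega0, eta=eta0,
        v=np.zeros_like(omega0), u=np.zeros_like(eta0),
        lambda1=0.0, lambda2=0.0, theta=config.theta, a=config.a,
    )


def update_centers(state: PCHState, ws: _Workspace):
    """Exact (beta, gamma) block update: replicate the solved block centers
    over the prior blocks (Kronecker structure applied implicitly)."""
    P = np.vstack([
        state.theta * state.omega - state.v,
        state.theta * state.eta - state.u,
    ])
    T = ws.solve_centers(P)
    q = state.beta.shape[0]
    cols = T[:, ws.labels]
    state.beta = cols[:q]
    state.gamma = cols[q:]
    return state


def update_fusion(state: PCHState, ws: _Workspace):
    """Per-pair hierarchical prox at omega* = beta_j - beta_m + v/theta,
    eta* = gamma_j - gamma_m + u/theta; prior pairs stay exactly zero."""
    pairs = ws.pairs
    db = state.beta[:, pairs.j_idx] - state.beta[:, pairs.m_idx]
    dg = state.gamma[:, pairs.j_idx] - state.gamma[:, pairs.m_idx]
    os_ = db + state.v / state.theta
    es_ = dg + state.u / state.theta
    om, et = prox_pairs(os_, es_, state.lambda1, state.lambda2, state.a,
                        state.theta)
    free = ~pairs.is_prior
    # identity prox on every free pair <=> all penalties sit in their flat
    # region: the objective is locally pure least squares (see fit)
    state._prox_identity = bool(
        np.array_equal(om[:, free], os_[:, free])
        and np.array_equal(et[:, free], es_[:, free])
    )
    om[:, pairs.is_prior] = 0.0
    et[:, pairs.is_prior] = 0.0
    state.omega, state.eta = om, et
    state._db, state._dg = db, dg  # reused by the dual step this iteration
    return state


def update_duals(state: PCHState, ws: _Workspace):
    """Dual ascent; returns the primal residual norm as a by-product."""
    pairs = ws.pairs
    if getattr(state, "_db", None) is not None:
        rb = state._db - state.omega
        rg = state._dg - state.eta
        state._db = state._dg = None
    else:
        rb = state.beta[:, pairs.j_idx] - state.beta[:, pairs.m_idx] - state.omega
        rg = state.gamma[:, pairs.j_idx] - state.gamma[:, pairs.m_idx] - state.eta
    if pairs.is_prior.any():
        rb[:, pairs.is_prior] = 0.0
        rg[:, pairs.is_prior] = 0.0
    state.v = state.v + state.theta * rb
    state.u = state.u + state.theta * rg
    return state, float(np.sqrt(np.sum(rb**2) + np.sum(rg**2)))


def fit(
    data: HierarchicalDataset,
    prior: PriorPairSet | None,
    lambda1: float,
    lambda2: float,
    config: SolverConfig = SolverConfig(),
    *,
    init: PCHState = None,
    partition: PriorPartition = None,
    pairs: PairIndex = None,
) -> PCHState:
    """Run ADMM to (primal) convergence for one (lambda1, lambda2).

    ``init`` allows warm starting: the lambda-independent two-step K-means
    state, or the converged state of a neighboring tuning-grid point.  The
    returned state satisfies the prior constraints exactly at every
    iteration by construction.
    """
    if prior is None:
        prior = PriorPairSet(n=data.n)
    if partition is None:
        partition = to_partition(prior)
    if pairs is None:
        pairs = build_pair_index(data.n, prior)
    ws = _Workspace(data, partition, pairs, config.theta)
    if init is None:
        state = initialize(data, partition, config, pairs)
    else:
        state = PCHState(
            beta=init.beta.copy(), gamma=init.gamma.copy(),
            omega=init.omega.copy(), eta=init.eta.copy(),
            v=init.v.copy(), u=init.u.copy(),
            lambda1=lambda1, lambda2=lambda2, theta=config.theta, a=config.a,
        )
    state.lambda1, state.lambda2 = float(lambda1), float(lambda2)
    state.theta, state.a = config.theta, config.a
    state.residuals = []
    tol = config.tol_primal * np.sqrt(pairs.n_pairs * (data.q + data.p))
    jumps = 0
    for it in range(1, config.max_iter + 1):
        state = update_centers(state, ws)
        state = update_fusion(state, ws)
        state, resid = update_duals(state, ws)
        state.iteration = it
        state.residuals.append(resid)
        if not np.isfinite(resid):
            raise FloatingPointError(f"non-finite ADMM state at iteration {it}")
        if state._prox_identity and jumps < 2:
            # every pairwise difference sits in the flat MCP region, where
            # the penalties are constants and the exact constrained
            # minimizer is the block-mean projection of the data; ADMM
            # would approach it at a slow geometric rate, so jump there and
            # keep it only if the flat regime is self-consistent
            jumps += 1
            state = _flat_regime_jump(state, ws)
            if state._prox_identity:
                state.residuals.append(0.0)
                state.converged = True
                break
            continue
        if resid <= tol:
            state.converged = True
            break
    return state


def _flat_regime_jump(state, ws):
    """Exact minimizer when all fusion penalties are flat: block means."""
    q = state.beta.shape[0]
    G = np.zeros((ws.W.shape[0], ws.K))
    np.add.at(G.T, ws.labels, ws.W.T)
    T = G / ws.sizes[None, :]
    cols = T[:, ws.labels]
    state.beta, state.gamma = cols[:q], cols[q:]
    state.v[:] = 0.0
    state.u[:] = 0.0
    state = update_fusion(state, ws)  # omega = diffs exactly; rechecks flatness
    return state
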
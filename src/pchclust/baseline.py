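"""Two-step convex clustering baseline (L1 or L2 fusion penalties).

Step 1 clusters all samples on the rough-level features X; step 2 runs a
fresh convex clustering on the refined-level features Z inside each
first-step cluster, so nesting holds by construction.  Each step's fusion
weight is chosen by the same modified BIC as the main method, restricted to
that step.  Pairwise weights are uniform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .extraction import ClusteringResult, _component_labels
from .selection import _CN


@dataclass(frozen=True)
class ConvexClusterConfig:
    norm: str = "L2"  # L1 | L2
    lam: float = 0.0
    theta: float = 1.0
    max_iter: int = 300
    tol: float = 1e-4
    zero_tol: float = 1e-8

    def __post_init__(self):
        if self.norm not in ("L1", "L2"):
            raise ValueError("norm must be 'L1' or 'L2'")
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")


def convex_cluster(features: np.ndarray, config: ConvexClusterConfig):
    """ADMM for (1/2) sum ||x_i - u_i||^2 + lam sum_{j<m} ||u_j - u_m||_norm.

    ``features`` is d x n.  Uses the same splitting as the main solver with
    the convex prox (soft threshold for L1, group shrinkage for L2); the
    quadratic center update has the closed-form inverse
    (I/c + (theta/c) 11^T), c = 1 + theta*n.  Returns (labels, centers)
    with labels from the exact-zero fusion differences.
    """
    F = np.asarray(features, dtype=float)
    d, n = F.shape
    if n < 2:
        raise ValueError("need at least two samples")
    lam, theta = config.lam, config.theta
    j_idx, m_idx = np.triu_indices(n, k=1)
    c = 1.0 + theta * n
    U = F.copy()
    omega = U[:, j_idx] - U[:, m_idx]
    v = np.zeros_like(omega)
    tol = config.tol * np.sqrt(len(j_idx) * d)
    for _ in range(config.max_iter):
        # centers update
        P = theta * omega - v
        PD = np.zeros((d, n))
        np.add.at(PD.T, j_idx, P.T)
        np.subtract.at(PD.T, m_idx, P.T)
        G = F + PD
        U = G / c + (theta / c) * G.sum(axis=1, keepdims=True)
        # fusion prox
        diffs = U[:, j_idx] - U[:, m_idx]
        star = diffs + v / theta
        if config.norm == "L2":
            norms = np.linalg.norm(star, axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                shrink = np.maximum(1.0 - (lam / theta) / np.where(norms > 0, norms, 1.0), 0.0)
            omega = star * np.where(norms > 0, shrink, 0.0)
        else:
            omega = np.sign(star) * np.maximum(np.abs(star) - lam / theta, 0.0)
        # duals
        resid = diffs - omega
        v = v + theta * resid
        if np.sqrt(np.sum(resid**2)) <= tol:
            break
    labels = _component_labels(
        n, j_idx, m_idx, np.linalg.norm(omega, axis=0) <= config.zero_tol
    )
    K = labels.max() + 1
    centers = np.column_stack([U[:, labels == k].mean(axis=1) for k in range(K)])
    return labels, centers


def _step_bic(F, labels, centers, Cn_mode):
    n = F.shape[1]
    resid = F - centers[:, labels]
    rss = float(np.sum(resid**2))
    if rss <= 0:
        return float("-inf")
    return float(np.log(rss / n) + _CN[Cn_mode](n) * (np.log(n) / n) * (labels.max() + 1))


def _step_grid(F, norm, size=8, lo=1.0, hi=20.0):
    """Fusion-weight grid over the region where merging actually happens.

    For uniform weights the relevant lam scale is the noise level divided
    by n (the accumulated pull of ~n unit-weight pairs must offset a
    noise-sized deviation): sqrt(d)*sigma_hat/n for the L2 group penalty,
    sigma_hat/n for the coordinate-wise L1 penalty.  The grid spans
    [lo, hi] times that scale, log-spaced; below this bracket the solution
    is near-saturated (every sample its own barely-shrunk cluster), whose
    vanishing residual makes the BIC's log term incomparable.
    """
    d, n = F.shape
    sigma = np.sqrt(np.mean(np.var(F, axis=1))) or 1.0
    scale = (np.sqrt(d) if norm == "L2" else 1.0) * sigma / n
    return np.geomspace(lo * scale, hi * scale, size)


def _tune_step(F, norm, grid, Cn_mode, **cfg_kw):
    """Best step fit by modified BIC; near-saturated fits (K > n/2) are
    recorded but never selected, since their BIC is dominated by a residual
    that measures shrinkage rather than clustering fit."""
    n = F.shape[1]
    best = fallback = None
    for lam in grid:
        config = ConvexClusterConfig(norm=norm, lam=lam, **cfg_kw)
        labels, centers = convex_cluster(F, config)
        score = _step_bic(F, labels, centers, Cn_mode)
        if not np.isfinite(score):
            continue
        fallback = (labels, centers)
        if labels.max() + 1 > max(n // 2, 1):
            continue
        if best is None or score < best[0] - 1e-12:
            best = (score, labels, centers)
    if best is None:
        if fallback is None:
            warnings.warn("all step fits saturated; falling back to singletons")
            return np.arange(n), F.copy()
        return fallback
    return best[1], best[2]


def two_step(
    data,
    norm: str = "L2",
    grid_size: int = 8,
    Cn_mode: str = "loglog",
    **cfg_kw,
) -> ClusteringResult:
    """Two-step convex clustering of a hierarchical dataset.

    Step-wise lam values are picked by the modified BIC on each step's own
    residual and cluster count.  Refined labels are renumbered globally;
    singleton rough clusters pass through as singleton refined clusters.
    """
    rough, xi = _tune_step(data.X, norm, _step_grid(data.X, norm, grid_size),
                           Cn_mode, **cfg_kw)
    n = data.n
    refined = np.zeros(n, dtype=np.int64)
    alpha_cols, nesting = [], []
    offset = 0
    for k in range(rough.max() + 1):
        idx = np.flatnonzero(rough == k)
        if len(idx) < 2:
            refined[idx] = offset
            alpha_cols.append(data.Z[:, idx].mean(axis=1))
            nesting.append(k)
            offset += 1
            continue
        sub, centers = _tune_step(data.Z[:, idx], norm,
                                  _step_grid(data.Z[:, idx], norm, grid_size),
                                  Cn_mode, **cfg_kw)
        refined[idx] = offset + sub
        for t in range(sub.max() + 1):
            alpha_cols.append(centers[:, t])
            nesting.append(k)
        offset += sub.max() + 1
    return ClusteringResult(
        rough_labels=rough, refined_labels=refined,
        xi_hat=xi, alpha_hat=np.column_stack(alpha_cols),
        nesting=tuple(nesting),
    )
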
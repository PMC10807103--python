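"""Discrete cluster structures from a converged solver state.

Membership is read from the fusion variables: the prox returns exact zeros,
so omega_hat/eta_hat are the algorithm's native sparsity certificate, which
is numerically far better posed than comparing beta_hat columns for
equality at finite ADMM precision.  A small ``zero_tol`` guards residual
jitter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .prior import PairIndex
from .solver import PCHState


@dataclass(frozen=True)
class ClusteringResult:
    """Rough and refined partitions with centers and the nesting map.

    Labels are 0-based and contiguous, ordered by first member.  The
    refined partition always refines the rough one: ``nesting[t]`` is the
    rough cluster containing refined cluster ``t``.
    """

    rough_labels: np.ndarray
    refined_labels: np.ndarray
    xi_hat: np.ndarray  # q x K1 rough centers
    alpha_hat: np.ndarray  # p x K2 refined centers
    nesting: tuple

    @property
    def K1(self) -> int:
        return self.xi_hat.shape[1]

    @property
    def K2(self) -> int:
        return self.alpha_hat.shape[1]


def _component_labels(n, j_idx, m_idx, edge_mask):
    g = sparse.csr_matrix(
        (np.ones(int(edge_mask.sum())), (j_idx[edge_mask], m_idx[edge_mask])),
        shape=(n, n),
    )
    _, labels = connected_components(g, directed=False)
    # connected_components orders by first member already; make explicit
    out = np.empty(n, dtype=np.int64)
    mapping = {}
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def extract(state: PCHState, pairs: PairIndex, zero_tol: float = 1e-8) -> ClusteringResult:
    """Connected components of the zero-fusion graphs.

    Rough merge edges: pairs with ||omega_hat|| <= zero_tol, plus all prior
    pairs.  Refined merge edges additionally require ||eta_hat|| <=
    zero_tol.  Refined edges are a subset of rough edges, so nesting holds
    by construction.  Centers are within-cluster means of beta_hat /
    gamma_hat (near-identical within a cluster; averaging removes
    sub-tolerance jitter).
    """
    n = state.beta.shape[1]
    om_zero = np.linalg.norm(state.omega, axis=0) <= zero_tol
    et_zero = np.linalg.norm(state.eta, axis=0) <= zero_tol
    rough_edges = om_zero | pairs.is_prior
    refined_edges = (om_zero & et_zero) | pairs.is_prior
    rough = _component_labels(n, pairs.j_idx, pairs.m_idx, rough_edges)
    refined = _component_labels(n, pairs.j_idx, pairs.m_idx, refined_edges)
    K1, K2 = rough.max() + 1, refined.max() + 1
    xi = np.column_stack(
        [state.beta[:, rough == k].mean(axis=1) for k in range(K1)]
    )
    alpha = np.column_stack(
        [state.gamma[:, refined == k].mean(axis=1) for k in range(K2)]
    )
    nesting = tuple(
        int(rough[np.flatnonzero(refined == t)[0]]) for t in range(K2)
    )
    return ClusteringResult(
        rough_labels=rough, refined_labels=refined,
        xi_hat=xi, alpha_hat=alpha, nesting=nesting,
    )
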
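"""Evaluation metrics: pair-counting ARI, center RMSE, pairwise similarity
index, and the leave-m-out clustering-stability procedure.

The ARI here is the pair-count form

    2 (TP*TN - FP*FN) / ((TP+FP)(FP+TN) + (TP+FN)(FN+TN)),

implemented verbatim (not the general Hubert-Arabie expression), since the
simulation tables are produced by this formula.  TP/FP count pair decisions
that place two samples in the same estimated cluster when they share /
don't share a true cluster; TN/FN the analogous "different cluster"
decisions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .prior import PriorPairSet
from .selection import TuningGrid, tune
from .solver import HierarchicalDataset, SolverConfig


@dataclass(frozen=True)
class PairConfusion:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def pair_confusion(labels_true, labels_est) -> PairConfusion:
    """Pairwise co-membership confusion counts over all n(n-1)/2 pairs."""
    a = np.asarray(labels_true)
    b = np.asarray(labels_est)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("labelings must be 1-D and of equal length")
    if len(a) < 2:
        raise ValueError("need at least two samples")
    j, m = np.triu_indices(len(a), k=1)
    same_t = a[j] == a[m]
    same_e = b[j] == b[m]
    return PairConfusion(
        TP=int(np.sum(same_t & same_e)),
        FP=int(np.sum(~same_t & same_e)),
        TN=int(np.sum(~same_t & ~same_e)),
        FN=int(np.sum(same_t & ~same_e)),
    )


def ari(labels_true, labels_est) -> float:
    """Pair-counting adjusted Rand index; 0 when the denominator vanishes."""
    c = pair_confusion(labels_true, labels_est)
    denom = (c.TP + c.FP) * (c.FP + c.TN) + (c.TP + c.FN) * (c.FN + c.TN)
    if denom == 0:
        return 0.0
    return 2.0 * (c.TP * c.TN - c.FP * c.FN) / denom


def mse_centers(estimate, truth) -> float:
    """Root of the entrywise mean squared deviation,
    ((1/(n*d)) sum_i ||est_i - truth_i||^2)^(1/2)."""
    est = np.asarray(estimate, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if est.shape != tru.shape:
        raise ValueError("shape mismatch between estimate and truth")
    return float(np.sqrt(np.mean((est - tru) ** 2)))


def similarity_SI(map_a, map_b) -> float:
    """Fraction of sample pairs on which two labelings agree about
    same-vs-different cluster; 1 iff they induce the same pair relation."""
    a = np.asarray(map_a)
    b = np.asarray(map_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("labelings must be 1-D and of equal length")
    j, m = np.triu_indices(len(a), k=1)
    agree = (a[j] == a[m]) == (b[j] == b[m])
    return float(np.mean(agree))


def _restrict_prior(prior: PriorPairSet, keep: np.ndarray) -> PriorPairSet:
    """Prior restricted to the kept samples, reindexed to their new positions."""
    pos = -np.ones(prior.n, dtype=np.int64)
    pos[keep] = np.arange(len(keep))
    pairs = set()
    for j, m in prior.pairs:
        if pos[j] >= 0 and pos[m] >= 0:
            pairs.add((int(pos[j]), int(pos[m])))
    return PriorPairSet(n=len(keep), pairs=frozenset(pairs))


def stability_run(
    data: HierarchicalDataset,
    prior: PriorPairSet | None,
    m: int,
    R: int,
    config: SolverConfig,
    grid: TuningGrid,
    seed: int = 0,
    full_result=None,
) -> pd.DataFrame:
    """Leave-m-out clustering stability.

    The full data is tuned once (or ``full_result`` supplied).  Each
    replicate removes m random samples -- with no regard to prior status --
    retunes on the remainder, and scores the pairwise similarity SI between
    the new rough/refined labelings and the full-data labelings restricted
    to the remaining samples.  Returns one row per replicate.
    """
    n = data.n
    if not 0 <= m < n:
        raise ValueError("m must satisfy 0 <= m < n")
    if prior is None:
        prior = PriorPairSet(n=n)
    if full_result is None:
        _, full_result, _ = tune(data, prior, grid, config)
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(R):
        keep = np.sort(rng.choice(n, size=n - m, replace=False))
        sub = HierarchicalDataset(
            X=data.X[:, keep], Z=data.Z[:, keep],
            sample_ids=tuple(data.sample_ids[i] for i in keep),
        )
        _, res, _ = tune(sub, _restrict_prior(prior, keep), grid, config)
        rows.append(dict(
            replicate=r,
            si_rough=similarity_SI(res.rough_labels,
                                   full_result.rough_labels[keep]),
            si_refined=similarity_SI(res.refined_labels,
                                     full_result.refined_labels[keep]),
        ))
    return pd.DataFrame(rows)
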
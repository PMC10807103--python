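"""Synthetic scenario generators for the simulation study conditions.

Five hierarchical scenarios (Gaussian clusters sims 1-3, half-moon sims
4-5) plus a hierarchy-violation scenario, with must-link prior sampling at
a configurable rate tau and the two prior-corruption modes.  Defaults are
the study conditions: n = 120 subjects, q = 6 rough-level features, p = 30
refined-level features, sigma^2 = 1, rho = 0.3.

Center patterns are +/-1 sign blocks: rough centers scale 4/5*mu over
thirds of q, refined centers scale mu over halves or thirds of p.  Refined
labels are uniform over the K2 clusters; the nesting of refined in rough
clusters follows each scenario's hierarchy map (the violation scenario
deliberately places one refined cluster across both rough clusters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .prior import PriorPairSet, partition_to_pairs, to_partition, validate_and_close
from .solver import HierarchicalDataset

SCENARIOS = ("sim1", "sim2", "sim3", "sim4", "sim5", "violation")


@dataclass(frozen=True)
class ScenarioConfig:
    scenario: str
    n: int = 120
    q: int = 6
    p: int = 30
    mu: float = 1.2
    nu: float = 2.0  # half-moon horizontal center offset (sim4/sim5)
    cov_Z: str = "diagonal"  # diagonal | AR | banded
    rho: float = 0.3
    sigma2: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.cov_Z not in ("diagonal", "AR", "banded"):
            raise ValueError(f"unknown covariance kind {self.cov_Z!r}")
        if self.scenario in ("sim1", "sim2", "sim3", "violation") and self.q % 3:
            raise ValueError("q must be divisible by 3 for sign-block rough centers")
        if self.scenario in ("sim4", "sim5") and self.q != 6:
            raise ValueError("half-moon scenarios fix q = 6")
        halves = self.scenario in ("sim1", "sim4", "violation")
        if halves and self.p % 2:
            raise ValueError("p must be divisible by 2 for this scenario")
        if not halves and self.p % 3:
            raise ValueError("p must be divisible by 3 for this scenario")


@dataclass(frozen=True)
class GroundTruth:
    rough_labels: np.ndarray
    refined_labels: np.ndarray
    beta_star: np.ndarray  # q x n
    gamma_star: np.ndarray  # p x n

    @property
    def N0(self) -> int:
        """Count of true same-refined-cluster pairs."""
        _, counts = np.unique(self.refined_labels, return_counts=True)
        return int(np.sum(counts * (counts - 1) // 2))


def _blocks(signs, d):
    """Sign pattern over equal blocks: e.g. (-1, 1, 1) over thirds of d."""
    k = len(signs)
    return np.repeat(np.asarray(signs, dtype=float), d // k)


# rough-center sign patterns (over thirds of q) and refined patterns, per scenario
_ROUGH = {
    "sim1": [(-1, 1, 1), (1, 1, -1)],
    "sim2": [(-1, 1, 1), (1, 1, -1)],
    "sim3": [(-1, 1, 1), (1, -1, 1), (1, 1, -1)],
    "violation": [(-1, 1, 1), (1, 1, -1)],
}
_REFINED = {
    "sim1": [(1, 1), (-1, 1), (1, -1), (-1, -1)],
    "sim2": [(-1, 1, 1), (1, -1, 1), (1, 1, -1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)],
    "sim3": [(-1, 1, 1), (1, -1, -1), (1, -1, 1), (-1, 1, -1), (1, 1, -1), (-1, -1, 1)],
    "violation": [(1, 1), (-1, 1), (0, 0), (1, -1), (-1, -1)],
}
# hierarchy map: refined label -> rough label
_NEST = {
    "sim1": [0, 0, 1, 1],
    "sim2": [0, 0, 0, 1, 1, 1],
    "sim3": [0, 0, 1, 1, 2, 2],
}


def cov_Z_matrix(config: ScenarioConfig) -> np.ndarray:
    p, s2, rho = config.p, config.sigma2, config.rho
    if config.scenario in ("sim4", "sim5"):
        return np.eye(p)  # half-moon scenarios fix the identity covariance
    if config.cov_Z == "diagonal":
        return s2 * np.eye(p)
    jm = np.abs(np.subtract.outer(np.arange(p), np.arange(p)))
    if config.cov_Z == "AR":
        return s2 * rho**jm
    banded = np.where(jm == 0, 1.0, np.where(jm == 1, rho, 0.0))
    return s2 * banded


def _draw_Z(refined, config, rng):
    p = config.p
    centers = np.column_stack(
        [config.mu * _blocks(s, p) for s in _REFINED[config.scenario]]
    )
    cov = cov_Z_matrix(config)
    chol = np.linalg.cholesky(cov)
    noise = chol @ rng.standard_normal((p, len(refined)))
    return centers[:, refined] + noise, centers[:, refined]


def generate_gaussian(config: ScenarioConfig):
    """Gaussian-cluster scenarios (sims 1-3): X_i ~ MVN(mu_X(Y_i), sigma^2 I_q),
    Z_i ~ MVN(mu_Z(Y_i), Sigma_Z) with the Table-pattern centers."""
    if config.scenario not in ("sim1", "sim2", "sim3"):
        raise ValueError("generate_gaussian handles sim1/sim2/sim3 only")
    rng = np.random.default_rng(config.seed)
    K2 = len(_REFINED[config.scenario])
    refined = rng.integers(0, K2, config.n)
    rough = np.asarray(_NEST[config.scenario])[refined]
    x_centers = np.column_stack(
        [0.8 * config.mu * _blocks(s, config.q) for s in _ROUGH[config.scenario]]
    )
    beta_star = x_centers[:, rough]
    X = beta_star + np.sqrt(config.sigma2) * rng.standard_normal((config.q, config.n))
    Z, gamma_star = _draw_Z(refined, config, rng)
    data = HierarchicalDataset(X=X, Z=Z)
    truth = GroundTruth(rough_labels=rough, refined_labels=refined,
                        beta_star=beta_star, gamma_star=gamma_star)
    return data, truth


def generate_halfmoon(config: ScenarioConfig):
    """Half-moon scenarios (sims 4-5).

    First two X dimensions: radius-4 arcs, upper arc about (-nu, 0.2) for
    rough cluster 1 (angle uniform on [0, pi]) and lower arc about
    (nu, -0.2) for rough cluster 2 (angle uniform on [pi, 2*pi]), plus
    N(0, 0.1^2) noise.  Remaining q-2 dimensions: unit-variance Gaussians
    at (4/5)*mu*(-1,-1,1,1) and (4/5)*mu*(1,1,-1,-1).  Z follows the sim1
    (sim4) or sim2 (sim5) refined patterns with identity covariance.
    """
    if config.scenario not in ("sim4", "sim5"):
        raise ValueError("generate_halfmoon handles sim4/sim5 only")
    rng = np.random.default_rng(config.seed)
    zlike = "sim1" if config.scenario == "sim4" else "sim2"
    K2 = len(_REFINED[zlike])
    refined = rng.integers(0, K2, config.n)
    rough = np.asarray(_NEST[zlike])[refined]
    n = config.n
    theta = np.where(
        rough == 0, rng.uniform(0, np.pi, n), rng.uniform(np.pi, 2 * np.pi, n)
    )
    cx = np.where(rough == 0, -config.nu, config.nu)
    cy = np.where(rough == 0, 0.2, -0.2)
    arc = np.vstack([cx + 4.0 * np.cos(theta), cy + 4.0 * np.sin(theta)])
    X_head = arc + 0.1 * rng.standard_normal((2, n))
    tail_centers = np.column_stack([
        0.8 * config.mu * np.array([-1.0, -1.0, 1.0, 1.0]),
        0.8 * config.mu * np.array([1.0, 1.0, -1.0, -1.0]),
    ])
    X_tail = tail_centers[:, rough] + rng.standard_normal((4, n))
    X = np.vstack([X_head, X_tail])
    zconf = ScenarioConfig(scenario=zlike, n=n, q=config.q, p=config.p,
                           mu=config.mu, cov_Z="diagonal", sigma2=1.0,
                           seed=config.seed)
    Z, gamma_star = _draw_Z(refined, zconf, rng)
    beta_star = np.vstack([arc, tail_centers[:, rough]])
    data = HierarchicalDataset(X=X, Z=Z)
    truth = GroundTruth(rough_labels=rough, refined_labels=refined,
                        beta_star=beta_star, gamma_star=gamma_star)
    return data, truth


def generate_violation(config: ScenarioConfig):
    """Hierarchy-violation scenario: 2 rough clusters, 5 refined clusters.

    Refined cluster 3 (center 0_p) spans both rough clusters: its members
    are assigned to a rough cluster at random, so the true refined
    structure is not nested in the rough one.
    """
    if config.scenario != "violation":
        raise ValueError("generate_violation handles the violation scenario only")
    rng = np.random.default_rng(config.seed)
    refined = rng.integers(0, 5, config.n)
    nest = np.array([0, 0, -1, 1, 1])
    rough = nest[refined]
    straddle = rough == -1
    rough[straddle] = rng.integers(0, 2, int(straddle.sum()))
    x_centers = np.column_stack(
        [0.8 * config.mu * _blocks(s, config.q) for s in _ROUGH["violation"]]
    )
    beta_star = x_centers[:, rough]
    X = beta_star + np.sqrt(config.sigma2) * rng.standard_normal((config.q, config.n))
    Z, gamma_star = _draw_Z(refined, config, rng)
    data = HierarchicalDataset(X=X, Z=Z)
    truth = GroundTruth(rough_labels=rough, refined_labels=refined,
                        beta_star=beta_star, gamma_star=gamma_star)
    return data, truth


def generate(config: ScenarioConfig):
    """Dispatch to the scenario family's generator."""
    if config.scenario in ("sim1", "sim2", "sim3"):
        return generate_gaussian(config)
    if config.scenario in ("sim4", "sim5"):
        return generate_halfmoon(config)
    return generate_violation(config)


def sample_prior_pairs(truth: GroundTruth, tau: float, seed: int):
    """Draw floor(tau * N0) raw pairs uniformly from the true
    same-refined-cluster pairs (before transitive closure)."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    labels = truth.refined_labels
    n = len(labels)
    j, m = np.triu_indices(n, k=1)
    same = labels[j] == labels[m]
    cand = np.flatnonzero(same)
    k = int(np.floor(tau * len(cand)))
    if k == 0:
        return []
    rng = np.random.default_rng(seed)
    take = rng.choice(cand, size=k, replace=False)
    return [(int(j[t]), int(m[t])) for t in take]


def sample_prior(truth: GroundTruth, tau: float, seed: int) -> PriorPairSet:
    """Sampled must-link prior, transitively closed (the pair-set contract
    demands closure; the raw draw is available via ``sample_prior_pairs``)."""
    raw = sample_prior_pairs(truth, tau, seed)
    return validate_and_close(raw, len(truth.refined_labels))


def corrupt_prior(prior: PriorPairSet, mode: str) -> PriorPairSet:
    """Merge the ten largest (or smallest) prior blocks into one block.

    Emulates mis-specified prior information: the merged block asserts many
    wrong must-link pairs.  Blocks are ranked by size with ties broken by
    smallest member index; singleton blocks participate in the ranking.
    The result is a superset of the original pairs.
    """
    if mode not in ("merge_largest10", "merge_smallest10"):
        raise ValueError(f"unknown corruption mode {mode!r}")
    part = to_partition(prior)
    if part.K < 10:
        raise ValueError("need at least 10 prior blocks to corrupt")
    sign = -1 if mode == "merge_largest10" else 1
    order = sorted(part.blocks, key=lambda b: (sign * len(b), b[0]))
    merged = sorted(i for b in order[:10] for i in b)
    rest = [list(b) for b in order[10:]]
    blocks = sorted([merged] + rest, key=lambda b: b[0])
    labels = np.empty(part.n, dtype=np.int64)
    for k, b in enumerate(blocks):
        labels[np.asarray(b)] = k
    from .prior import PriorPartition  # local import to avoid cycle at top

    newpart = PriorPartition(n=part.n, blocks=tuple(tuple(b) for b in blocks),
                             labels=labels)
    return partition_to_pairs(newpart)
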
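"""Minimax concave penalty (MCP) and the hierarchical groupwise prox.

The per-pair ADMM subproblem minimizes

    p(sqrt(||w||^2 + ||e||^2); lam1) + p(||w||; lam2)
        + (theta/2) ||w - w*||^2 + (theta/2) ||e - e*||^2

over (w, e).  The objective depends on (w, e) only through their norms and
their inner products with (w*, e*), so the minimizer is blockwise collinear
with the input: w = (r_w/||w*||) w*, e = (r_e/||e*||) e*.  The reduced 2-D
problem in the radii (r_w, r_e) is piecewise quadratic (MCP is piecewise
quadratic), so the finitely many stationary candidates of every smooth
piece, plus the axis/origin boundary points, are enumerated in closed form
(one piece needs a scalar root, found by vectorized bisection) and the
global minimizer is picked by direct objective comparison.  Ties within
1e-12 prefer the candidate with larger r_w + r_e (less shrinkage), for
deterministic output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class PenaltySpec:
    """MCP with tuning value ``lam`` >= 0 and concavity constant ``a`` > 1."""

    lam: float
    a: float = 3.0
    kind: str = "MCP"

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")
        if self.a <= 1:
            raise ValueError("MCP constant a must exceed 1")
        if self.kind != "MCP":
            raise ValueError(f"unsupported penalty kind {self.kind!r}")


def mcp_value(t, spec: PenaltySpec):
    """p(t; lam) = lam*t - t^2/(2a) for t <= a*lam, else a*lam^2/2.

    Zero at t=0, non-decreasing, concave, and flat beyond a*lam.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("MCP is defined for nonnegative arguments")
    lam, a = spec.lam, spec.a
    out = np.where(t <= a * lam, lam * t - t * t / (2.0 * a), a * lam * lam / 2.0)
    return out if out.ndim else float(out)


def mcp_derivative(t, spec: PenaltySpec):
    """p'(t; lam) = (lam - t/a)_+ ; continuous, bounded by lam."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("MCP is defined for nonnegative arguments")
    out = np.maximum(spec.lam - t / spec.a, 0.0)
    return out if out.ndim else float(out)


def _mcp_val(t, lam, a):
    return np.where(t <= a * lam, lam * t - t * t / (2.0 * a), a * lam * lam / 2.0)


def _radial_objective(rw, rh, w, h, lam1, lam2, a, theta):
    r = np.sqrt(rw * rw + rh * rh)
    return (
        _mcp_val(r, lam1, a)
        + _mcp_val(rw, lam2, a)
        + 0.5 * theta * ((rw - w) ** 2 + (rh - h) ** 2)
    )


def _case_d_root(w, h, lam1, lam2, a, theta, iters=48):
    """Interior stationary radius where both MCP pieces are active.

    With s(r) = (lam1 - r/a)/r the stationarity system gives
    r_w = (theta*w - lam2)_+ * r / (lam1 + (theta - 2/a) r) and
    r_e = theta*h*r / (lam1 + (theta - 1/a) r); the joint radius solves
    g(r) = r_w^2 + r_e^2 - r^2 = 0 on (0, a*lam1].  Bisection, vectorized,
    run only on the pairs whose bracket actually changes sign.
    """
    num_w = np.maximum(theta * w - lam2, 0.0)
    num_h = theta * h

    def g(r, nw, nh):
        dw = lam1 + (theta - 2.0 / a) * r
        dh = lam1 + (theta - 1.0 / a) * r
        with np.errstate(divide="ignore", invalid="ignore"):
            rw = np.where(dw > 0, nw * r / dw, np.inf)
            rh = np.where(dh > 0, nh * r / dh, np.inf)
        return rw * rw + rh * rh - r * r, rw, rh

    rw_out = np.zeros_like(w)
    rh_out = np.zeros_like(h)
    hi0 = a * lam1
    g_lo = num_w * num_w + num_h * num_h - lam1 * lam1  # sign of g near 0
    g_hi, _, _ = g(np.full_like(w, hi0), num_w, num_h)
    sel = np.flatnonzero((g_lo > 0) & (g_hi < 0))
    if len(sel) == 0:
        return rw_out, rh_out
    nw, nh = num_w[sel], num_h[sel]
    lo = np.full(len(sel), 1e-12)
    hi = np.full(len(sel), hi0)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        g_mid, _, _ = g(mid, nw, nh)
        go_right = g_mid > 0
        lo = np.where(go_right, mid, lo)
        hi = np.where(go_right, hi, mid)
    _, rw, rh = g(0.5 * (lo + hi), nw, nh)
    rw_out[sel] = np.where(np.isfinite(rw), rw, 0.0)
    rh_out[sel] = np.where(np.isfinite(rh), rh, 0.0)
    return rw_out, rh_out


def radial_prox(w, h, lam1, lam2, a, theta):
    """Solve the reduced 2-D prox in the radii, vectorized over pairs.

    ``w`` and ``h`` are arrays of input norms ||w*||, ||e*||; returns arrays
    (r_w, r_e) of output radii in [0, w] x [0, h].
    """
    w = np.asarray(w, dtype=float)
    h = np.asarray(h, dtype=float)
    shape = w.shape
    w, h = np.atleast_1d(w), np.atleast_1d(h)

    rho = np.sqrt(w * w + h * h)
    d1 = theta - 1.0 / a
    cands = [(w, h)]  # flat region of both penalties
    if lam1 > 0 or lam2 > 0:
        zeros = np.zeros_like(w)
        # beta-level MCP active, group term flat
        if d1 > 0:
            cands.append((np.clip((theta * w - lam2) / d1, 0.0, None), h))
        # group term active, beta-level flat: uniform shrink by c;
        # with h = 0 this also covers the r_e = 0 axis pieces
        if lam1 > 0 and d1 > 0:
            c = np.clip((theta - lam1 / np.where(rho > 0, rho, 1.0)) / d1, 0.0, None)
            c = np.where(rho > 0, c, 0.0)
            cands.append((c * w, c * h))
        # both terms active: interior stationary point (covers h = 0 too)
        if lam1 > 0:
            cands.append(_case_d_root(w, h, lam1, lam2, a, theta))
        # r_w = 0 axis: optimal when theta*w <= lam2; r_e from the scalar
        # MCP prox of h under lam1 (its three pieces)
        cands.append((zeros, h))
        if d1 > 0:
            cands.append((zeros, np.clip((theta * h - lam1) / d1, 0.0, None)))
        cands.append((zeros, zeros))
        if d1 <= 0:
            # tiny a*theta: concave pieces have no interior minima; the
            # flat-region and boundary candidates above remain exhaustive
            cands.append((w, zeros))

    rw_c = np.stack([c[0] for c in cands])
    rh_c = np.stack([c[1] for c in cands])
    obj = _radial_objective(rw_c, rh_c, w[None, :], h[None, :], lam1, lam2, a, theta)
    best = obj.min(axis=0)
    # tie-break: among near-optimal candidates take the least-shrunk one
    admissible = obj <= best + _TIE_TOL
    score = np.where(admissible, rw_c + rh_c, -np.inf)
    pick = score.argmax(axis=0)
    cols = np.arange(w.size)
    return rw_c[pick, cols].reshape(shape), rh_c[pick, cols].reshape(shape)


def prox_pairs(omega_star, eta_star, lam1, lam2, a, theta):
    """Blockwise prox applied column-wise: inputs are q x N and p x N arrays."""
    w = np.linalg.norm(omega_star, axis=0)
    h = np.linalg.norm(eta_star, axis=0)
    rw, rh = radial_prox(w, h, lam1, lam2, a, theta)
    with np.errstate(divide="ignore", invalid="ignore"):
        cw = np.where(w > 0, rw / np.where(w > 0, w, 1.0), 0.0)
        ch = np.where(h > 0, rh / np.where(h > 0, h, 1.0), 0.0)
    return omega_star * cw, eta_star * ch


@dataclass(frozen=True)
class ProxProblem:
    """One instance of the (omega, eta) proximal subproblem."""

    omega_star: np.ndarray
    eta_star: np.ndarray
    lambda1: float
    lambda2: float
    theta: float = 1.0
    a: float = 3.0

    def __post_init__(self):
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("tuning values must be nonnegative")


def hierarchical_prox(problem: ProxProblem):
    """Minimize the per-pair subproblem; returns (omega, eta) vectors."""
    om, et = prox_pairs(
        np.asarray(problem.omega_star, dtype=float).reshape(-1, 1),
        np.asarray(problem.eta_star, dtype=float).reshape(-1, 1),
        problem.lambda1,
        problem.lambda2,
        problem.a,
        problem.theta,
    )
    return om.ravel(), et.ravel()
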
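"""Fuzzy c-means clustering of countries in the governance plane.

Countries are placed on two min-max normalised axes -- rule of law and trade
barrier strength, both oriented so 1 = strongest -- and soft-clustered with
the classic alternating fuzzy c-means updates: given memberships u, each
center is the u^m-weighted mean of the points; given centers, membership of
point i in cluster j is 1 / sum_k (d_ij / d_ik)^(2/(m-1)).  The objective
J = sum_ij u_ij^m ||x_i - c_j||^2 is non-increasing across iterations.

Cluster-count selection uses the fuzzy partition coefficient
PC = (1/n) sum_ij u_ij^2, which rewards crisp, well-defined partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ClusterMembership:
    points: np.ndarray          # n x 2
    centers: np.ndarray         # c x 2
    memberships: np.ndarray     # n x c, rows sum to 1
    m: float
    objective: float
    iterations: int
    converged: bool
    objective_path: np.ndarray = field(default=None, repr=False)


def normalize_axes(points) -> np.ndarray:
    """Min-max normalise each column to [0, 1]."""
    points = np.asarray(points, dtype=float)
    lo = points.min(axis=0)
    span = points.max(axis=0) - lo
    span[span == 0] = 1.0
    return (points - lo) / span


def _objective(points, centers, u, m) -> float:
    d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return float(np.sum(u**m * d2))


def fcm(
    points,
    c: int,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
) -> ClusterMembership:
    """Fuzzy c-means with seeded random (Dirichlet-row) initialisation.

    A point coinciding with a center receives crisp membership in that
    center (split equally if it coincides with several), which keeps
    duplicate-point datasets well defined.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if not (n >= c >= 2):
        raise ValueError(f"need n >= c >= 2, got n={n}, c={c}")
    if m <= 1:
        raise ValueError("fuzzifier m must exceed 1")

    rng = np.random.default_rng(seed)
    u = rng.dirichlet(np.ones(c), size=n)
    path = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        um = u**m
        centers = (um.T @ points) / um.sum(axis=0)[:, None]
        d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_u = np.empty_like(u)
        zero = d2 <= 0.0
        regular = ~zero.any(axis=1)
        with np.errstate(divide="ignore"):
            inv = d2[regular] ** (-1.0 / (m - 1.0))
        new_u[regular] = inv / inv.sum(axis=1, keepdims=True)
        coincident = ~regular
        if coincident.any():
            crisp = zero[coincident].astype(float)
            new_u[coincident] = crisp / crisp.sum(axis=1, keepdims=True)
        delta = np.abs(new_u - u).max()
        u = new_u
        path.append(_objective(points, centers, u, m))
        if delta < tol:
            converged = True
            break
    return ClusterMembership(
        points=points,
        centers=centers,
        memberships=u,
        m=m,
        objective=path[-1],
        iterations=it,
        converged=converged,
        objective_path=np.asarray(path),
    )


def partition_coefficient(memberships) -> float:
    """Fuzzy partition coefficient (1/n) sum u^2; 1 = crisp, 1/c = uniform."""
    u = np.asarray(memberships, dtype=float)
    return float((u**2).sum() / len(u))


def select_cluster_count(points, candidates, m: float = 2.0, seed: int = 0) -> int:
    """Pick the candidate c maximising the partition coefficient (ties: smaller c)."""
    candidates = sorted(set(int(c) for c in candidates))
    if not candidates:
        raise ValueError("candidate cluster counts must be non-empty")
    n = len(points)
    if candidates[0] < 2 or candidates[-1] > n - 1:
        raise ValueError(f"candidates must lie within [2, {n - 1}]")
    best_c, best_pc = None, -np.inf
    for c in candidates:
        fit = fcm(points, c=c, m=m, seed=seed)
        pc = partition_coefficient(fit.memberships)
        if pc > best_pc + 1e-12:
            best_c, best_pc = c, pc
    return best_c


def scenario_quadrant_labels(centers) -> list[str]:
    """Label centers A-D by quadrant of the (rule-of-law, barrier) unit square.

    Columns are (rule_of_law, trade_barrier), 1 = strongest; the split is at
    0.5 on each axis with ties counted as strong.  A = both strong, D = both
    weak; of the mixed quadrants, strong barriers with weak law is B and weak
    barriers with strong law is C (a documented convention -- the storyline
    scenarios define B and C by role, which a single point cannot express).
    """
    centers = np.asarray(centers, dtype=float)
    labels = []
    for law, barrier in centers:
        strong_law, strong_barrier = law >= 0.5, barrier >= 0.5
        if strong_law and strong_barrier:
            labels.append("A")
        elif strong_barrier:
            labels.append("B")
        elif strong_law:
            labels.append("C")
        else:
            labels.append("D")
    return labels
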
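"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import expit

import birdtrade as bt


def naive_clm_loglik(beta, theta, E, T):
    """Per-observation probability product, written independently of the
    packaged vectorised likelihood: cumulative logistic differences summed
    one observation at a time."""
    theta = list(theta)
    total = 0.0
    for e, t in zip(E, T):
        upper = 1.0 if t == 5 else expit(theta[t - 1] - beta * e)
        lower = 0.0 if t == 1 else expit(theta[t - 2] - beta * e)
        total += np.log(upper - lower)
    return total


def lattice_clm_mle(E, T, step=0.01, beta_bound=3.0, theta_bound=8.0, max_cycles=60):
    """Derivative-free lattice search for the CLM maximum likelihood.

    Cyclic exhaustive scans of each parameter over its 0.01-step lattice
    (thresholds constrained to stay increasing), repeated until no single
    coordinate move improves the likelihood.  Valid as a global oracle
    because the cumulative-logit log-likelihood is concave in (beta, theta).
    """
    E = np.asarray(E, float)
    T = np.asarray(T, int)

    def ll(x):
        return naive_clm_loglik(x[0], x[1:], E, T)

    from itertools import product

    x = np.array([0.0, -1.0, -0.25, 0.25, 1.0])
    best = ll(x)
    neighborhood = [np.array(d) * step for d in product((-1, 0, 1), repeat=5)]
    for _ in range(max_cycles):
        moved = False
        for i in range(5):
            if i == 0:
                grid = np.round(np.arange(-beta_bound, beta_bound + step / 2, step), 10)
            else:
                lo = x[i - 1] + step if i > 1 else -theta_bound
                hi = x[i + 1] - step if i < 4 else theta_bound
                if hi < lo:
                    continue
                grid = np.round(np.arange(lo, hi + step / 2, step), 10)
            vals = [ll(np.concatenate([x[:i], [g], x[i + 1 :]])) for g in grid]
            j = int(np.argmax(vals))
            if vals[j] > best + 1e-12:
                x[i] = grid[j]
                best = vals[j]
                moved = True
        if not moved:
            # coordinate scans stalled: examine the full +/-step neighborhood
            # (diagonal moves escape correlated ridges between thresholds)
            for d in neighborhood:
                cand = x + d
                if (np.diff(cand[1:]) <= 0).any():
                    continue
                v = ll(cand)
                if v > best + 1e-12:
                    x, best, moved = cand, v, True
                    break
            if not moved:
                break
    return x[0], x[1:], best


def simulate_clm_pairs(beta, theta, E, seed):
    """Draw ordinal categories from the CLM, independently of the generator."""
    rng = np.random.default_rng(seed)
    E = np.asarray(E, float)
    cum = expit(np.asarray(theta)[None, :] - beta * E[:, None])
    u = rng.random(len(E))
    return 1 + (u[:, None] > cum).sum(axis=1)


@pytest.fixture(scope="session")
def small_world():
    """A compact default-parameter world reused by read-only tests."""
    return bt.generate_world(bt.SyntheticWorldConfig(seed=42))


@pytest.fixture()
def trade_csv(tmp_path):
    """Write a small hand-made trade CSV and return its path."""

    def write(rows, header=None):
        header = header or (
            "Year,App.,Taxon,Class,Importer,Exporter,Origin,"
            "Importer reported quantity,Exporter reported quantity,"
            "Term,Unit,Purpose,Source"
        )
        path = tmp_path / "trade.csv"
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        return path

    return write
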
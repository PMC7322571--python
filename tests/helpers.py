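"""Independent oracles used to cross-check the ensemble engine.

The steady-state oracle finds all roots of the ODE right-hand side by a
dense multi-start Newton search (scipy's hybrid solver) from many points
spanning the attainable range, dedupes them, and classifies stability by
the eigenvalues of a finite-difference Jacobian.  It shares only the model
definition (the derivative function) with the engine, none of its
integration or clustering machinery.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from circuitscreen.engine import ParameterSet, SamplingConfig


def fd_jacobian(deriv, x: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian of ``deriv`` at ``x``."""
    n = x.size
    J = np.empty((n, n))
    for j in range(n):
        h = rel_step * max(abs(x[j]), 1.0)
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (deriv(xp) - deriv(xm)) / (2 * h)
    return J


def oracle_steady_states(
    deriv,
    params: ParameterSet,
    config: SamplingConfig,
    n_starts: int = 400,
    seed: int = 0,
    rel_tol: float = 1e-3,
):
    """All stable fixed points by dense multi-start root finding.

    Returns an (m, n_nodes) array of stable roots (positive, deduplicated
    at relative tolerance ``rel_tol``), sorted lexicographically.
    """
    rng = np.random.default_rng(seed)
    lo = 1e-3 * config.g_range[0] / config.k_range[1]
    hi = params.state_upper_bound() * 1.5
    u = rng.uniform(0.0, 1.0, (n_starts, params.n_nodes))
    starts = np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))
    # include the unregulated fixed point as a deterministic start
    starts = np.vstack([starts, params.g / params.k])

    roots: list[np.ndarray] = []
    for x0 in starts:
        sol = optimize.root(deriv, x0, method="hybr", tol=1e-12)
        x = sol.x
        if not sol.success or np.any(x <= 0) or not np.all(np.isfinite(x)):
            continue
        if np.max(np.abs(deriv(x)) / np.maximum(np.abs(x), 1.0)) > 1e-8:
            continue
        if any(np.max(np.abs(x - r) / np.maximum(r, 1e-12)) < rel_tol for r in roots):
            continue
        roots.append(x)

    stable = [r for r in roots if np.all(np.linalg.eigvals(fd_jacobian(deriv, r)).real < 0)]
    stable.sort(key=lambda s: tuple(s))
    return np.array(stable) if stable else np.empty((0, params.n_nodes))


def census_matches(engine_states: np.ndarray, oracle_states: np.ndarray, rel_tol: float = 0.005):
    """True when the two stable-state lists agree one-to-one within rel_tol."""
    if engine_states.shape[0] != oracle_states.shape[0]:
        return False
    used = set()
    for s in engine_states:
        hit = None
        for j, o in enumerate(oracle_states):
            if j in used:
                continue
            if np.max(np.abs(s - o) / np.maximum(o, 1e-12)) < rel_tol:
                hit = j
                break
        if hit is None:
            return False
        used.add(hit)
    return True
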
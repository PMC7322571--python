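"""Randomized-circuit ensemble simulation of small regulatory networks.

Each simulated "cell" is one parameter set of a shifted-Hill ODE model of a
signed network:

    dx_i/dt = g_i * prod_j H(x_j; B0_ji, n_ji, lam_ji) - k_i * x_i

where the product runs over the regulators j of node i and

    H(B) = lam + (1 - lam) / (1 + (B / B0)^n)

is the shifted Hill function: equal to 1 with no regulator, saturating at the
fold change lam (lam > 1 for activation, 0 < lam < 1 for inhibition), with
threshold B0 and cooperativity n.  Parameters are sampled uniformly from
configured ranges; each parameter set is integrated from many random initial
conditions by forward Euler to census its stable steady states, which are
then sharpened by a damped Newton polish and deduplicated in log2 space.
The ensemble of stable states across parameter sets stands in for expression
heterogeneity across a cell population.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from functools import lru_cache
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import _kernels
from .topology import ACTIVATION, RegulatoryNetwork

__all__ = [
    "SamplingConfig",
    "ParameterSet",
    "SteadyStateSearch",
    "SteadyStateEnsemble",
    "EngineError",
    "shifted_hill",
    "sample_parameters",
    "build_ode",
    "jacobian",
    "find_steady_states",
    "run_ensemble",
    "read_ensemble",
]

# internal seed for the Monte-Carlo estimate of the median unregulated level;
# fixed so that the half-functional threshold rule is part of the model, not
# of the user-visible random stream
_MEDIAN_MC_SEED = 190
_MEDIAN_MC_DRAWS = 10_000


class EngineError(RuntimeError):
    """Raised for pathological simulation configurations or inputs."""


@dataclass(frozen=True)
class SamplingConfig:
    """Parameter ranges and integration settings for an ensemble run.

    Defaults follow the randomized-circuit-perturbation convention:
    production g uniform on [1, 100] (molecules/time), degradation k uniform
    on [0.1, 1] (1/time), integer Hill coefficient on [1, 6], fold-change
    magnitude uniform on [1, 100] (reciprocal applied for inhibition), and
    thresholds drawn by the half-functional rule (see
    :func:`sample_parameters`).  Integration is forward Euler with step
    ``dt`` up to ``max_time``, stopping when the per-node relative rate
    ``|f_i| / max(|x_i|, 1)`` drops below ``conv_tol`` on every node;
    converged endpoints are merged when closer than ``state_merge_tol`` in
    log2 space.
    """

    g_range: tuple[float, float] = (1.0, 100.0)
    k_range: tuple[float, float] = (0.1, 1.0)
    n_range: tuple[int, int] = (1, 6)
    lambda_range: tuple[float, float] = (1.0, 100.0)
    threshold_spread: tuple[float, float] = (0.02, 1.98)
    n_param_sets: int = 10_000
    n_init: int = 100
    seed: int = 0
    dt: float = 0.05
    max_time: float = 200.0
    conv_tol: float = 1e-3
    state_merge_tol: float = 0.05

    def __post_init__(self) -> None:
        for name in ("g_range", "k_range", "n_range", "lambda_range", "threshold_spread"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} lower bound must be < upper bound, got {(lo, hi)}")
        if self.g_range[0] <= 0 or self.k_range[0] <= 0:
            raise ValueError("g_range and k_range lower bounds must be positive")
        if self.lambda_range[0] < 1:
            raise ValueError("lambda_range lower bound must be >= 1")
        if self.n_param_sets < 1 or self.n_init < 1:
            raise ValueError("n_param_sets and n_init must be >= 1")
        if min(self.dt, self.max_time, self.conv_tol, self.state_merge_tol) <= 0:
            raise ValueError("dt, max_time, conv_tol and state_merge_tol must be positive")

    def digest(self) -> str:
        """Stable hash of the full configuration, recorded with every run."""
        blob = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ParameterSet:
    """One sampled parameterization of a network (one simulated cell).

    Arrays are aligned with the network's node and edge declaration order:
    ``g``/``k`` per node; ``b0``/``n``/``lam`` per edge, with ``edge_src`` and
    ``edge_tgt`` holding node indices.  Activation edges carry lam > 1,
    inhibition edges 0 < lam < 1 (reciprocal of the sampled magnitude).
    """

    node_names: tuple[str, ...]
    g: np.ndarray
    k: np.ndarray
    edge_src: np.ndarray
    edge_tgt: np.ndarray
    b0: np.ndarray
    n: np.ndarray
    lam: np.ndarray

    def __post_init__(self) -> None:
        if len(self.g) != len(self.node_names) or len(self.k) != len(self.node_names):
            raise ValueError("g and k must have one entry per node")
        n_edges = len(self.edge_src)
        for name in ("edge_tgt", "b0", "n", "lam"):
            if len(getattr(self, name)) != n_edges:
                raise ValueError("edge arrays must have equal length")
        if np.any(self.b0 <= 0):
            raise ValueError("Hill thresholds must be positive")
        if np.any(self.lam <= 0):
            raise ValueError("fold changes must be positive")

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    def state_upper_bound(self) -> np.ndarray:
        """Attainable-range bound (g_i/k_i) * prod_j max(1, lam_ji) per node."""
        bound = self.g / self.k
        for e in range(len(self.edge_src)):
            bound[self.edge_tgt[e]] *= max(1.0, self.lam[e])
        return bound


@dataclass
class SteadyStateSearch:
    """Stable-state census for one parameter set."""

    states: np.ndarray  # (n_states, n_nodes), sorted lexicographically
    n_init: int
    n_converged: int
    n_unconverged: int
    n_diverged: int
    n_rescued: int

    @property
    def n_states(self) -> int:
        return self.states.shape[0]


@dataclass
class SteadyStateEnsemble:
    """Stable steady states across all sampled parameter sets.

    ``data`` holds one row per (parameter set, distinct stable state) with
    columns ``param_set``, ``state_index``, ``n_states`` and one column per
    node.  ``meta`` records seed, config digest and convergence bookkeeping;
    ``is_log2`` flags whether expression columns have been log2-transformed.
    """

    data: pd.DataFrame
    nodes: tuple[str, ...]
    config: SamplingConfig
    meta: dict
    is_log2: bool = False

    def values(self, node: str) -> np.ndarray:
        if node not in self.nodes:
            raise KeyError(f"unknown node {node!r}; ensemble columns are {list(self.nodes)}")
        return self.data[node].to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            fh.write("# circuitscreen ensemble\n")
            fh.write(f"# log2={self.is_log2}\n")
            fh.write(f"# seed={self.config.seed} config_digest={self.config.digest()}\n")
            self.data.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# shifted Hill function and parameter sampling
# ---------------------------------------------------------------------------

def shifted_hill(B, B0: float, n: int, lam: float):
    """Regulation multiplier H(B) = lam + (1 - lam) / (1 + (B/B0)^n).

    Equals 1 at B = 0, (1 + lam)/2 at B = B0, and tends to lam as B grows;
    monotone in B.  Vectorized over B.
    """
    if np.any(np.asarray(B0) <= 0):
        raise ValueError("Hill threshold B0 must be positive")
    B = np.asarray(B, dtype=float)
    out = lam + (1.0 - lam) / (1.0 + (B / B0) ** n)
    return out if out.ndim else float(out)


@lru_cache(maxsize=None)
def _median_unregulated_level(g_range: tuple, k_range: tuple) -> float:
    """Median of g/k under the configured ranges, by fixed-seed Monte Carlo."""
    rng = np.random.default_rng(_MEDIAN_MC_SEED)
    g = rng.uniform(*g_range, _MEDIAN_MC_DRAWS)
    k = rng.uniform(*k_range, _MEDIAN_MC_DRAWS)
    return float(np.median(g / k))


def sample_parameters(
    network: RegulatoryNetwork, config: SamplingConfig, rng: np.random.Generator
) -> ParameterSet:
    """Draw one uniformly sampled parameter set for ``network``.

    Production and degradation rates are uniform on their ranges; per edge,
    the Hill coefficient is an integer uniform on ``n_range`` and the
    fold-change magnitude uniform on ``lambda_range`` (its reciprocal is
    stored for inhibition edges).  Thresholds follow the half-functional
    rule: B0 uniform on ``[s_lo * M, s_hi * M]`` where M is the median
    unregulated level g/k under the configured ranges — so each link is
    functional in roughly half the ensemble.
    """
    n_nodes = network.n_nodes
    idx = {name: i for i, name in enumerate(network.nodes)}
    g = rng.uniform(*config.g_range, n_nodes)
    k = rng.uniform(*config.k_range, n_nodes)
    n_edges = network.n_edges
    n_hill = rng.integers(config.n_range[0], config.n_range[1] + 1, n_edges)
    lam_mag = rng.uniform(*config.lambda_range, n_edges)
    median_level = _median_unregulated_level(tuple(config.g_range), tuple(config.k_range))
    s_lo, s_hi = config.threshold_spread
    b0 = rng.uniform(s_lo * median_level, s_hi * median_level, n_edges)
    lam = np.where(
        np.array([e.sign == ACTIVATION for e in network.edges]), lam_mag, 1.0 / lam_mag
    )
    return ParameterSet(
        node_names=network.nodes,
        g=g,
        k=k,
        edge_src=np.array([idx[e.source] for e in network.edges], dtype=np.int64),
        edge_tgt=np.array([idx[e.target] for e in network.edges], dtype=np.int64),
        b0=b0,
        n=n_hill.astype(np.int64),
        lam=lam,
    )


# ---------------------------------------------------------------------------
# ODE assembly
# ---------------------------------------------------------------------------

def build_ode(
    network: RegulatoryNetwork, params: ParameterSet
) -> Callable[[np.ndarray], np.ndarray]:
    """Return the derivative function f(x) of the shifted-Hill ODE system.

    Nodes without regulators have the bare g - k*x form; each incoming edge
    multiplies its target's production by a shifted-Hill term.
    """
    if params.node_names != network.nodes or len(params.edge_src) != network.n_edges:
        raise ValueError("parameter set does not match the network's nodes/edges")
    g, k = params.g, params.k
    src, tgt = params.edge_src, params.edge_tgt
    b0, nh, lam = params.b0, params.n, params.lam

    def deriv(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape != g.shape:
            raise ValueError(f"state vector must have shape {g.shape}, got {x.shape}")
        f = g.copy()
        for e in range(len(src)):
            f[tgt[e]] *= lam[e] + (1.0 - lam[e]) / (1.0 + (x[src[e]] / b0[e]) ** nh[e])
        return f - k * x

    return deriv


def jacobian(x: np.ndarray, params: ParameterSet) -> np.ndarray:
    """Analytic Jacobian of the shifted-Hill system at state ``x``."""
    x = np.asarray(x, dtype=float)
    n_nodes = params.n_nodes
    src, tgt = params.edge_src, params.edge_tgt
    b0, nh, lam = params.b0, params.n, params.lam
    n_edges = len(src)
    hvals = np.empty(n_edges)
    hderiv = np.empty(n_edges)
    for e in range(n_edges):
        r = x[src[e]] / b0[e]
        rn = r ** nh[e]
        hvals[e] = lam[e] + (1.0 - lam[e]) / (1.0 + rn)
        # dH/dB = -(1 - lam) * n * r^(n-1) / (B0 * (1 + r^n)^2)
        rn1 = r ** (nh[e] - 1)
        hderiv[e] = -(1.0 - lam[e]) * nh[e] * rn1 / (b0[e] * (1.0 + rn) ** 2)
    J = np.diag(-params.k.astype(float))
    for e in range(n_edges):
        i = tgt[e]
        prod_others = params.g[i]
        for e2 in range(n_edges):
            if e2 != e and tgt[e2] == i:
                prod_others *= hvals[e2]
        J[i, src[e]] += prod_others * hderiv[e]
    return J


def is_stable(x: np.ndarray, params: ParameterSet) -> bool:
    """True when all Jacobian eigenvalues at ``x`` have negative real part."""
    eig = np.linalg.eigvals(jacobian(x, params))
    return bool(np.all(eig.real < 0))


# ---------------------------------------------------------------------------
# steady-state search
# ---------------------------------------------------------------------------

_TINY = 1e-300


def _rate_criterion(f: np.ndarray, x: np.ndarray) -> float:
    """Worst per-node relative rate |f_i| / max(|x_i|, 1)."""
    return float(np.max(np.abs(f) / np.maximum(np.abs(x), 1.0)))


def _newton_polish(
    x: np.ndarray,
    deriv: Callable[[np.ndarray], np.ndarray],
    params: ParameterSet,
    tol: float = 1e-12,
    max_iter: int = 50,
) -> np.ndarray | None:
    """Damped Newton refinement of a candidate steady state.

    Returns the refined (strictly positive, finite) root, or None when the
    iteration leaves the positive orthant, stalls, or fails to converge.
    """
    x = np.maximum(np.asarray(x, dtype=float), _TINY)
    scale = max(np.max(x), 1.0)
    for _ in range(max_iter):
        f = deriv(x)
        if np.max(np.abs(f)) / scale < tol:
            return x
        try:
            step = np.linalg.solve(jacobian(x, params), -f)
        except np.linalg.LinAlgError:
            return None
        # damp so no coordinate changes by more than a factor of 4 per step
        new = x + step
        bad = new < 0.25 * x
        if np.any(bad):
            alpha = np.min(np.where(bad, 0.75 * x / np.maximum(-step, _TINY), 1.0))
            new = x + alpha * step
        new = np.maximum(new, _TINY)
        if not np.all(np.isfinite(new)):
            return None
        x = new
        scale = max(np.max(x), 1.0)
    f = deriv(x)
    if np.max(np.abs(f)) / scale < 1e-9:
        return x
    return None


def _log2_clusters(points: np.ndarray, tol: float) -> list[np.ndarray]:
    """Greedy dedup of state vectors by Chebyshev distance in log2 space."""
    reps: list[np.ndarray] = []
    logs: list[np.ndarray] = []
    for p in points:
        lp = np.log2(np.maximum(p, _TINY))
        if not any(np.max(np.abs(lp - lq)) < tol for lq in logs):
            reps.append(p)
            logs.append(lp)
    return reps


def sample_initial_conditions(
    params: ParameterSet, config: SamplingConfig, rng: np.random.Generator
) -> np.ndarray:
    """Log-uniform initial states over the attainable range.

    Each coordinate is drawn log-uniformly on
    [1e-2 * g_min/k_max, (g_i/k_i) * prod_j max(1, lam_ji)] so that searches
    cover the reachable state space including near-zero expression.
    """
    lo = 1e-2 * config.g_range[0] / config.k_range[1]
    hi = params.state_upper_bound()
    log_lo = np.log(lo)
    log_hi = np.log(np.maximum(hi, lo * (1 + 1e-9)))
    u = rng.uniform(0.0, 1.0, (config.n_init, params.n_nodes))
    return np.exp(log_lo + u * (log_hi - log_lo))


def find_steady_states(
    deriv: Callable[[np.ndarray], np.ndarray],
    params: ParameterSet,
    config: SamplingConfig,
    rng: np.random.Generator,
) -> SteadyStateSearch:
    """Census the stable steady states of one parameter set.

    ``config.n_init`` random initial conditions are forward-Euler integrated
    until the per-node relative-rate criterion
    ``|f_i| / max(|x_i|, 1) < conv_tol`` (every node) or ``max_time``.
    Converged endpoints are deduplicated in log2 space and sharpened by a
    Newton polish (see inline notes on saddle ghosts).  Endpoints that ran
    out the clock are offered a Newton rescue: a nearby root is accepted
    only when it is verifiably stable (negative-real-part Jacobian
    spectrum) — this recovers stable states whose local relaxation rate
    exceeds the explicit-Euler stability limit for the configured step.
    Divergent (overflowing) trajectories are counted and excluded.
    """
    x0 = sample_initial_conditions(params, config, rng)
    n_steps = int(round(config.max_time / config.dt))
    endpoints, status = _kernels.euler_endpoints(
        x0,
        params.g,
        params.k,
        params.edge_src,
        params.edge_tgt,
        params.b0,
        params.n.astype(np.int64),
        params.lam,
        config.dt,
        n_steps,
        config.conv_tol,
    )
    conv = endpoints[status == _kernels.CONVERGED]
    timed_out = endpoints[status == _kernels.MAX_TIME]
    n_diverged = int(np.sum(status == _kernels.DIVERGED))

    # Polish every endpoint cluster before the final dedup.  Endpoints that
    # pass the rate criterion can still sit measurably off their root (slow
    # nodes, saddle-node ghosts), so clusters belonging to one basin only
    # merge reliably after Newton pins them to the exact root.  A polished
    # root is kept when verifiably stable; a polish that lands on an
    # unstable root exposes the endpoint as a saddle ghost and the cluster
    # is discarded; the raw endpoint is kept only when the polish fails.
    states: list[np.ndarray] = []
    for rep in _log2_clusters(conv, config.state_merge_tol):
        polished = _newton_polish(rep, deriv, params)
        if polished is None:
            states.append(rep)
        elif is_stable(polished, params):
            states.append(polished)

    n_rescued = 0
    if timed_out.shape[0]:
        accepted_logs = [np.log2(np.maximum(s, _TINY)) for s in states]
        for rep in _log2_clusters(timed_out, config.state_merge_tol):
            lp = np.log2(np.maximum(rep, _TINY))
            if any(np.max(np.abs(lp - lq)) < config.state_merge_tol for lq in accepted_logs):
                continue
            polished = _newton_polish(rep, deriv, params)
            if polished is not None and is_stable(polished, params):
                states.append(polished)
                accepted_logs.append(np.log2(polished))
                n_rescued += 1

    # final dedup, re-verification and deterministic ordering
    states = _log2_clusters(np.array(states), config.state_merge_tol) if states else []
    verified = [
        s for s in states if _rate_criterion(deriv(s), s) < config.conv_tol and np.all(s > 0)
    ]
    verified.sort(key=lambda s: tuple(s))
    return SteadyStateSearch(
        states=np.array(verified) if verified else np.empty((0, params.n_nodes)),
        n_init=config.n_init,
        n_converged=int(conv.shape[0]),
        n_unconverged=int(timed_out.shape[0]),
        n_diverged=n_diverged,
        n_rescued=n_rescued,
    )


# ---------------------------------------------------------------------------
# ensemble driver
# ---------------------------------------------------------------------------

def run_ensemble(network: RegulatoryNetwork, config: SamplingConfig) -> SteadyStateEnsemble:
    """Sample ``config.n_param_sets`` parameter sets and census their states.

    Each multistable parameter set contributes one row per distinct stable
    state (unweighted).  Fully reproducible from (network, config) including
    the seed; parameter sets whose trajectories all failed to converge are
    flagged in the metadata and contribute no rows.
    """
    rng = np.random.default_rng(config.seed)
    rows: list[np.ndarray] = []
    index_cols: list[tuple[int, int, int]] = []
    n_failed_sets = 0
    totals = {"n_converged": 0, "n_unconverged": 0, "n_diverged": 0, "n_rescued": 0}
    for ps_idx in range(config.n_param_sets):
        params = sample_parameters(network, config, rng)
        deriv = build_ode(network, params)
        search = find_steady_states(deriv, params, config, rng)
        totals["n_converged"] += search.n_converged
        totals["n_unconverged"] += search.n_unconverged
        totals["n_diverged"] += search.n_diverged
        totals["n_rescued"] += search.n_rescued
        if search.n_states == 0:
            n_failed_sets += 1
            continue
        for s_idx in range(search.n_states):
            index_cols.append((ps_idx, s_idx, search.n_states))
            rows.append(search.states[s_idx])
    if not rows:
        raise EngineError(
            "no parameter set produced a converged stable state; "
            "check integration settings (dt, max_time, conv_tol)"
        )
    data = pd.DataFrame(
        index_cols, columns=["param_set", "state_index", "n_states"]
    )
    data[list(network.nodes)] = np.array(rows)
    meta = {
        "seed": config.seed,
        "config_digest": config.digest(),
        "n_param_sets": config.n_param_sets,
        "n_failed_sets": n_failed_sets,
        **totals,
    }
    return SteadyStateEnsemble(
        data=data, nodes=network.nodes, config=config, meta=meta, is_log2=False
    )


def read_ensemble(path: str | Path) -> SteadyStateEnsemble:
    """Read an ensemble table written by :meth:`SteadyStateEnsemble.to_tsv`.

    The config digest in the file is informational; the returned ensemble
    carries a default config with the recorded seed.
    """
    path = Path(path)
    is_log2 = False
    seed = 0
    header_lines = 0
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            if line.startswith("# log2="):
                is_log2 = line.strip() == "# log2=True"
            if line.startswith("# seed="):
                seed = int(line.split()[1].split("=")[1])
    data = pd.read_csv(path, sep="\t", skiprows=header_lines)
    nodes = tuple(c for c in data.columns if c not in ("param_set", "state_index", "n_states"))
    config = replace(SamplingConfig(), seed=seed)
    return SteadyStateEnsemble(
        data=data, nodes=nodes, config=config, meta={"seed": seed}, is_log2=is_log2
    )
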
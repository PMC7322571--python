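"""Ensemble correlation statistics.

Steady-state ensembles are log2-transformed and summarized by pairwise
Pearson correlations with two-sided t-distribution significance and an
ordinary-least-squares fitted line (y on x, log2 units) — the ensemble-level
readout that links circuit structure to expected co-expression signs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .engine import SteadyStateEnsemble

DEFAULT_PAIRS = (("TWIST1", "CDH1"), ("TWIST1", "VIM"), ("TWIST1", "BUBR1"))


@dataclass(frozen=True)
class CorrelationResult:
    """Correlation between two genes with its fitted line."""

    gene_x: str
    gene_y: str
    rho: float
    p_value: float
    n: int
    method: str  # "pearson" or "irls"
    slope: float
    intercept: float


def log_transform(ensemble: SteadyStateEnsemble) -> SteadyStateEnsemble:
    """Elementwise log2 of the expression columns; metadata preserved.

    Applying the transform twice is never valid; an already-transformed
    ensemble is rejected.  Non-positive values indicate an upstream engine
    bug and are fatal.
    """
    if ensemble.is_log2:
        raise ValueError("ensemble is already log2-transformed")
    data = ensemble.data.copy()
    values = data[list(ensemble.nodes)].to_numpy()
    if not np.all(values > 0):
        raise ValueError("ensemble contains non-positive expression values")
    data[list(ensemble.nodes)] = np.log2(values)
    return replace(ensemble, data=data, is_log2=True)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with t-test significance and OLS line.

    The two-sided p-value comes from the t-distribution with n - 2 degrees
    of freedom; slope and intercept are the least-squares fit of y on x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    for name, arr in (("x", x), ("y", y)):
        if np.ptp(arr) == 0:
            raise ValueError(f"series {name} has zero variance")
    res = sps.pearsonr(x, y)
    fit = sps.linregress(x, y)
    return CorrelationResult(
        gene_x="x",
        gene_y="y",
        rho=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(x.size),
        method="pearson",
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


def correlation_report(
    ensemble: SteadyStateEnsemble,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> list[CorrelationResult]:
    """Log2-transform the ensemble and correlate each requested gene pair.

    With ``pairs=None`` the TWIST1 circuit's readout pairs are used:
    (TWIST1, CDH1), (TWIST1, VIM), (TWIST1, BUBR1).
    """
    if pairs is None:
        pairs = DEFAULT_PAIRS
    for gx, gy in pairs:
        for g in (gx, gy):
            if g not in ensemble.nodes:
                raise KeyError(
                    f"unknown gene {g!r}; ensemble columns are {list(ensemble.nodes)}"
                )
    log_ens = ensemble if ensemble.is_log2 else log_transform(ensemble)
    results = []
    for gx, gy in pairs:
        res = pearson_correlation(log_ens.values(gx), log_ens.values(gy))
        results.append(replace(res, gene_x=gx, gene_y=gy))
    return results
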
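"""Synthetic inputs with known ground truth.

Two families of test inputs are generated here: small named circuits for
the ensemble engine, and multi-cohort expression matrices for the screen.

The cohort generator emulates the statistical structure of a pan-cancer
expression compendium without attempting to reproduce any real cohort: per
cohort a latent driver level z ~ N(0, 1) is drawn per sample, the driver's
log2 expression is an affine function of z (plus an optional per-stage mean
shift), and every target gene is a * z + sqrt(1 - a^2) * noise on the
standardized scale — so the true driver-target correlation is exactly the
requested a.  Mutation burden is negative-binomial with log-mean linked to
z, and the copy-number-altered genome fraction is logit-normal linked
likewise; both are heavy-tailed by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .screen import CohortMatrix, GeneSet, default_gene_sets, write_gmt
from .topology import (
    ACTIVATION,
    INHIBITION,
    Edge,
    RegulatoryNetwork,
    twist1_emt_cin_network,
    write_topology,
)

__all__ = ["CohortRecipe", "make_toy_circuits", "generate_cohorts", "write_cohort_files"]


def make_toy_circuits() -> dict[str, RegulatoryNetwork]:
    """Named fixture circuits spanning the engine's qualitative regimes."""
    return {
        "single_node": RegulatoryNetwork(["A"], []),
        "toggle_switch": RegulatoryNetwork(
            ["A", "B"], [Edge("A", "B", INHIBITION), Edge("B", "A", INHIBITION)]
        ),
        "cascade": RegulatoryNetwork(
            ["A", "B", "C"], [Edge("A", "B", ACTIVATION), Edge("B", "C", ACTIVATION)]
        ),
        "twist1_emt_cin": twist1_emt_cin_network(),
    }


@dataclass(frozen=True)
class CohortRecipe:
    """Ground-truth description of a synthetic multi-cohort matrix.

    ``associations`` maps cohort label -> target gene -> true standardized
    driver-target correlation in [-1, 1]; unlisted pairs default to 0.
    ``stage_shift`` gives the per-stage additive shift of the driver's mean
    (log2 units), aligned with ``stages``.  ``mut_assoc`` and ``cna_assoc``
    link the latent driver level to log mutation burden and CNA fraction.
    """

    cohorts: tuple[tuple[str, int], ...] = (("COAD", 300),)
    driver: str = "TWIST1"
    targets: tuple[str, ...] = ("CDH1", "OCLN", "TJP1", "CDH2", "FN1", "SNAI1", "VIM")
    associations: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    stages: tuple[str, ...] = ("I", "II", "III", "IV")
    stage_probs: tuple[float, ...] = (0.25, 0.30, 0.25, 0.20)
    stage_shift: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    missing_stage_frac: float = 0.0
    expr_sd: float = 1.0
    mut_assoc: float = 0.0
    mut_log10_mean: float = 1.7
    mut_log10_sd: float = 0.4
    nb_dispersion: float = 1.0
    cna_assoc: float = 0.0
    cna_logit_center: float = -1.5
    cna_logit_spread: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for label, n in self.cohorts:
            if n < 1:
                raise ValueError(f"cohort {label!r} must have at least one sample")
        for label, targets in self.associations.items():
            for target, a in targets.items():
                if abs(a) > 1:
                    raise ValueError(
                        f"association {label}/{target} = {a} outside [-1, 1]"
                    )
        if len(self.stage_probs) != len(self.stages) or len(self.stage_shift) != len(
            self.stages
        ):
            raise ValueError("stage_probs and stage_shift must align with stages")
        if not 0 <= self.missing_stage_frac < 1:
            raise ValueError("missing_stage_frac must be in [0, 1)")

    def association(self, cohort: str, target: str) -> float:
        return float(self.associations.get(cohort, {}).get(target, 0.0))


def generate_cohorts(recipe: CohortRecipe) -> CohortMatrix:
    """Sample a :class:`CohortMatrix` realizing the recipe's ground truth.

    Deterministic under the recipe's seed.  Per-gene cohort baselines are
    drawn uniformly on [4, 10] log2 units, a plausible span for
    log2(normalized expression + 0.01) values.
    """
    rng = np.random.default_rng(recipe.seed)
    genes = [recipe.driver, *recipe.targets]
    expr_blocks: list[pd.DataFrame] = []
    ann_blocks: list[pd.DataFrame] = []
    for label, n in recipe.cohorts:
        baselines = rng.uniform(4.0, 10.0, len(genes))
        z = rng.standard_normal(n)
        stage_idx = rng.choice(len(recipe.stages), size=n, p=recipe.stage_probs)
        stage = np.array(recipe.stages, dtype=object)[stage_idx]
        if recipe.missing_stage_frac > 0:
            missing = rng.uniform(size=n) < recipe.missing_stage_frac
            stage = np.where(missing, None, stage)
        shift = np.array(recipe.stage_shift)[stage_idx]

        columns = {recipe.driver: baselines[0] + recipe.expr_sd * (z + shift)}
        for j, target in enumerate(recipe.targets, start=1):
            a = recipe.association(label, target)
            eps = rng.standard_normal(n)
            latent = a * z + np.sqrt(1.0 - a * a) * eps
            columns[target] = baselines[j] + recipe.expr_sd * latent

        u_mut = recipe.mut_assoc * z + np.sqrt(1.0 - recipe.mut_assoc**2) * (
            rng.standard_normal(n)
        )
        mean_mut = 10.0 ** (recipe.mut_log10_mean + recipe.mut_log10_sd * u_mut)
        r = 1.0 / recipe.nb_dispersion
        mutation_count = rng.negative_binomial(r, r / (r + mean_mut))

        u_cna = recipe.cna_assoc * z + np.sqrt(1.0 - recipe.cna_assoc**2) * (
            rng.standard_normal(n)
        )
        logit = recipe.cna_logit_center + recipe.cna_logit_spread * u_cna
        cna_fraction = 1.0 / (1.0 + np.exp(-logit))

        samples = [f"{label}-{i:05d}" for i in range(n)]
        expr_blocks.append(pd.DataFrame(columns, index=samples)[genes])
        ann_blocks.append(
            pd.DataFrame(
                {
                    "cohort": label,
                    "stage": stage,
                    "mutation_count": mutation_count,
                    "cna_fraction": cna_fraction,
                },
                index=samples,
            )
        )
    expression = pd.concat(expr_blocks)
    annotations = pd.concat(ann_blocks)
    expression.index.name = "sample"
    annotations.index.name = "sample"
    return CohortMatrix(expression, annotations)


def write_cohort_files(
    matrix: CohortMatrix,
    out_dir: str | Path,
    gene_sets: Sequence[GeneSet] | None = None,
) -> dict[str, Path]:
    """Emit the tab-delimited expression/annotation/GMT files the screen reads.

    When no gene sets are given, the built-in EMT/CIN/DSB sets are written
    restricted to genes actually present in the matrix (sets left empty by
    the restriction are omitted), so the emitted bundle is always
    self-consistent.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out_dir / "expression.tsv",
        "annotations": out_dir / "annotations.tsv",
        "gene_sets": out_dir / "gene_sets.gmt",
    }
    matrix.expression.to_csv(paths["expression"], sep="\t")
    matrix.annotations.to_csv(paths["annotations"], sep="\t")
    if gene_sets is None:
        present = set(matrix.expression.columns)
        gene_sets = []
        for gs in default_gene_sets():
            members = tuple(g for g in gs.members if g in present)
            if members:
                gene_sets.append(GeneSet(gs.name, members))
    write_gmt(gene_sets, paths["gene_sets"])
    return paths


def write_toy_circuit_files(out_dir: str | Path) -> dict[str, Path]:
    """Write every toy circuit as a topology file; returns name -> path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, net in make_toy_circuits().items():
        path = out_dir / f"{name}.topo"
        write_topology(net, path)
        paths[name] = path
    return paths
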
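"""Synthetic multi-condition expression data with planted differential
coexpression, for end-to-end testing and benchmarking.

Genes are generated from a latent-factor model.  Each block b carries one
latent factor f_b per condition; a member gene in condition k is

    x = sqrt(rho_bk) * f_b + sqrt(1 - rho_bk) * eps,     eps ~ N(0, 1)

so the expected within-block correlation is exactly rho_bk.  Couplings
prescribe the factor–factor correlation r_k per condition, giving an
expected gene-level cross-block correlation sqrt(rho_a rho_b) * r_k.
Background genes are i.i.d. standard normal.  The implied per-condition
factor correlation matrix is validated to be positive semi-definite at
construction, so impossible scenarios are rejected up front.

Two canonical scenarios mirror the archetypal differential-coexpression
patterns:

* ``scenario_a`` — a single block coexpressed in condition 1 only
  (within-module correlation loss).
* ``scenario_b`` — two blocks whose within-block correlation is conserved
  across conditions but whose block-to-block coupling disappears in
  condition 2 (module-to-module rewiring), the pattern that direct
  pairwise-change methods miss.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .dataset import UNASSIGNED, ExpressionDataset, ModuleAssignment

__all__ = [
    "Block",
    "Coupling",
    "SimulationScenario",
    "generate",
    "scenario_a",
    "scenario_b",
    "scenario_from_yaml",
]


@dataclass
class Block:
    """A planted gene block: size and within-correlation per condition."""

    size: int
    rho: Sequence[float]  # one value per condition, each in [0, 1)

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("block size must be positive")
        self.rho = tuple(float(r) for r in self.rho)
        if any(not (0.0 <= r < 1.0) for r in self.rho):
            raise ValueError(f"within-block correlations must be in [0, 1): {self.rho}")


@dataclass
class Coupling:
    """Factor-level cross correlation between two blocks, per condition."""

    block_a: int
    block_b: int
    r: Sequence[float]  # one value per condition, each in [-1, 1]

    def __post_init__(self) -> None:
        if self.block_a == self.block_b:
            raise ValueError("a coupling must link two distinct blocks")
        self.r = tuple(float(x) for x in self.r)
        if any(abs(x) > 1 for x in self.r):
            raise ValueError(f"cross correlations must be in [-1, 1]: {self.r}")


@dataclass
class SimulationScenario:
    """Full description of one synthetic dataset."""

    blocks: Sequence[Block]
    couplings: Sequence[Coupling] = ()
    n_genes_background: int = 0
    samples_per_condition: Sequence[int] = (50, 50)
    condition_labels: Sequence[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.blocks = [b if isinstance(b, Block) else Block(**b) for b in self.blocks]
        self.couplings = [
            c if isinstance(c, Coupling) else Coupling(**c) for c in self.couplings
        ]
        self.samples_per_condition = tuple(int(m) for m in self.samples_per_condition)
        n_cond = len(self.samples_per_condition)
        if n_cond < 2:
            raise ValueError("at least two conditions required")
        if any(m < 3 for m in self.samples_per_condition):
            raise ValueError("every condition needs >= 3 samples")
        if self.condition_labels is None:
            self.condition_labels = tuple(f"cond{i + 1}" for i in range(n_cond))
        else:
            self.condition_labels = tuple(self.condition_labels)
            if len(self.condition_labels) != n_cond:
                raise ValueError("condition_labels length mismatch")
        if self.n_genes_background < 0:
            raise ValueError("n_genes_background must be nonnegative")
        for b in self.blocks:
            if len(b.rho) != n_cond:
                raise ValueError("each block needs one rho per condition")
        for c in self.couplings:
            if len(c.r) != n_cond:
                raise ValueError("each coupling needs one r per condition")
            for side in (c.block_a, c.block_b):
                if not 0 <= side < len(self.blocks):
                    raise ValueError(f"coupling references unknown block {side}")
        # validate factor correlation matrices (PSD per condition)
        for k in range(n_cond if self.blocks else 0):
            R = self.factor_correlation(k)
            eig = np.linalg.eigvalsh(R)
            if eig.min() < -1e-8:
                raise ValueError(
                    f"couplings imply a non-positive-semi-definite factor "
                    f"correlation matrix in condition {self.condition_labels[k]!r} "
                    f"(min eigenvalue {eig.min():.3g})"
                )

    @property
    def n_conditions(self) -> int:
        return len(self.samples_per_condition)

    def factor_correlation(self, k: int) -> np.ndarray:
        nb = len(self.blocks)
        R = np.eye(nb)
        for c in self.couplings:
            R[c.block_a, c.block_b] = R[c.block_b, c.block_a] = c.r[k]
        return R


def generate(scenario: SimulationScenario) -> tuple[ExpressionDataset, ModuleAssignment]:
    """Sample a dataset and its ground-truth module assignment.

    Deterministic for a fixed ``scenario.seed``.  Truth labels name the
    blocks ``block1``, ``block2``, ... and background genes ``grey``.
    """
    rng = np.random.default_rng(scenario.seed)
    nb = len(scenario.blocks)
    block_sizes = [b.size for b in scenario.blocks]
    n_block_genes = sum(block_sizes)
    n_genes = n_block_genes + scenario.n_genes_background

    gene_ids, truth = [], []
    for bi, b in enumerate(scenario.blocks):
        gene_ids += [f"b{bi + 1}_g{j + 1}" for j in range(b.size)]
        truth += [f"block{bi + 1}"] * b.size
    gene_ids += [f"bg_g{j + 1}" for j in range(scenario.n_genes_background)]
    truth += [UNASSIGNED] * scenario.n_genes_background

    columns, cond_of = [], []
    blocks_X = []
    for k, (label, m) in enumerate(
        zip(scenario.condition_labels, scenario.samples_per_condition)
    ):
        columns += [f"{label}_s{j + 1}" for j in range(m)]
        cond_of += [label] * m
        X = np.empty((n_genes, m))
        if nb:
            R = scenario.factor_correlation(k)
            # eigendecomposition root: tolerant of semi-definite couplings
            w, V = np.linalg.eigh(R)
            root = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
            factors = root @ rng.standard_normal((nb, m))
            row = 0
            for bi, b in enumerate(scenario.blocks):
                rho = b.rho[k]
                noise = rng.standard_normal((b.size, m))
                X[row : row + b.size] = (
                    np.sqrt(rho) * factors[bi] + np.sqrt(1.0 - rho) * noise
                )
                row += b.size
        if scenario.n_genes_background:
            X[n_block_genes:] = rng.standard_normal(
                (scenario.n_genes_background, m)
            )
        blocks_X.append(X)

    values = pd.DataFrame(
        np.concatenate(blocks_X, axis=1), index=pd.Index(gene_ids, name="gene_id"),
        columns=pd.Index(columns, name="sample_id"),
    )
    conditions = pd.Series(cond_of, index=values.columns)
    data = ExpressionDataset(values, conditions)
    assignment = ModuleAssignment(pd.Series(truth, index=values.index, dtype=object))
    return data, assignment


def scenario_a(seed: int = 0) -> SimulationScenario:
    """One 100-gene block, within-correlation 0.8 → 0.0, 1900 background
    genes, 50 samples per condition."""
    return SimulationScenario(
        blocks=[Block(100, (0.8, 0.0))],
        n_genes_background=1900,
        samples_per_condition=(50, 50),
        seed=seed,
    )


def scenario_b(seed: int = 0) -> SimulationScenario:
    """Two 50-gene blocks with conserved within-correlation 0.7 and a
    factor-level cross correlation 0.6 → 0.0, 1900 background genes."""
    return SimulationScenario(
        blocks=[Block(50, (0.7, 0.7)), Block(50, (0.7, 0.7))],
        couplings=[Coupling(0, 1, (0.6, 0.0))],
        n_genes_background=1900,
        samples_per_condition=(50, 50),
        seed=seed,
    )


def scenario_from_yaml(path) -> SimulationScenario:
    """Load a scenario description from a YAML config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return SimulationScenario(**cfg)
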
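"""Seeded synthetic datasets with class-specific co-expression structure.

The generator embodies the modeling assumption behind the network
classifier: the two response classes differ in *which genes co-vary*, not in
marginal expression levels. Genes are partitioned into blocks; within a
class, genes in the same block load on a shared latent factor. The resistant
class uses a (partially or fully) reshuffled block assignment, so gene pairs
that co-vary in one class need not co-vary in the other, while every gene's
marginal mean and variance are identical across classes. A weak global
factor shared by all genes and both classes adds the background correlation
floor seen in real transcriptomes, so thresholding decisions face both false
edges (low thresholds) and false dismissals (high thresholds).

Per gene i in a sample s of a class with block assignment b:

    x_is = baseline_i + a_g * G_s + a_b * Z_{b(i),s} + noise_sd * eps_is

with G, Z, eps standard normal and loadings chosen so that the pairwise
Pearson correlation is ``within_block_corr`` for block mates and
``background_corr`` across blocks.

EC50 values are drawn on the −log10 molar scale around two class centers
separated by ``ec50_separation`` and mapped back to µM, so the standard
cutoff-pair labeling yields sensitive / ambiguous / resistant zones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import child_rng
from .errors import DomainError
from .io_formats import DrugResponseTable, ExpressionMatrix
from .labeling import RESISTANT, SENSITIVE, CutoffPair, clinical_cutoffs


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings; the defaults define the reference study conditions.

    noise_sd is the residual SD around the latent factors; ec50_separation is
    the gap between class EC50 centers in −log10 units; ec50_noise_sd the SD
    of per-cell-line scatter around its class center (0.3, enough to spill a
    few cell lines into the ambiguous zone as real screens do).
    """

    n_genes: int = 100
    n_per_class: int = 100
    n_blocks: int = 5
    within_block_corr: float = 0.9
    block_assignment_divergence: float = 1.0
    noise_sd: float = 1.0
    background_corr: float = 0.5
    ec50_separation: float = 1.0
    ec50_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_blocks <= self.n_genes:
            raise DomainError("need n_genes >= n_blocks >= 1")
        if not 0 < self.within_block_corr < 1:
            raise DomainError("within_block_corr must be in (0, 1)")
        if not 0 <= self.block_assignment_divergence <= 1:
            raise DomainError("block_assignment_divergence must be in [0, 1]")
        if not 0 <= self.background_corr < self.within_block_corr:
            raise DomainError("background_corr must be in [0, within_block_corr)")
        if self.noise_sd < 0 or self.ec50_noise_sd < 0:
            raise DomainError("noise SDs must be non-negative")
        if self.n_per_class < 2:
            raise DomainError("need at least 2 samples per class")


@dataclass(frozen=True)
class SyntheticDataset:
    expression: ExpressionMatrix
    responses: DrugResponseTable
    labels: pd.Series  # generating class per cell line (the ground truth)
    blocks: dict[str, np.ndarray] = field(default_factory=dict)  # class -> per-gene block
    cutoffs: CutoffPair | None = None
    drug: str = "synthetic-drug"


def _loadings(spec: SyntheticSpec) -> tuple[float, float, float]:
    rho, beta = spec.within_block_corr, spec.background_corr
    if spec.noise_sd == 0:
        # noiseless: factors carry all variance, block mates correlate at 1
        v = 1.0
        return np.sqrt(beta * v), np.sqrt((1 - beta) * v), 0.0
    v = spec.noise_sd**2 / (1 - rho)  # total per-gene variance
    return np.sqrt(beta * v), np.sqrt((rho - beta) * v), spec.noise_sd


def generate_dataset(
    spec: SyntheticSpec, cutoffs: CutoffPair | None = None
) -> SyntheticDataset:
    """Generate (expression matrix, drug responses, true labels).

    Fully reproducible from ``spec.seed``: block reshuffling, expression and
    EC50 noise each draw from independent child streams of that seed.
    """
    cutoffs = cutoffs or clinical_cutoffs(1.0, clamp_floor=None)
    rng_blocks = child_rng(spec.seed, 1)
    rng_expr = child_rng(spec.seed, 2)
    rng_ec50 = child_rng(spec.seed, 3)

    genes = [f"g{i:04d}" for i in range(spec.n_genes)]
    blocks_sens = np.arange(spec.n_genes) % spec.n_blocks
    blocks_res = blocks_sens.copy()
    n_div = round(spec.block_assignment_divergence * spec.n_genes)
    if n_div:
        moved = rng_blocks.choice(spec.n_genes, size=n_div, replace=False)
        blocks_res[moved] = rng_blocks.permutation(blocks_res[moved])
    blocks = {SENSITIVE: blocks_sens, RESISTANT: blocks_res}

    a_g, a_b, resid = _loadings(spec)
    baseline = rng_expr.normal(8.0, 2.0, size=spec.n_genes)  # shared across classes

    columns: dict[str, np.ndarray] = {}
    labels: dict[str, str] = {}
    for cls, prefix in ((RESISTANT, "R"), (SENSITIVE, "S")):
        b = blocks[cls]
        G = rng_expr.normal(size=spec.n_per_class)
        Z = rng_expr.normal(size=(spec.n_blocks, spec.n_per_class))
        eps = rng_expr.normal(size=(spec.n_genes, spec.n_per_class))
        X = baseline[:, None] + a_g * G[None, :] + a_b * Z[b, :] + resid * eps
        for s in range(spec.n_per_class):
            cell = f"{prefix}{s:04d}"
            columns[cell] = X[:, s]
            labels[cell] = cls

    expr = ExpressionMatrix(
        pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    )

    mid = 0.5 * (cutoffs.resistant + cutoffs.sensitive)
    centers = {
        SENSITIVE: mid + 0.5 * spec.ec50_separation,
        RESISTANT: mid - 0.5 * spec.ec50_separation,
    }
    records = []
    for cell in expr.cell_lines:
        score = rng_ec50.normal(centers[labels[cell]], spec.ec50_noise_sd)
        records.append(
            {"cell_line": cell, "drug": "synthetic-drug", "ec50_um": 10.0 ** (6.0 - score)}
        )
    responses = DrugResponseTable(pd.DataFrame(records))

    return SyntheticDataset(
        expression=expr,
        responses=responses,
        labels=pd.Series(labels, name="label"),
        blocks=blocks,
        cutoffs=cutoffs,
    )


def empirical_block_correlation(
    class_expr: pd.DataFrame, blocks: np.ndarray
) -> float | None:
    """Mean absolute pairwise Pearson r within blocks (generator self-check).

    ``class_expr`` is samples x genes for one class, ``blocks`` the per-gene
    block index in column order. Returns ``None`` when every block is a
    singleton (no within-block pair exists).
    """
    blocks = np.asarray(blocks)
    if blocks.shape[0] != class_expr.shape[1]:
        raise DomainError("blocks must assign one label per gene column")
    corr = np.corrcoef(class_expr.to_numpy(), rowvar=False)
    vals = []
    for b in np.unique(blocks):
        idx = np.flatnonzero(blocks == b)
        for ii in range(len(idx)):
            for jj in range(ii + 1, len(idx)):
                vals.append(abs(corr[idx[ii], idx[jj]]))
    if not vals:
        return None
    return float(np.mean(vals))
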
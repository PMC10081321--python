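"""Synthetic single-cell datasets and network pairs with known ground truth.

Two generators cover the pipeline end to end:

* :func:`simulate_dataset` draws negative-binomial counts for a population of
  cell types, each carrying a disjoint marker program.  Marker genes are
  mean-elevated in their own type (differential expression) and share a
  per-cell gamma-distributed program activity (within-program co-expression),
  the two signals every downstream statistic is built to detect.
* :func:`simulate_network_pair` plants co-expression modules in a reference
  network and produces a test network in which each gene's reference
  neighborhood survives with probability ``p`` and is otherwise rewired to
  random partners, giving a dial from no preservation (p=0) to exact
  preservation (p=1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .network import CoexpressionNetwork, rank_standardize


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cell-type world.

    Defaults give 5 cell types of 300 cells each over 2,000 genes, with 50
    disjoint marker genes per type elevated 32-fold in their own type, a
    sequencing depth of 5,000 counts per cell and moderate overdispersion —
    a small but realistically noisy droplet-style experiment.
    """

    n_cell_types: int = 5
    cells_per_type: int = 300
    n_genes: int = 2000
    markers_per_type: int = 50
    marker_fold: float = 32.0
    coactivity_sd: float = 0.7
    depth: float = 5000.0
    dispersion: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.markers_per_type * self.n_cell_types > self.n_genes:
            raise ValueError(
                "markers_per_type * n_cell_types exceeds n_genes; "
                "marker programs must be disjoint"
            )


@dataclass
class SimulatedDataset:
    """A labeled expression matrix plus its planted ground truth."""

    expression: ExpressionMatrix
    marker_map: dict[str, list[str]]
    config: SimulationConfig


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Draw one synthetic labeled dataset from the configured world.

    Counts are gamma-Poisson (negative binomial): per-cell relative rates
    are the product of lognormal base gene abundances, the cell's program
    activities (gamma, mean 1, sd ``coactivity_sd``, shared by all genes of
    a program within the cell) and the ``marker_fold`` elevation of the
    cell's own program.  Reproducible under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = np.array([f"G{i:05d}" for i in range(cfg.n_genes)], dtype=object)
    types = [f"type_{t}" for t in range(cfg.n_cell_types)]
    marker_map = {
        types[t]: list(
            genes[t * cfg.markers_per_type : (t + 1) * cfg.markers_per_type]
        )
        for t in range(cfg.n_cell_types)
    }
    program_of_gene = np.full(cfg.n_genes, -1)
    for t in range(cfg.n_cell_types):
        program_of_gene[t * cfg.markers_per_type : (t + 1) * cfg.markers_per_type] = t

    base = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)
    n_cells = cfg.n_cell_types * cfg.cells_per_type
    labels = np.repeat(types, cfg.cells_per_type)

    shape = 1.0 / (cfg.coactivity_sd**2)
    activities = rng.gamma(
        shape, scale=1.0 / shape, size=(n_cells, cfg.n_cell_types)
    )

    rates = np.tile(base, (n_cells, 1))
    in_program = program_of_gene >= 0
    rates[:, in_program] *= activities[:, program_of_gene[in_program]]
    for t, ct in enumerate(types):
        own = labels == ct
        rates[np.ix_(own, program_of_gene == t)] *= cfg.marker_fold

    rates /= rates.sum(axis=1, keepdims=True)
    lam = rates * cfg.depth
    if cfg.dispersion > 0:
        nb_shape = 1.0 / cfg.dispersion
        lam = rng.gamma(nb_shape, scale=lam / nb_shape)
    counts = rng.poisson(lam).astype(np.float64).T  # genes x cells

    meta = pd.DataFrame(
        {"cell_type": labels},
        index=pd.Index([f"cell_{i:05d}" for i in range(n_cells)], name="barcode"),
    )
    em = ExpressionMatrix(counts, genes, meta, normalized="counts")
    return SimulatedDataset(expression=em, marker_map=marker_map, config=cfg)


def simulate_network_pair(
    n_genes: int = 500,
    module_spec: dict[str, int] | None = None,
    p: float = 1.0,
    seed: int = 0,
    k: int = 10,
    background_high: float = 0.3,
    module_low: float = 0.7,
) -> tuple[CoexpressionNetwork, CoexpressionNetwork, dict[str, list[str]]]:
    """Reference/test network pair with tunable neighborhood preservation.

    The reference carries planted modules: disjoint gene blocks whose mutual
    weights are drawn from ``[module_low, 1]`` against a ``[0,
    background_high]`` background.  The test network is rebuilt from
    per-gene neighborhoods over a fresh background: each gene elevates
    either its top-k reference partners (with probability ``p``) or k random
    partners, with elevated entries max-symmetrized.  Retention draws are
    coupled across values of ``p`` under the same seed, so a gene retained
    at some p stays retained at every larger p.  Both networks are
    rank-standardized.  Returns (reference, test, module gene map).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("preservation p must lie in [0, 1]")
    if module_spec is None:
        module_spec = {"module_0": 50}
    sizes = list(module_spec.values())
    if sum(sizes) > n_genes:
        raise ValueError("planted modules exceed n_genes")

    rng = np.random.default_rng(seed)
    genes = np.array([f"G{i:05d}" for i in range(n_genes)], dtype=object)
    modules: dict[str, list[str]] = {}
    start = 0
    w = rng.uniform(0.0, background_high, size=(n_genes, n_genes))
    w = np.triu(w, 1)
    w = w + w.T
    for name, size in module_spec.items():
        idx = np.arange(start, start + size)
        modules[name] = list(genes[idx])
        block = rng.uniform(module_low, 1.0, size=(size, size))
        block = np.triu(block, 1)
        block = block + block.T
        w[np.ix_(idx, idx)] = block
        start += size
    np.fill_diagonal(w, 0.0)

    # top-k reference partners per gene (ties have measure zero here)
    masked = w.copy()
    np.fill_diagonal(masked, -np.inf)
    ref_topk = np.argsort(-masked, axis=1, kind="stable")[:, :k]

    bg = rng.uniform(0.0, background_high, size=(n_genes, n_genes))
    bg = np.triu(bg, 1)
    w_test = bg + bg.T
    retain = rng.random(n_genes) < p
    for i in range(n_genes):
        # draw regardless of retention so the rng stream is p-independent
        random_partners = rng.choice(
            np.delete(np.arange(n_genes), i), size=k, replace=False
        )
        random_vals = 1.0 + rng.uniform(0.0, 1.0, size=k)
        if retain[i]:
            partners = ref_topk[i]
            # order-preserving boost: elevated entries keep the reference
            # ordering, so a fully retained gene scores an AUROC of exactly 1
            vals = 1.0 + w[i, partners]
        else:
            partners, vals = random_partners, random_vals
        w_test[i, partners] = np.maximum(w_test[i, partners], vals)
        w_test[partners, i] = np.maximum(w_test[partners, i], vals)
    np.fill_diagonal(w_test, 0.0)

    ref = rank_standardize(w, genes)
    test = rank_standardize(w_test, genes)
    return ref, test, modules
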
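import numpy as np
import pandas as pd
import pytest

from coexqc import (
    CoexpressionNetwork,
    ExpressionMatrix,
    SimulationConfig,
    simulate_dataset,
)


def pair_counting_auroc(scores, labels) -> float:
    """Independent O(n0*n1) oracle: fraction of (positive, negative) pairs
    where the positive outranks the negative, ties counting one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated world shared across tests (3 types, 300 genes)."""
    return simulate_dataset(
        SimulationConfig(
            n_cell_types=3,
            cells_per_type=60,
            n_genes=300,
            markers_per_type=20,
            seed=7,
        )
    )


@pytest.fixture
def toy_em():
    """4 genes x 5 cells with simple counts and cell-type labels."""
    values = np.array(
        [
            [10.0, 12.0, 0.0, 1.0, 0.0],
            [0.0, 1.0, 8.0, 9.0, 10.0],
            [5.0, 5.0, 5.0, 5.0, 5.0],
            [0.0, 0.0, 0.0, 0.0, 0.0],
        ]
    )
    meta = pd.DataFrame(
        {"cell_type": ["A", "A", "B", "B", "B"]},
        index=[f"c{i}" for i in range(5)],
    )
    return ExpressionMatrix(values, np.array(["g1", "g2", "g3", "g4"], dtype=object), meta)


@pytest.fixture
def hand_network():
    """5-gene network with hand-assigned, strictly ordered weights."""
    genes = np.array(["a", "b", "c", "d", "e"], dtype=object)
    w = np.array(
        [
            [1.00, 0.90, 0.80, 0.30, 0.20],
            [0.90, 1.00, 0.70, 0.40, 0.10],
            [0.80, 0.70, 1.00, 0.60, 0.50],
            [0.30, 0.40, 0.60, 1.00, 0.15],
            [0.20, 0.10, 0.50, 0.15, 1.00],
        ]
    )
    return CoexpressionNetwork(w, genes)
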
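import numpy as np
import pandas as pd
import pytest

from blastohet import ExpressionMatrix, SimulationConfig, simulate_counts, tpm_normalize


def make_matrix(counts, lengths=None, conditions=None, stages=None):
    """Wrap a genes x cells array into an ExpressionMatrix with dummy metadata."""
    counts = np.asarray(counts)
    genes = [f"g{i}" for i in range(counts.shape[0])]
    cells = [f"c{j}" for j in range(counts.shape[1])]
    meta = pd.DataFrame(
        {
            "condition": conditions if conditions is not None else ["WT"] * len(cells),
            "stage": stages if stages is not None else [2] * len(cells),
            "embryo_id": [f"e{j}" for j in range(len(cells))],
        },
        index=pd.Index(cells, name="cell_id"),
    )
    gl = None
    if lengths is not None:
        gl = pd.Series(lengths, index=pd.Index(genes, name="gene"), name="length")
    return ExpressionMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=cells),
        cell_meta=meta,
        gene_lengths=gl,
    )


@pytest.fixture(scope="session")
def small_sim():
    """One small default-ish simulation shared across tests (WT+KO, planted subpopulation)."""
    cfg = SimulationConfig(
        seed=11,
        conditions=("WT", "KO"),
        diff_fraction={("WT", 4): 0.25, ("KO", 4): 0.0},
    )
    return simulate_counts(cfg)


@pytest.fixture(scope="session")
def small_norm(small_sim):
    matrix, _truth = small_sim
    return tpm_normalize(matrix)
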
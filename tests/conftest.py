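import numpy as np
import pandas as pd
import pytest

from gwgen import simulate
from gwgen.expression import ExpressionDataset
from gwgen.network import CandidateGWGEN, NodeRecord


@pytest.fixture
def small_truth():
    """Deterministic small ground-truth network with a few of every kind."""
    cfg = simulate.SimulationConfig(n_proteins=6, n_tfs=2, n_receptors=1,
                                    n_mirnas=2, n_lncrnas=2, seed=11)
    return simulate.generate_true_gwgen(cfg)


@pytest.fixture
def tiny_net():
    """Hand-built 5-node candidate network, one edge of each kind."""
    net = CandidateGWGEN()
    net.add_node(NodeRecord("P1", "TF", "A"))
    net.add_node(NodeRecord("P2", "protein", "B"))
    net.add_node(NodeRecord("G1", "gene", "A"))
    net.add_node(NodeRecord("M1", "miRNA", "M1"))
    net.add_node(NodeRecord("L1", "lncRNA", "L1"))
    net.add_edge("P2", "P1", "PPI")
    net.add_edge("P1", "G1", "TF_reg")
    net.add_edge("M1", "G1", "miRNA_rep")
    net.add_edge("L1", "G1", "lncRNA_reg")
    return net


def make_dataset(node_values: dict[str, np.ndarray],
                 stage: str = "young_adult") -> ExpressionDataset:
    T = len(next(iter(node_values.values())))
    df = pd.DataFrame(node_values).T
    df.columns = np.arange(T, dtype=float)
    return ExpressionDataset(stage, df)
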
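"""Principal network projection (PNP): core-network extraction by SVD.

The identified network is assembled into a system matrix H whose rows are
the regulated nodes (protein block, gene block, miRNA block, lncRNA
block) and whose columns are the possible regulators (protein/TF block,
miRNA block, lncRNA block); entries are the estimated abilities, zero
where no interaction was retained.  The energy of each singular direction
(the *eigen expression fraction* E_h = d_h^2 / sum d^2) determines the
minimal rank gamma capturing a target energy share (default 85%), and
each node is scored by the 2-norm of its row's projection onto the top
gamma right singular vectors.  Nodes with the largest projection values
form the core network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionDataset
from .network import RealGWGEN

ROW_KIND_ORDER = ("protein", "gene", "miRNA", "lncRNA")


@dataclass
class SystemMatrix:
    H: np.ndarray
    row_ids: list[str]      # protein block, gene block, miRNA block, lncRNA block
    col_ids: list[str]      # protein block, miRNA block, lncRNA block


@dataclass
class ProjectionResult:
    singular_values: np.ndarray
    eigen_fractions: np.ndarray        # E_h, summing to 1
    gamma: int                         # minimal rank reaching the energy share
    energy_threshold: float
    V: np.ndarray                      # right singular vectors (columns)
    DR: dict[str, float] = field(default_factory=dict)


@dataclass
class CoreGWGEN:
    stage: str
    node_dr: pd.DataFrame              # node_id, kind, DR, rank
    network: RealGWGEN                 # induced subnetwork

    @property
    def node_ids(self) -> set[str]:
        return set(self.node_dr["node_id"])

    def edge_set(self):
        return self.network.edge_set()


def build_system_matrix(real: RealGWGEN) -> SystemMatrix:
    """Lay out the estimated abilities in the PNP block structure."""
    kinds = {"protein": [], "gene": [], "miRNA": [], "lncRNA": []}
    for nid in sorted(real.nodes):
        node = real.nodes[nid]
        key = "protein" if node.is_protein else node.kind
        kinds[key].append(nid)
    row_ids = kinds["protein"] + kinds["gene"] + kinds["miRNA"] + kinds["lncRNA"]
    col_ids = kinds["protein"] + kinds["miRNA"] + kinds["lncRNA"]
    row_pos = {n: i for i, n in enumerate(row_ids)}
    col_pos = {n: j for j, n in enumerate(col_ids)}
    H = np.zeros((len(row_ids), len(col_ids)))
    for (reg, tgt, kind), w in real.abilities.items():
        if tgt not in row_pos or reg not in col_pos:
            raise ValueError(f"ability ({reg}->{tgt}) references an unknown node")
        H[row_pos[tgt], col_pos[reg]] = w
    return SystemMatrix(H, row_ids, col_ids)


def svd_energy(H: np.ndarray, energy_threshold: float = 0.85) -> ProjectionResult:
    """Singular spectrum, eigen expression fractions and minimal rank gamma."""
    H = np.asarray(H, dtype=float)
    if not np.all(np.isfinite(H)):
        raise ValueError("H must be finite")
    _, d, Vt = np.linalg.svd(H, full_matrices=True)
    total = float(np.sum(d ** 2))
    if total == 0.0:
        raise ValueError("all-zero system matrix: eigen fractions undefined")
    frac = d ** 2 / total
    cum = np.cumsum(frac)
    gamma = int(np.searchsorted(cum, energy_threshold - 1e-12) + 1)
    gamma = min(gamma, d.size)
    return ProjectionResult(
        singular_values=d, eigen_fractions=frac, gamma=gamma,
        energy_threshold=energy_threshold, V=Vt.T,
    )


def projection_values(sm: SystemMatrix, proj: ProjectionResult) -> dict[str, float]:
    """2-norm projection value DR(w) of every row of H onto the top-gamma
    right singular vectors."""
    NR = sm.H @ proj.V[:, :proj.gamma]
    dr = np.sqrt(np.sum(NR ** 2, axis=1))
    proj.DR = {nid: float(v) for nid, v in zip(sm.row_ids, dr)}
    return proj.DR


def pnp_project(real: RealGWGEN, energy_threshold: float = 0.85
                ) -> tuple[SystemMatrix, ProjectionResult]:
    sm = build_system_matrix(real)
    proj = svd_energy(sm.H, energy_threshold)
    projection_values(sm, proj)
    return sm, proj


def extract_core(real: RealGWGEN, DR: dict[str, float], top_n: int = 4000,
                 stage: str = "") -> CoreGWGEN:
    """Top-``top_n`` nodes by projection value (ties broken by node_id
    ascending) together with the induced subnetwork."""
    ranked = sorted(DR.items(), key=lambda kv: (-kv[1], kv[0]))
    chosen = ranked[:min(top_n, len(ranked))]
    rows = [(nid, real.nodes[nid].kind, dr, r + 1)
            for r, (nid, dr) in enumerate(chosen)]
    table = pd.DataFrame(rows, columns=["node_id", "kind", "DR", "rank"])
    return CoreGWGEN(stage, table, real.induced([nid for nid, _ in chosen]))


@dataclass
class StageComparison:
    """Differential classification of two consecutive-stage cores."""

    edges: pd.DataFrame   # source, target, kind, status in {A_only,B_only,shared}
    nodes: pd.DataFrame   # node_id, kind, status
    expression_direction: dict[str, str]  # node -> 'up'/'down'/'flat' in B vs A


def compare_stages(core_a: CoreGWGEN, core_b: CoreGWGEN,
                   expr_a: ExpressionDataset | None = None,
                   expr_b: ExpressionDataset | None = None,
                   rel_tolerance: float = 0.05) -> StageComparison:
    """Label edges and nodes as stage-A-only / stage-B-only / shared, and
    (optionally) call each node's expression direction in the later stage:
    'up'/'down' when |mean_B - mean_A| exceeds ``rel_tolerance`` times the
    earlier-stage mean magnitude, else 'flat'."""
    ea, eb = core_a.edge_set(), core_b.edge_set()
    edge_rows = [(s, t, k, "shared" if (s, t, k) in eb else "A_only")
                 for (s, t, k) in sorted(ea)]
    edge_rows += [(s, t, k, "B_only") for (s, t, k) in sorted(eb - ea)]
    na, nb = core_a.node_ids, core_b.node_ids
    all_nodes = {**core_a.network.nodes, **core_b.network.nodes}
    node_rows = []
    for nid in sorted(na | nb):
        status = "shared" if nid in na and nid in nb else (
            "A_only" if nid in na else "B_only")
        node_rows.append((nid, all_nodes[nid].kind, status))

    direction: dict[str, str] = {}
    if expr_a is not None and expr_b is not None:
        for nid in sorted(na | nb):
            if nid not in expr_a.values.index or nid not in expr_b.values.index:
                continue
            ma = float(np.mean(expr_a.trajectory(nid)))
            mb = float(np.mean(expr_b.trajectory(nid)))
            tol = rel_tolerance * max(abs(ma), 1e-12)
            if mb - ma > tol:
                direction[nid] = "up"
            elif ma - mb > tol:
                direction[nid] = "down"
            else:
                direction[nid] = "flat"
    return StageComparison(
        edges=pd.DataFrame(edge_rows, columns=["source", "target", "kind", "status"]),
        nodes=pd.DataFrame(node_rows, columns=["node_id", "kind", "status"]),
        expression_direction=direction,
    )
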
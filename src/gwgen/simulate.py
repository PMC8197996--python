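"""Ground-truth network generation and forward simulation.

The generator fabricates a typed GWGEN (proteins — some of them TFs and
receptors — their coding genes, miRNAs and lncRNAs) with known dynamic
parameters, simulates expression trajectories from the discrete-time
dynamic models the identification stage assumes, and contaminates the
true edge set with false positives so that pruning can be scored against
a known truth.

Dynamic models (one time step):

  protein i:   p(t+1) = p + sum_j alpha_ij * p * p_j - sigma*p + lam*g_i + beta + eps
  gene-like k: g(t+1) = g + sum_i a_ki * p_i - sum_r b_kr * g * m_r
                          + sum_z c_kz * o_z - mu*g + delta + eps

with sigma, lam, b, mu >= 0; miRNA and lncRNA genes follow the same
gene-type form with their own parameter sets, their node expression being
the miRNA / lncRNA abundance itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionDataset
from .network import CandidateGWGEN, NodeRecord, canonical_edge


@dataclass
class SimulationConfig:
    n_proteins: int = 10
    n_tfs: int = 3
    n_receptors: int = 2
    n_mirnas: int = 3
    n_lncrnas: int = 3
    ppi_density: float = 0.15
    tf_density: float = 0.2
    mirna_density: float = 0.15
    lncrna_density: float = 0.15
    T: int = 200
    noise_sd: float = 0.0
    seed: int = 0
    # parameter ranges (low, high); interaction signs drawn at random
    interaction_range: tuple[float, float] = (0.05, 0.2)
    decay_range: tuple[float, float] = (0.05, 0.3)
    basal_range: tuple[float, float] = (0.0, 0.1)
    translation_range: tuple[float, float] = (0.02, 0.1)
    stability_cap: float = 1e3

    def __post_init__(self) -> None:
        if self.n_tfs + self.n_receptors > self.n_proteins:
            raise ValueError("TFs plus receptors cannot exceed protein count")
        for d in (self.ppi_density, self.tf_density, self.mirna_density,
                  self.lncrna_density):
            if not 0.0 <= d <= 1.0:
                raise ValueError("edge densities must lie in [0, 1]")
        if self.T < 4:
            raise ValueError("T must be >= 4")


@dataclass
class TrueGWGEN:
    """A candidate-shaped network plus the true dynamic parameters."""

    network: CandidateGWGEN
    #: directional PPI ability: (target_protein, partner) -> alpha
    alpha: dict[tuple[str, str], float] = field(default_factory=dict)
    sigma: dict[str, float] = field(default_factory=dict)
    lam: dict[str, float] = field(default_factory=dict)
    beta: dict[str, float] = field(default_factory=dict)
    #: TF regulation: (target_gene_like, tf_protein) -> a
    a: dict[tuple[str, str], float] = field(default_factory=dict)
    #: miRNA repression: (target_gene_like, mirna) -> b >= 0
    b: dict[tuple[str, str], float] = field(default_factory=dict)
    #: lncRNA regulation: (target_gene_like, lncrna) -> c
    c: dict[tuple[str, str], float] = field(default_factory=dict)
    mu: dict[str, float] = field(default_factory=dict)
    delta: dict[str, float] = field(default_factory=dict)
    #: protein node -> its coding-gene node
    coding_gene: dict[str, str] = field(default_factory=dict)

    def validate_signs(self) -> None:
        bad = [v for v in list(self.sigma.values()) + list(self.lam.values())
               + list(self.b.values()) + list(self.mu.values()) if v < 0]
        if bad:
            raise ValueError("sign constraints violated in true parameters")


def _protein_kind(i: int, cfg: SimulationConfig) -> str:
    if i < cfg.n_tfs:
        return "TF"
    if i < cfg.n_tfs + cfg.n_receptors:
        return "receptor"
    return "protein"


def _signed(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(rng.uniform(lo, hi) * rng.choice([-1.0, 1.0]))


def generate_true_gwgen(cfg: SimulationConfig) -> TrueGWGEN:
    """Draw a typed ground-truth network; a pure function of (cfg, seed)."""
    rng = np.random.default_rng(cfg.seed)
    net = CandidateGWGEN()
    proteins = [f"P{i:03d}" for i in range(cfg.n_proteins)]
    genes = [f"G{i:03d}" for i in range(cfg.n_proteins)]
    mirnas = [f"M{i:03d}" for i in range(cfg.n_mirnas)]
    lncrnas = [f"L{i:03d}" for i in range(cfg.n_lncrnas)]
    for i, (p, g) in enumerate(zip(proteins, genes)):
        net.add_node(NodeRecord(p, _protein_kind(i, cfg), f"SYM{i:03d}"))
        net.add_node(NodeRecord(g, "gene", f"SYM{i:03d}"))
    for m in mirnas:
        net.add_node(NodeRecord(m, "miRNA", m))
    for o in lncrnas:
        net.add_node(NodeRecord(o, "lncRNA", o))

    truth = TrueGWGEN(network=net,
                      coding_gene=dict(zip(proteins, genes)))
    lo, hi = cfg.interaction_range

    # PPI edges with directional abilities on both endpoint models
    for i, pi in enumerate(proteins):
        for pj in proteins[i + 1:]:
            if rng.random() < cfg.ppi_density:
                net.add_edge(pi, pj, "PPI")
                truth.alpha[(pi, pj)] = _signed(rng, lo, hi)
                truth.alpha[(pj, pi)] = _signed(rng, lo, hi)

    tfs = proteins[:cfg.n_tfs]
    gene_like = genes + mirnas + lncrnas
    for tgt in gene_like:
        for tf in tfs:
            if rng.random() < cfg.tf_density:
                net.add_edge(tf, tgt, "TF_reg")
                truth.a[(tgt, tf)] = _signed(rng, lo, hi)
        for m in mirnas:
            if m != tgt and rng.random() < cfg.mirna_density:
                net.add_edge(m, tgt, "miRNA_rep")
                truth.b[(tgt, m)] = float(rng.uniform(lo, hi))
        for o in lncrnas:
            if o != tgt and rng.random() < cfg.lncrna_density:
                net.add_edge(o, tgt, "lncRNA_reg")
                truth.c[(tgt, o)] = _signed(rng, lo, hi)

    dlo, dhi = cfg.decay_range
    blo, bhi = cfg.basal_range
    tlo, thi = cfg.translation_range
    for p in proteins:
        truth.sigma[p] = float(rng.uniform(dlo, dhi))
        truth.lam[p] = float(rng.uniform(tlo, thi))
        truth.beta[p] = float(rng.uniform(blo, bhi))
    for g in gene_like:
        truth.mu[g] = float(rng.uniform(dlo, dhi))
        truth.delta[g] = float(rng.uniform(blo, bhi))
    truth.validate_signs()
    _apply_stability_cap(truth, cfg)
    return truth


def _apply_stability_cap(truth: TrueGWGEN, cfg: SimulationConfig,
                         max_rescales: int = 40) -> None:
    """Shrink interaction parameters until the deterministic system stays
    bounded over cfg.T steps from a mid-range initial state."""
    # bound the trajectories well inside the cap, from two independent
    # initial states, both noise-free and under a reference process noise
    # larger than typical downstream noise, so noisy runs stay bounded too
    margin_cap = min(cfg.stability_cap, 10.0)
    screen_noise = max(cfg.noise_sd, 0.05)
    for _ in range(max_rescales):
        try:
            for s in (cfg.seed, cfg.seed + 1):
                simulate_expression(truth, max(cfg.T, 500), 0.0, seed=s,
                                    stability_cap=margin_cap)
                simulate_expression(truth, max(cfg.T, 500), screen_noise,
                                    seed=s, stability_cap=margin_cap)
            return
        except RuntimeError:
            for d in (truth.alpha, truth.a, truth.b, truth.c):
                for k in d:
                    d[k] *= 0.7
    raise RuntimeError("could not stabilize the generated system; "
                       "reduce densities or interaction ranges")


def simulate_expression(truth: TrueGWGEN, T: int, noise_sd: float = 0.0,
                        seed: int = 0, stage: str = "young_adult",
                        stability_cap: float = 1e3,
                        x0: dict[str, float] | None = None) -> ExpressionDataset:
    """Iterate the dynamic models for T time points (columns 0..T-1).

    Initial expression is Uniform(0.5, 1.5) unless ``x0`` provides values;
    process noise is i.i.d. Normal(0, noise_sd^2) per node and step.
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    rng = np.random.default_rng(seed)
    net = truth.network
    node_ids = sorted(net.nodes)
    idx = {n: i for i, n in enumerate(node_ids)}
    n = len(node_ids)
    traj = np.empty((n, T))
    traj[:, 0] = rng.uniform(0.5, 1.5, size=n)
    if x0:
        for nid, v in x0.items():
            traj[idx[nid], 0] = v

    proteins = [nid for nid in node_ids if net.nodes[nid].is_protein]
    gene_like = [nid for nid in node_ids if net.nodes[nid].is_gene_like]

    # adjacency resolved to integer indices once, outside the time loop
    p_partners: dict[str, list[tuple[int, float]]] = {p: [] for p in proteins}
    for (tgt, j), al in truth.alpha.items():
        p_partners[tgt].append((idx[j], al))
    g_tfs: dict[str, list[tuple[int, float]]] = {g: [] for g in gene_like}
    g_mirs: dict[str, list[tuple[int, float]]] = {g: [] for g in gene_like}
    g_lncs: dict[str, list[tuple[int, float]]] = {g: [] for g in gene_like}
    for (tgt, tf), av in truth.a.items():
        g_tfs[tgt].append((idx[tf], av))
    for (tgt, m), bv in truth.b.items():
        g_mirs[tgt].append((idx[m], bv))
    for (tgt, o), cv in truth.c.items():
        g_lncs[tgt].append((idx[o], cv))

    for t in range(T - 1):
        x = traj[:, t]
        nxt = traj[:, t + 1]
        noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
        for p in proteins:
            i = idx[p]
            v = x[i] * (1.0 - truth.sigma[p]) + truth.beta[p]
            g = truth.coding_gene.get(p)
            if g is not None:
                v += truth.lam[p] * x[idx[g]]
            for j, al in p_partners[p]:
                v += al * x[i] * x[j]
            nxt[i] = v + noise[i]
        for gl in gene_like:
            k = idx[gl]
            v = x[k] * (1.0 - truth.mu[gl]) + truth.delta[gl]
            for j, av in g_tfs[gl]:
                v += av * x[j]
            for j, bv in g_mirs[gl]:
                v -= bv * x[k] * x[j]
            for j, cv in g_lncs[gl]:
                v += cv * x[j]
            nxt[k] = v + noise[k]
        if np.max(np.abs(nxt)) > stability_cap:
            raise RuntimeError(
                "trajectory diverged beyond the stability cap; "
                "use smaller interaction parameters or densities"
            )
    df = pd.DataFrame(traj, index=node_ids, columns=np.arange(T, dtype=float))
    return ExpressionDataset(stage, df)


def contaminate_candidate(truth: TrueGWGEN, fp_ratio: float,
                          seed: int = 0) -> tuple[CandidateGWGEN, set]:
    """Inject round(fp_ratio * |E|) random false edges of matching kinds.

    Returns the contaminated candidate network together with the true edge
    set (the truth mask) so downstream pruning can be scored.
    """
    if fp_ratio < 0:
        raise ValueError("fp_ratio must be >= 0")
    rng = np.random.default_rng(seed)
    net = truth.network
    true_edges = set(net.edges)
    n_fake = int(round(fp_ratio * len(true_edges)))

    proteins = [n.node_id for n in net.nodes_of_kind("protein", "TF", "receptor")]
    tfs = [n.node_id for n in net.nodes_of_kind("TF")]
    mirnas = [n.node_id for n in net.nodes_of_kind("miRNA")]
    lncrnas = [n.node_id for n in net.nodes_of_kind("lncRNA")]
    gene_like = [n.node_id for n in net.nodes_of_kind("gene", "miRNA", "lncRNA")]

    def possible(kind: str) -> list[tuple[str, str, str]]:
        if kind == "PPI":
            cands = [canonical_edge(a, b, kind)
                     for i, a in enumerate(proteins) for b in proteins[i + 1:]]
        elif kind == "TF_reg":
            cands = [(s, t, kind) for s in tfs for t in gene_like]
        elif kind == "miRNA_rep":
            cands = [(s, t, kind) for s in mirnas for t in gene_like if s != t]
        else:
            cands = [(s, t, kind) for s in lncrnas for t in gene_like if s != t]
        return [e for e in cands if e not in true_edges]

    kind_counts = {}
    for _, _, k in true_edges:
        kind_counts[k] = kind_counts.get(k, 0) + 1
    pool: list[tuple[str, str, str]] = []
    quotas: list[int] = []
    kinds = sorted(kind_counts)
    total = sum(kind_counts.values())
    assigned = 0
    for j, k in enumerate(kinds):
        q = (round(n_fake * sum(kind_counts[kk] for kk in kinds[:j + 1]) / total)
             - assigned)
        assigned += q
        avail = possible(k)
        if q > len(avail):
            raise ValueError(
                f"cannot inject {q} false {k} edges; only {len(avail)} non-edges"
            )
        if q > 0:
            picks = rng.choice(len(avail), size=q, replace=False)
            pool.extend(avail[i] for i in picks)

    cand = CandidateGWGEN(nodes=dict(net.nodes), edges=set(true_edges))
    for s, t, k in pool:
        cand.edges.add((s, t, k))
    return cand, true_edges
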
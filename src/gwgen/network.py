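"""Typed network containers and edge-list I/O.

A genome-wide genetic and epigenetic network (GWGEN) is the union of a
protein--protein interaction network (PPIN) and a gene regulatory network
(GRN) that includes miRNA repression and lncRNA regulation.  A *candidate*
GWGEN is presence-only (boolean edges mined from interaction databases);
the *real* GWGEN produced by system identification carries one estimated
regulatory ability per retained (regulator, target) pair.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping

NODE_KINDS = frozenset({"protein", "TF", "receptor", "miRNA", "lncRNA", "gene"})
EDGE_KINDS = frozenset({"PPI", "TF_reg", "miRNA_rep", "lncRNA_reg"})

#: protein-like node kinds (TFs and receptors are proteins with an extra role)
PROTEIN_KINDS = frozenset({"protein", "TF", "receptor"})
#: node kinds whose expression obeys the gene-type dynamic model
GENE_LIKE_KINDS = frozenset({"gene", "miRNA", "lncRNA"})


class NetworkFormatError(ValueError):
    """Malformed edge-list file or unknown node/edge kind."""


class NetworkValidationError(ValueError):
    """Structurally invalid network (duplicate ids, conflicting edges...)."""


@dataclass(frozen=True)
class NodeRecord:
    node_id: str
    kind: str
    gene_symbol: str = ""

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise NetworkFormatError(f"unknown node kind {self.kind!r}")

    @property
    def is_protein(self) -> bool:
        return self.kind in PROTEIN_KINDS

    @property
    def is_gene_like(self) -> bool:
        return self.kind in GENE_LIKE_KINDS


def canonical_edge(source: str, target: str, kind: str) -> tuple[str, str, str]:
    """Canonical key for an edge; PPI edges are undirected so their
    endpoints are stored sorted."""
    if kind not in EDGE_KINDS:
        raise NetworkFormatError(f"unknown edge kind {kind!r}")
    if kind == "PPI" and source > target:
        source, target = target, source
    return (source, target, kind)


@dataclass
class CandidateGWGEN:
    """Presence-only network over typed nodes.

    ``edges`` holds canonical (source, target, kind) triples; regulatory
    edges are directed, PPI edges undirected (endpoints sorted).
    """

    nodes: dict[str, NodeRecord] = field(default_factory=dict)
    edges: set[tuple[str, str, str]] = field(default_factory=set)

    def add_node(self, node: NodeRecord) -> None:
        existing = self.nodes.get(node.node_id)
        if existing is not None and existing != node:
            raise NetworkValidationError(
                f"conflicting records for node {node.node_id!r}: "
                f"{existing.kind} vs {node.kind}"
            )
        self.nodes[node.node_id] = node

    def add_edge(self, source: str, target: str, kind: str) -> None:
        if source not in self.nodes or target not in self.nodes:
            raise NetworkValidationError(
                f"edge ({source}, {target}) references an unknown node"
            )
        self.edges.add(canonical_edge(source, target, kind))

    def has_edge(self, source: str, target: str, kind: str) -> bool:
        return canonical_edge(source, target, kind) in self.edges

    def nodes_of_kind(self, *kinds: str) -> list[NodeRecord]:
        return sorted(
            (n for n in self.nodes.values() if n.kind in kinds),
            key=lambda n: n.node_id,
        )

    def regulators_of(self, node_id: str) -> dict[str, list[str]]:
        """Candidate regulators of ``node_id`` grouped by edge kind;
        PPI partners are reported under "PPI" regardless of stored order."""
        out: dict[str, list[str]] = {k: [] for k in sorted(EDGE_KINDS)}
        for s, t, k in self.edges:
            if k == "PPI":
                if s == node_id:
                    out[k].append(t)
                elif t == node_id:
                    out[k].append(s)
            elif t == node_id:
                out[k].append(s)
        for k in out:
            out[k].sort()
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CandidateGWGEN):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges


@dataclass
class RealGWGEN:
    """Identified network: per (regulator -> target) estimated ability.

    PPI abilities are directional estimates (the effect of partner j on
    protein i and of i on j are estimated separately), keyed by the ordered
    (regulator, target) pair; the undirected PPI edge exists if either
    direction was retained.
    """

    nodes: dict[str, NodeRecord] = field(default_factory=dict)
    #: (regulator_id, target_id, kind) -> estimated ability
    abilities: dict[tuple[str, str, str], float] = field(default_factory=dict)

    def add_ability(self, regulator: str, target: str, kind: str, weight: float) -> None:
        if kind not in EDGE_KINDS:
            raise NetworkFormatError(f"unknown edge kind {kind!r}")
        self.abilities[(regulator, target, kind)] = float(weight)

    def edge_set(self) -> set[tuple[str, str, str]]:
        """Canonical (undirected-PPI) edge set, comparable with a
        CandidateGWGEN's ``edges``."""
        return {canonical_edge(s, t, k) for (s, t, k) in self.abilities}

    def induced(self, node_ids: Iterable[str]) -> "RealGWGEN":
        keep = set(node_ids)
        sub = RealGWGEN(nodes={i: self.nodes[i] for i in keep if i in self.nodes})
        sub.abilities = {
            (s, t, k): w
            for (s, t, k), w in self.abilities.items()
            if s in keep and t in keep
        }
        return sub


_HEADER = ["source", "source_kind", "target", "target_kind", "edge_kind"]


def read_edge_list(path) -> CandidateGWGEN:
    """Read a TSV edge table into a validated CandidateGWGEN.

    Expected columns: source, source_kind, target, target_kind, edge_kind
    (an optional trailing ``weight`` column is tolerated and ignored here;
    use :func:`read_real_gwgen` to keep it).
    """
    net = CandidateGWGEN()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not set(_HEADER) <= set(reader.fieldnames):
            raise NetworkFormatError(
                f"edge list must have columns {_HEADER}, got {reader.fieldnames}"
            )
        for row in reader:
            net.add_node(NodeRecord(row["source"], row["source_kind"],
                                    row.get("gene_symbol", row["source"])))
            net.add_node(NodeRecord(row["target"], row["target_kind"],
                                    row.get("target_symbol", row["target"])))
            net.add_edge(row["source"], row["target"], row["edge_kind"])
    return net


def write_edge_list(net: CandidateGWGEN, path,
                    weights: Mapping[tuple[str, str, str], float] | None = None) -> None:
    """Write a network as a TSV edge table (round-trips with
    :func:`read_edge_list`); an optional weight map adds a weight column."""
    header = list(_HEADER) + (["weight"] if weights is not None else [])
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for s, t, k in sorted(net.edges):
            row = [s, net.nodes[s].kind, t, net.nodes[t].kind, k]
            if weights is not None:
                row.append(repr(weights.get((s, t, k), 0.0)))
            writer.writerow(row)


def write_real_gwgen(real: RealGWGEN, path) -> None:
    """Persist an identified network with its directional abilities."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_HEADER + ["weight"])
        for (s, t, k), w in sorted(real.abilities.items()):
            writer.writerow([s, real.nodes[s].kind, t, real.nodes[t].kind, k, repr(w)])


def read_real_gwgen(path) -> RealGWGEN:
    real = RealGWGEN()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "weight" not in reader.fieldnames:
            raise NetworkFormatError("real-GWGEN file needs a weight column")
        for row in reader:
            for nid, kind in ((row["source"], row["source_kind"]),
                              (row["target"], row["target_kind"])):
                if nid not in real.nodes:
                    real.nodes[nid] = NodeRecord(nid, kind, nid)
            real.add_ability(row["source"], row["target"], row["edge_kind"],
                             float(row["weight"]))
    return real
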
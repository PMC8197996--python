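"""Biomarker identification, candidate-drug filters and multi-molecule
drug assembly.

Biomarkers are differential core-network nodes that are both known
aging-associated genes and druggable targets; each carries the direction
of its abnormal expression change in the later stage.  Candidate drugs
from DTI prediction pass two filters: (1) regulation reversal — the drug
must regulate the biomarker opposite to its abnormal direction; (2)
sensitivity — the drug's cell-viability effect score must be near zero
(neither cytotoxic nor proliferative).  Surviving drugs are combined by
greedy set cover into a multiple-molecule drug targeting every biomarker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .pnp import StageComparison

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Biomarker:
    gene_symbol: str
    transition: str                 # e.g. "young_adult->middle_aged"
    abnormal_direction: str         # 'up' or 'down' in the later stage


@dataclass
class DrugCandidate:
    drug_id: str
    #: biomarker gene_symbol -> DTI interaction probability
    target_probs: dict[str, float] = field(default_factory=dict)
    #: biomarker gene_symbol -> regulation sign ('up'/'down')
    regulation: dict[str, str] = field(default_factory=dict)
    sensitivity: float | None = None
    filter_log: list[str] = field(default_factory=list)

    @property
    def covered(self) -> set[str]:
        return set(self.target_probs)

    def mean_prob(self) -> float:
        if not self.target_probs:
            return 0.0
        return sum(self.target_probs.values()) / len(self.target_probs)


@dataclass
class MultiMoleculeDrug:
    transition: str
    drugs: list[str]
    coverage: dict[str, set[str]]       # drug -> covered biomarkers
    uncovered: set[str] = field(default_factory=set)

    def dot_matrix(self, biomarkers: list[str]) -> pd.DataFrame:
        """Drug x biomarker indicator table (the dot matrix)."""
        rows = {d: {b: ("●" if b in self.coverage.get(d, set()) else "")
                    for b in biomarkers} for d in self.drugs}
        return pd.DataFrame.from_dict(rows, orient="index", columns=biomarkers)


def identify_biomarkers(diff: StageComparison, aging_genes: list[str],
                        druggable_targets: list[str],
                        transition: str = "") -> list[Biomarker]:
    """Differential core nodes that are aging genes AND druggable targets,
    with a definite expression direction in the later stage."""
    if not aging_genes or not druggable_targets:
        raise ValueError("reference gene lists must be non-empty")
    aging = set(aging_genes)
    druggable = set(druggable_targets)
    out = []
    for nid in sorted(set(diff.nodes["node_id"])):
        if nid not in aging or nid not in druggable:
            continue
        direction = diff.expression_direction.get(nid)
        if direction in (None, "flat"):
            logger.info("node %s excluded: expression change below tolerance", nid)
            continue
        out.append(Biomarker(nid, transition, direction))
    return out


def build_candidates(dti_table: pd.DataFrame) -> list[DrugCandidate]:
    """Group a DTI prediction table (candidate pairs only) per drug."""
    cands: dict[str, DrugCandidate] = {}
    for row in dti_table.itertuples():
        if hasattr(row, "candidate") and not row.candidate:
            continue
        c = cands.setdefault(row.drug_id, DrugCandidate(row.drug_id))
        c.target_probs[row.target_id] = float(row.probability)
    return [cands[d] for d in sorted(cands)]


def filter_regulation(candidates: list[DrugCandidate],
                      biomarkers: list[Biomarker],
                      regulation: pd.DataFrame) -> list[DrugCandidate]:
    """Keep only (drug, biomarker) pairings whose recorded regulation sign
    opposes the biomarker's abnormal direction; drugs with no recorded
    regulation for a biomarker lose that pairing.  Drugs retaining at
    least one pairing survive."""
    abnormal = {b.gene_symbol: b.abnormal_direction for b in biomarkers}
    signs = {(r.drug_id, r.gene_symbol): r.sign for r in regulation.itertuples()}
    out = []
    for cand in candidates:
        kept = DrugCandidate(cand.drug_id, sensitivity=cand.sensitivity,
                             filter_log=list(cand.filter_log))
        for tgt, p in cand.target_probs.items():
            direction = abnormal.get(tgt)
            sign = signs.get((cand.drug_id, tgt))
            if direction is None or sign is None:
                kept.filter_log.append(f"{tgt}: no regulation record, dropped")
                continue
            if (direction == "up" and sign == "down") or (
                    direction == "down" and sign == "up"):
                kept.target_probs[tgt] = p
                kept.regulation[tgt] = sign
            else:
                kept.filter_log.append(f"{tgt}: regulation {sign} does not "
                                       f"reverse abnormal {direction}, dropped")
        if kept.target_probs:
            out.append(kept)
    return out


def filter_sensitivity(candidates: list[DrugCandidate],
                       sensitivity: pd.DataFrame,
                       tau: float = 0.3) -> list[DrugCandidate]:
    """Keep drugs with |sensitivity score| <= tau (near-zero effect on cell
    viability); drugs without a score are dropped with a warning."""
    scores = {r.drug_id: float(r.score) for r in sensitivity.itertuples()}
    out = []
    for cand in candidates:
        score = scores.get(cand.drug_id)
        if score is None:
            logger.warning("drug %s has no sensitivity score; dropped",
                           cand.drug_id)
            continue
        if abs(score) <= tau:
            cand.sensitivity = score
            out.append(cand)
        else:
            cand.filter_log.append(f"sensitivity {score} outside +/-{tau}")
    return out


def assemble_multi_molecule_drug(candidates: list[DrugCandidate],
                                 biomarkers: list[Biomarker],
                                 transition: str = "") -> MultiMoleculeDrug:
    """Greedy set cover of the biomarkers by filtered candidate drugs.

    Repeatedly picks the drug covering the most still-uncovered biomarkers
    (ties: higher mean DTI probability, then lexicographic drug_id) until
    everything is covered or no drug adds coverage; biomarkers nobody
    targets are reported as uncovered.
    """
    targets = {b.gene_symbol for b in biomarkers}
    uncovered = set(targets)
    pool = list(candidates)
    chosen: list[str] = []
    coverage: dict[str, set[str]] = {}
    while uncovered and pool:
        best = max(
            pool,
            key=lambda c: (len(c.covered & uncovered), c.mean_prob(),
                           # lexicographically smaller id wins ties
                           tuple(-ord(ch) for ch in c.drug_id)),
        )
        gain = best.covered & uncovered
        if not gain:
            break
        chosen.append(best.drug_id)
        coverage[best.drug_id] = best.covered & targets
        uncovered -= gain
        pool.remove(best)
    return MultiMoleculeDrug(transition, chosen, coverage, uncovered)
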
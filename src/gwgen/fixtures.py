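"""Synthetic drug-design fixtures.

Stand-ins, generated at run time, for the external resources the drug
design stage consumes in real use: BindingDB-style drug/target descriptor
pairs with interaction labels, CMap-style drug regulation signatures and
PRISM-style drug sensitivity scores.  Labels follow a planted
low-dimensional rule so that learnability and filter behaviour can be
scored against a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: descriptor widths mirroring typical small-molecule / protein descriptor sets
DRUG_DESCRIPTOR_DIM = 363
TARGET_DESCRIPTOR_DIM = 996


@dataclass
class DTIFixture:
    """Drug/target descriptor tables plus planted interaction labels."""

    drug_descriptors: pd.DataFrame      # index drug_id, numeric columns
    target_descriptors: pd.DataFrame    # index target_id
    known_pairs: list[tuple[str, str]]  # positives under the planted rule
    latent_drug: pd.DataFrame           # planted factors (for oracles)
    latent_target: pd.DataFrame
    rule_noise: float
    seed: int

    def all_pairs(self) -> list[tuple[str, str]]:
        return [(d, t) for d in self.drug_descriptors.index
                for t in self.target_descriptors.index]

    def label(self, drug_id: str, target_id: str) -> int:
        return int((drug_id, target_id) in self._known_set)

    def __post_init__(self) -> None:
        self._known_set = set(self.known_pairs)


def generate_dti_fixture(n_drugs: int, n_targets: int, n_known: int,
                         rule_noise: float = 0.0, seed: int = 0,
                         latent_dim: int = 4,
                         drug_dim: int = DRUG_DESCRIPTOR_DIM,
                         target_dim: int = TARGET_DESCRIPTOR_DIM) -> DTIFixture:
    """Plant a bilinear interaction rule in descriptor space.

    Each drug and target carries a low-dimensional latent factor; a pair
    interacts iff the inner product of its factors (plus rule noise)
    exceeds the quantile threshold yielding exactly ``n_known`` positives.
    Descriptors are random linear encodings of the factors plus small
    Gaussian residue, so the rule is recoverable from descriptors alone.
    """
    if n_known > n_drugs * n_targets:
        raise ValueError("n_known exceeds the number of drug-target pairs")
    if n_known < 1:
        raise ValueError("n_known must be >= 1")
    rng = np.random.default_rng(seed)
    drugs = [f"drug{i:04d}" for i in range(n_drugs)]
    targets = [f"tgt{i:04d}" for i in range(n_targets)]

    U = rng.normal(size=(n_drugs, latent_dim))
    W = rng.normal(size=(n_targets, latent_dim))
    proj_d = rng.normal(size=(latent_dim, drug_dim)) / np.sqrt(latent_dim)
    proj_t = rng.normal(size=(latent_dim, target_dim)) / np.sqrt(latent_dim)
    D = U @ proj_d + 0.05 * rng.normal(size=(n_drugs, drug_dim))
    T = W @ proj_t + 0.05 * rng.normal(size=(n_targets, target_dim))

    score = U @ W.T
    if rule_noise > 0:
        score = score + rule_noise * rng.normal(size=score.shape)
    flat = score.ravel()
    # threshold at the n_known-th largest score
    thresh = np.partition(flat, flat.size - n_known)[flat.size - n_known]
    known = [(drugs[i], targets[j])
             for i, j in zip(*np.nonzero(score >= thresh))]
    known = known[:n_known] if len(known) > n_known else known

    return DTIFixture(
        drug_descriptors=pd.DataFrame(D, index=drugs),
        target_descriptors=pd.DataFrame(T, index=targets),
        known_pairs=known,
        latent_drug=pd.DataFrame(U, index=drugs),
        latent_target=pd.DataFrame(W, index=targets),
        rule_noise=rule_noise,
        seed=seed,
    )


@dataclass
class DrugAnnotationFixture:
    """CMap-style regulation signs and PRISM-style sensitivity scores."""

    regulation: pd.DataFrame   # columns drug_id, gene_symbol, sign ('up'/'down')
    sensitivity: pd.DataFrame  # columns drug_id, score
    good_drugs: set[str] = field(default_factory=set)  # planted truth


def generate_drug_annotations(drugs: list[str], genes: list[str],
                              planted_reversal_pattern: dict,
                              seed: int = 0) -> DrugAnnotationFixture:
    """Realize a planted regulation/sensitivity pattern exactly.

    ``planted_reversal_pattern`` maps drug_id -> dict with keys
    ``regulates`` (gene_symbol -> 'up'/'down'), ``sensitivity`` (float)
    and ``good`` (bool: should survive both downstream filters).
    Drugs absent from the pattern get random signs on a random subset of
    genes and a random benign sensitivity score (distractor background).
    """
    rng = np.random.default_rng(seed)
    reg_rows, sens_rows, good = [], [], set()
    for d in drugs:
        entry = planted_reversal_pattern.get(d)
        if entry is None:
            for g in genes:
                if rng.random() < 0.5:
                    reg_rows.append((d, g, rng.choice(["up", "down"])))
            sens_rows.append((d, float(rng.uniform(-0.2, 0.2))))
            continue
        for g, sign in entry.get("regulates", {}).items():
            if sign not in ("up", "down"):
                raise ValueError(f"regulation sign must be 'up'/'down', got {sign!r}")
            reg_rows.append((d, g, sign))
        sens_rows.append((d, float(entry.get("sensitivity", 0.0))))
        if entry.get("good"):
            good.add(d)
    seen = set()
    for d, g, _ in reg_rows:
        if (d, g) in seen:
            raise ValueError(f"duplicate regulation row for ({d}, {g})")
        seen.add((d, g))
    return DrugAnnotationFixture(
        regulation=pd.DataFrame(reg_rows,
                                columns=["drug_id", "gene_symbol", "sign"]),
        sensitivity=pd.DataFrame(sens_rows, columns=["drug_id", "score"]),
        good_drugs=good,
    )
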
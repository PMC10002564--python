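"""Synthetic DDI study generator with planted, recoverable structure.

The generator emulates the statistical shape of a DDI-event study without
any external data: drugs carry a latent chemical class, each class draws
SMILES from its own family of valid strings (so the sequence and molecular
graph carry class signal), the toy knowledge graph links every drug to its
class node (so a translational embedder can recover the classes), and the
event of a drug pair is a deterministic function of the unordered class
pair, flipped to a random other event with probability ``label_noise``.
Every channel of the downstream model therefore has learnable signal, and
the label function has a closed form a test can check against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DatasetBundle, DDIRecord, Drug, EventVocabulary, KGTriplet

__all__ = ["SynthConfig", "ConfigError", "class_pair_event_map", "generate_bundle",
           "SMILES_LIBRARY"]


class ConfigError(ValueError):
    """Infeasible synthetic-study configuration."""


@dataclass
class SynthConfig:
    """Study conditions for a synthetic bundle.

    Defaults are the desk-scale conditions used throughout the test suite:
    40 drugs in 4 latent classes, 8 event types, 5% label noise.
    """

    n_drugs: int = 40
    n_classes: int = 4
    n_events: int = 8
    label_noise: float = 0.05
    kg_noise_triplets: int = 60
    seed: int = 0

    def __post_init__(self):
        if self.n_drugs < 2 or self.n_classes < 1 or self.n_events < 1:
            raise ConfigError("need at least 2 drugs, 1 class and 1 event")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ConfigError("label_noise must be a probability")
        if self.kg_noise_triplets < 0:
            raise ConfigError("kg_noise_triplets must be nonnegative")


def _chain_family(prefix: str, suffix: str = "", n: int = 20) -> list[str]:
    return [prefix + "C" * k + suffix for k in range(n)]


# One family of ~20 valid SMILES per latent class.  Families differ in
# heteroatoms / aromaticity so tokens, graphs and lengths all separate the
# classes; strings are plain enough that validity is independent of any
# chemistry toolkit quirk (asserted once in the tests via the graph parser).
SMILES_LIBRARY: list[list[str]] = [
    ["C" * k for k in range(1, 21)],                 # alkanes
    _chain_family("OC", "O"),                        # terminal diol chains
    ["c1ccccc1" + "C" * k for k in range(20)],       # benzene + alkyl tail
    _chain_family("NC", "N"),                        # terminal diamines
    _chain_family("ClC", "Cl"),                      # terminal dichlorides
    _chain_family("COC"),                            # methyl ethers
    _chain_family("OC(=O)C"),                        # carboxylic acids
    _chain_family("SC", "S"),                        # terminal dithiols
    _chain_family("BrC"),                            # bromoalkanes
    ["c1ccncc1" + "C" * k for k in range(20)],       # pyridine + alkyl tail
]


def class_pair_event_map(n_classes: int, n_events: int) -> dict[tuple[int, int], int]:
    """Deterministic round-robin assignment of events to unordered class pairs.

    Pairs ``(a, b)`` with ``a <= b`` are enumerated lexicographically and
    the k-th pair receives event ``k mod n_events``; the map is symmetric in
    the pair and surjective onto the events whenever there are at least as
    many pairs as events.
    """
    if n_classes < 1 or n_events < 1:
        raise ConfigError("n_classes and n_events must be at least 1")
    mapping: dict[tuple[int, int], int] = {}
    k = 0
    for a in range(n_classes):
        for b in range(a, n_classes):
            mapping[(a, b)] = k % n_events
            k += 1
    return mapping


def pair_event(assignment: dict[str, int],
               mapping: dict[tuple[int, int], int],
               drug_i: str, drug_j: str) -> int:
    """Noise-free event of a drug pair under the planted label function."""
    a, b = sorted((assignment[drug_i], assignment[drug_j]))
    return mapping[(a, b)]


def generate_bundle(cfg: SynthConfig) -> tuple[DatasetBundle, dict[str, int]]:
    """Generate a bundle plus the latent class assignment that explains it.

    All randomness flows from ``cfg.seed``; two calls with equal configs
    produce identical bundles.
    """
    n_pairs = cfg.n_classes * (cfg.n_classes + 1) // 2
    if cfg.n_events > n_pairs:
        raise ConfigError(
            f"{cfg.n_events} events cannot all be planted over "
            f"{n_pairs} distinct class pairs"
        )
    if cfg.n_classes > len(SMILES_LIBRARY):
        raise ConfigError(
            f"at most {len(SMILES_LIBRARY)} classes supported by the SMILES library"
        )
    rng = np.random.default_rng(cfg.seed)

    width = max(3, len(str(cfg.n_drugs - 1)))
    drug_ids = [f"D{idx:0{width}d}" for idx in range(cfg.n_drugs)]
    assignment = {did: i % cfg.n_classes for i, did in enumerate(drug_ids)}

    drugs = [
        Drug(did, SMILES_LIBRARY[assignment[did]][
            int(rng.integers(len(SMILES_LIBRARY[assignment[did]])))])
        for did in drug_ids
    ]

    # toy KG: class-membership triplets plus uniform noise over aux entities
    triplets = [
        KGTriplet(did, "has_class", f"CLASS_{assignment[did]}") for did in drug_ids
    ]
    aux = [f"AUX_{i:02d}" for i in range(12)]
    noise_rels = ["assoc_0", "assoc_1", "assoc_2"]
    for _ in range(cfg.kg_noise_triplets):
        h = aux[int(rng.integers(len(aux)))]
        t = aux[int(rng.integers(len(aux)))]
        r = noise_rels[int(rng.integers(len(noise_rels)))]
        triplets.append(KGTriplet(h, r, t))

    mapping = class_pair_event_map(cfg.n_classes, cfg.n_events)
    events = EventVocabulary([f"event_{k}" for k in range(cfg.n_events)])
    ddis = []
    for i in range(cfg.n_drugs):
        for j in range(i + 1, cfg.n_drugs):
            ev = pair_event(assignment, mapping, drug_ids[i], drug_ids[j])
            if cfg.label_noise > 0 and rng.random() < cfg.label_noise:
                # noise redraws uniformly over all events, so the expected
                # fraction of pairs matching the planted rule is
                # (1 - p) + p / n_events
                ev = int(rng.integers(cfg.n_events))
            ddis.append(DDIRecord(drug_ids[i], drug_ids[j], ev))

    bundle = DatasetBundle(drugs, ddis, triplets, events, warnings=[])
    return bundle, assignment
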
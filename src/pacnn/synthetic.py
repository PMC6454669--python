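"""Seeded synthetic knowledge graphs with planted treatment-path signal.

Real inputs for this pipeline are a predication graph extracted from
millions of biomedical abstracts and a gold standard of drug–target–disease
triplets from a therapeutic-target database.  This module generates a
desk-scale stand-in with the same statistical shape:

* a typed directed graph over drug / target / disease / other entities with
  ``m`` opaque relation types;
* for every planted positive triplet (d, t, s), edges realising one
  designated *signal* relation path from d to t and one from t to s
  (length-2 motifs route through an intermediate "other" entity), each edge
  independently dropped with probability ``noise`` — so positives carry a
  nonzero PRA feature at the signal-path indices unless noise removed it;
* uniform random background edges superimposed at ``background_density``
  expected edges per entity, which occasionally gift a negative triplet
  some signal (label noise by construction, not prevented);
* balanced negatives drawn uniformly and rejected against the positives;
* a rediscovery benchmark: per disease one known (planted) drug hidden
  among 100 candidate drugs, plus a candidate-target pool containing the
  true targets.

Everything derives from a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .kg import KnowledgeGraph, TripletRecord, load_graph, load_triplets, save_triplets
from .pra import RelationPath, sample_negatives

__all__ = [
    "SynthConfig",
    "RediscoveryCase",
    "SynthBundle",
    "generate",
    "write_bundle",
    "load_bundle",
]


@dataclass
class SynthConfig:
    """Generator settings.

    Defaults are the package's study conditions: 120 drugs (enough for the
    100-candidate rediscovery protocol), 40 targets, 30 diseases, 100
    intermediate entities, m=8 relation types (a small-vocabulary analogue
    of the 52 extracted predication types), 200 planted positives, 10%
    edge-drop noise and 8 expected background edges per entity.
    """

    n_drugs: int = 120
    n_targets: int = 40
    n_diseases: int = 30
    n_other: int = 100
    m: int = 8
    signal_paths: tuple[RelationPath, RelationPath] = (("R1", "R2"), ("R3", "R4"))
    n_positive: int = 200
    background_density: float = 8.0
    noise: float = 0.1
    seed: int = 0
    n_rediscovery_diseases: int = 10
    n_candidates: int = 100
    n_candidate_targets: int = 10

    def __post_init__(self) -> None:
        for name in ("n_drugs", "n_targets", "n_diseases", "n_other", "m", "n_positive"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.noise < 1:
            raise ValueError("noise must be in [0, 1)")
        if self.background_density < 0:
            raise ValueError("background_density must be >= 0")
        vocab = set(self.relation_types)
        for path in self.signal_paths:
            if not set(path) <= vocab:
                raise ValueError(
                    f"signal path {path} uses relations outside the "
                    f"{self.m}-relation vocabulary"
                )
        if self.n_candidates > self.n_drugs:
            raise ValueError(
                "n_candidates exceeds n_drugs: not enough distinct candidate drugs"
            )

    @property
    def relation_types(self) -> list[str]:
        return [f"R{i + 1}" for i in range(self.m)]


@dataclass
class RediscoveryCase:
    """One disease with its known drug hidden among candidate drugs."""

    disease: str
    known_drug: str
    candidate_drugs: list[str]  # includes known_drug; length n_candidates
    candidate_targets: list[str]


@dataclass
class SynthBundle:
    config: SynthConfig
    graph: KnowledgeGraph
    positives: list[TripletRecord]
    negatives: list[TripletRecord]
    rediscovery: list[RediscoveryCase]
    planted_edges: set[tuple[str, str, str]] = field(default_factory=set)

    @property
    def labeled(self) -> list[TripletRecord]:
        return list(self.positives) + list(self.negatives)


def _realize_leg(
    src: str,
    dst: str,
    path: RelationPath,
    others: Sequence[str],
    rng: np.random.Generator,
) -> list[tuple[str, str, str]]:
    """Edges realising one signal relation path from src to dst."""
    nodes = [src]
    for _ in range(len(path) - 1):
        nodes.append(others[rng.integers(len(others))])
    nodes.append(dst)
    return [(nodes[i], rel, nodes[i + 1]) for i, rel in enumerate(path)]


def generate(cfg: SynthConfig) -> SynthBundle:
    """Generate a full bundle (graph + labelled triplets + rediscovery set)."""
    drugs = [f"D{i:03d}" for i in range(cfg.n_drugs)]
    targets = [f"T{i:03d}" for i in range(cfg.n_targets)]
    diseases = [f"S{i:03d}" for i in range(cfg.n_diseases)]
    others = [f"O{i:03d}" for i in range(cfg.n_other)]
    entities = drugs + targets + diseases + others
    relations = cfg.relation_types
    dt_path, td_path = cfg.signal_paths

    rng_pos = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    rng_noise = np.random.default_rng(np.random.SeedSequence([cfg.seed, 12]))
    rng_bg = np.random.default_rng(np.random.SeedSequence([cfg.seed, 13]))
    rng_red = np.random.default_rng(np.random.SeedSequence([cfg.seed, 14]))

    # planted positives: distinct (drug, target, disease)
    total = cfg.n_drugs * cfg.n_targets * cfg.n_diseases
    if cfg.n_positive > total:
        raise ValueError("n_positive exceeds the number of distinct triplets")
    seen: set[tuple[str, str, str]] = set()
    positives: list[TripletRecord] = []
    while len(positives) < cfg.n_positive:
        key = (
            drugs[rng_pos.integers(cfg.n_drugs)],
            targets[rng_pos.integers(cfg.n_targets)],
            diseases[rng_pos.integers(cfg.n_diseases)],
        )
        if key in seen:
            continue
        seen.add(key)
        positives.append(TripletRecord(*key, True))

    # planted signal edges, each surviving with probability 1 - noise
    planted: set[tuple[str, str, str]] = set()
    for t in positives:
        for edge in _realize_leg(t.drug, t.target, dt_path, others, rng_pos):
            if cfg.noise == 0 or rng_noise.random() >= cfg.noise:
                planted.add(edge)
        for edge in _realize_leg(t.target, t.disease, td_path, others, rng_pos):
            if cfg.noise == 0 or rng_noise.random() >= cfg.noise:
                planted.add(edge)

    # uniform background edges (no self-loops, deduplicated)
    edges: set[tuple[str, str, str]] = set(planted)
    n_bg = int(round(cfg.background_density * len(entities)))
    n_added = 0
    while n_added < n_bg:
        s = entities[rng_bg.integers(len(entities))]
        o = entities[rng_bg.integers(len(entities))]
        if s == o:
            continue
        r = relations[rng_bg.integers(cfg.m)]
        if (s, r, o) in edges:
            continue
        edges.add((s, r, o))
        n_added += 1

    edge_list = sorted(edges)  # deterministic construction order
    graph = KnowledgeGraph(edge_list, relation_vocab=relations, entities=entities)

    negatives = sample_negatives(
        positives,
        drugs,
        targets,
        diseases,
        seed=int(np.random.SeedSequence([cfg.seed, 15]).generate_state(1)[0] % 2**31),
    )

    # rediscovery benchmark: diseases that have a planted drug
    by_disease: dict[str, list[TripletRecord]] = {}
    for t in positives:
        by_disease.setdefault(t.disease, []).append(t)
    eligible = sorted(by_disease)
    n_red = min(cfg.n_rediscovery_diseases, len(eligible))
    chosen = [eligible[i] for i in rng_red.choice(len(eligible), size=n_red, replace=False)]
    rediscovery: list[RediscoveryCase] = []
    for disease in chosen:
        cases = by_disease[disease]
        known = cases[0].drug
        decoy_pool = [d for d in drugs if d != known]
        decoys = [
            decoy_pool[i]
            for i in rng_red.choice(
                len(decoy_pool), size=cfg.n_candidates - 1, replace=False
            )
        ]
        candidates = [known] + decoys
        true_targets = sorted({c.target for c in cases})
        extra_pool = [t for t in targets if t not in set(true_targets)]
        n_extra = max(0, cfg.n_candidate_targets - len(true_targets))
        extras = [
            extra_pool[i]
            for i in rng_red.choice(
                len(extra_pool), size=min(n_extra, len(extra_pool)), replace=False
            )
        ]
        rediscovery.append(
            RediscoveryCase(disease, known, candidates, true_targets + extras)
        )

    return SynthBundle(cfg, graph, positives, negatives, rediscovery, planted)


# -- file round trip ---------------------------------------------------


def write_bundle(bundle: SynthBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle as plain-text files loadable by the kg module.

    Emits ``edges.tsv``, ``relations.txt``, ``entities.txt``,
    ``triplets.tsv`` (labelled positives + negatives), ``rediscovery.tsv``
    (disease, candidate drug, known flag) and ``candidate_targets.tsv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "edges": out / "edges.tsv",
        "relations": out / "relations.txt",
        "entities": out / "entities.txt",
        "triplets": out / "triplets.tsv",
        "rediscovery": out / "rediscovery.tsv",
        "candidate_targets": out / "candidate_targets.tsv",
    }
    g = bundle.graph
    with files["edges"].open("w", encoding="utf-8") as fh:
        for s in g.entities:
            for r in g.relation_types:
                for o in g.objects(s, r):
                    fh.write(f"{s}\t{r}\t{o}\n")
    files["relations"].write_text(
        "".join(r + "\n" for r in g.relation_types), encoding="utf-8"
    )
    files["entities"].write_text(
        "".join(e + "\n" for e in g.entities), encoding="utf-8"
    )
    save_triplets(bundle.labeled, files["triplets"])
    with files["rediscovery"].open("w", encoding="utf-8") as fh:
        for case in bundle.rediscovery:
            for drug in case.candidate_drugs:
                fh.write(f"{case.disease}\t{drug}\t{int(drug == case.known_drug)}\n")
    with files["candidate_targets"].open("w", encoding="utf-8") as fh:
        for case in bundle.rediscovery:
            for t in case.candidate_targets:
                fh.write(f"{case.disease}\t{t}\n")
    return files


def load_bundle(in_dir: str | Path, config: Optional[SynthConfig] = None) -> SynthBundle:
    """Reload a written bundle (planted-edge provenance is not recoverable)."""
    d = Path(in_dir)
    graph = load_graph(
        d / "edges.tsv",
        relation_vocab_path=d / "relations.txt",
        entities_path=d / "entities.txt",
    )
    labeled = load_triplets(d / "triplets.tsv", labeled=True)
    positives = [t for t in labeled if t.label]
    negatives = [t for t in labeled if not t.label]

    cand: dict[str, list[str]] = {}
    known: dict[str, str] = {}
    for line in (d / "rediscovery.tsv").read_text(encoding="utf-8").splitlines():
        disease, drug, flag = line.split("\t")
        cand.setdefault(disease, []).append(drug)
        if flag == "1":
            known[disease] = drug
    ctargets: dict[str, list[str]] = {}
    for line in (d / "candidate_targets.tsv").read_text(encoding="utf-8").splitlines():
        disease, target = line.split("\t")
        ctargets.setdefault(disease, []).append(target)
    rediscovery = [
        RediscoveryCase(disease, known[disease], drugs, ctargets[disease])
        for disease, drugs in cand.items()
    ]
    return SynthBundle(
        config or SynthConfig(), graph, positives, negatives, rediscovery, set()
    )
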
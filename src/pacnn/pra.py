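"""Path Ranking Algorithm (PRA) relation-path features.

A *relation path* is an ordered sequence of relation types; its identity
depends only on the relations, never on the entities traversed.  For a node
pair (i, j) and path P = R_1..R_n, the PRA feature h_{i,P}(j) is the
probability that a random walk started at i, which at each step follows a
uniformly chosen out-edge of the next relation in P, ends at j:

    h_{i,()}(j)   = 1 if j == i else 0
    h_{i,P}(j)    = sum_{j'} h_{i,P'}(j') * P(j | j'; R_n)

where P' drops the final relation and P(j | j'; R_n) is uniform over the
R_n-out-neighbours of j' (0 at dead ends, so mass may be lost).  Stacking
h over the canonical enumeration of all paths up to length ``l_max`` gives
the feature vector pi of length L = sum_{t=1..l_max} m^t for m relation
types.  A drug–target–disease triplet is featurised as the concatenation
[pi_drug->target ; pi_target->disease] of length 2L.

Canonical path ordering is length-major, then lexicographic by relation
*index* in the graph's vocabulary ordering — deterministic so that feature
layouts are reusable across runs.  Inverse relations are not added to the
vocabulary (config switch deliberately absent from the default pipeline).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .kg import KnowledgeGraph, TripletRecord, UnknownEntityError

__all__ = [
    "RelationPath",
    "TripletFeature",
    "enumerate_relation_paths",
    "compute_h",
    "feature_vector",
    "triplet_features",
    "sample_negatives",
    "PathFeaturizer",
    "write_feature_matrix",
]

# A relation path is a tuple of relation ids; () is the internal base case
# and never appears as a feature.
RelationPath = tuple[str, ...]


@dataclass
class TripletFeature:
    """Concatenated PRA feature vector for one drug–target–disease case."""

    triplet: TripletRecord
    vector: np.ndarray  # shape (2L,), drug->target leg first
    label: Optional[bool] = None


def enumerate_relation_paths(
    relation_types: Sequence[str], l_max: int
) -> list[RelationPath]:
    """All relation paths of length 1..l_max in canonical order.

    Length-major, then lexicographic by relation position in
    ``relation_types``.  Returns ``m + m^2 + ... + m^l_max`` paths.
    """
    if l_max < 1:
        raise ValueError(f"l_max must be >= 1, got {l_max}")
    if not relation_types:
        raise ValueError("relation vocabulary is empty")
    paths: list[RelationPath] = []
    for length in range(1, l_max + 1):
        paths.extend(itertools.product(relation_types, repeat=length))
    return paths


def compute_h(
    g: KnowledgeGraph, source: str, path: Sequence[str]
) -> dict[str, float]:
    """Sparse walk-end distribution h_{source,path} over entities.

    The empty path returns ``{source: 1.0}``.  Entities with probability 0
    are omitted; the values sum to at most 1 (mass is dropped at dead ends).
    """
    if source not in g:
        raise UnknownEntityError(f"unknown entity {source!r}")
    dist: dict[str, float] = {source: 1.0}
    for rel in path:
        nxt: dict[str, float] = {}
        for node, p in dist.items():
            deg = g.out_degree(node, rel)
            if deg == 0:
                continue
            w = p / deg
            for obj in g.objects(node, rel):
                nxt[obj] = nxt.get(obj, 0.0) + w
        dist = nxt
        if not dist:
            break
    return dist


def feature_vector(
    g: KnowledgeGraph,
    source: str,
    target: str,
    paths: Sequence[RelationPath],
) -> np.ndarray:
    """Dense PRA feature vector: entry k is h_{source, paths[k]}(target)."""
    if target not in g:
        raise UnknownEntityError(f"unknown entity {target!r}")
    vec = np.zeros(len(paths), dtype=np.float64)
    for k, path in enumerate(paths):
        vec[k] = compute_h(g, source, path).get(target, 0.0)
    return vec


def triplet_features(
    g: KnowledgeGraph,
    triplet: TripletRecord,
    paths: Sequence[RelationPath],
) -> TripletFeature:
    """Concatenated [pi_drug->target ; pi_target->disease] feature."""
    for leg, entity in (
        ("drug", triplet.drug),
        ("target", triplet.target),
        ("disease", triplet.disease),
    ):
        if entity not in g:
            raise UnknownEntityError(
                f"{leg} entity {entity!r} of triplet {triplet.key} not in graph"
            )
    left = feature_vector(g, triplet.drug, triplet.target, paths)
    right = feature_vector(g, triplet.target, triplet.disease, paths)
    return TripletFeature(triplet, np.concatenate([left, right]), triplet.label)


class PathFeaturizer:
    """Feature extraction with per-source caching of walk distributions.

    Computing pi for many pairs that share a source (as candidate scoring
    does: one drug against many targets, one target against many diseases)
    repeats the same walk recursion; this class computes the distribution
    for every canonical path from a source once and reads feature entries
    off the cached maps.  Results are bit-identical to ``feature_vector``.
    """

    def __init__(self, g: KnowledgeGraph, l_max: int = 2):
        self.graph = g
        self.l_max = l_max
        self.paths = enumerate_relation_paths(g.relation_types, l_max)
        self._path_index = {p: k for k, p in enumerate(self.paths)}
        self._cache: dict[str, list[dict[str, float]]] = {}

    @property
    def n_features(self) -> int:
        """Per-leg feature length L = sum_t m^t."""
        return len(self.paths)

    def _distributions(self, source: str) -> list[dict[str, float]]:
        if source in self._cache:
            return self._cache[source]
        # Extend along the path trie: dist(P) derives from dist(P[:-1]).
        dists: list[dict[str, float]] = []
        by_path: dict[RelationPath, dict[str, float]] = {(): {source: 1.0}}
        for path in self.paths:
            prev = by_path[path[:-1]]
            rel = path[-1]
            nxt: dict[str, float] = {}
            for node, p in prev.items():
                deg = self.graph.out_degree(node, rel)
                if deg == 0:
                    continue
                w = p / deg
                for obj in self.graph.objects(node, rel):
                    nxt[obj] = nxt.get(obj, 0.0) + w
            if len(path) < self.l_max:
                by_path[path] = nxt
            dists.append(nxt)
        self._cache[source] = dists
        return dists

    def pair_vector(self, source: str, target: str) -> np.ndarray:
        if source not in self.graph:
            raise UnknownEntityError(f"unknown entity {source!r}")
        if target not in self.graph:
            raise UnknownEntityError(f"unknown entity {target!r}")
        dists = self._distributions(source)
        vec = np.zeros(len(self.paths), dtype=np.float64)
        for k, dist in enumerate(dists):
            vec[k] = dist.get(target, 0.0)
        return vec

    def triplet_vector(self, triplet: TripletRecord) -> TripletFeature:
        for leg, entity in (
            ("drug", triplet.drug),
            ("target", triplet.target),
            ("disease", triplet.disease),
        ):
            if entity not in self.graph:
                raise UnknownEntityError(
                    f"{leg} entity {entity!r} of triplet {triplet.key} not in graph"
                )
        vec = np.concatenate(
            [
                self.pair_vector(triplet.drug, triplet.target),
                self.pair_vector(triplet.target, triplet.disease),
            ]
        )
        return TripletFeature(triplet, vec, triplet.label)

    def featurize(self, triplets: Sequence[TripletRecord]) -> list[TripletFeature]:
        return [self.triplet_vector(t) for t in triplets]

    def clear_cache(self) -> None:
        self._cache.clear()


def sample_negatives(
    positives: Sequence[TripletRecord],
    drug_pool: Sequence[str],
    target_pool: Sequence[str],
    disease_pool: Sequence[str],
    seed: int,
    n: Optional[int] = None,
) -> list[TripletRecord]:
    """Uniform negative triplets disjoint from the positive set.

    Draws (drug, target, disease) uniformly over the pool product, rejecting
    positives and duplicates, until ``n`` (default: as many as positives)
    negatives are collected.  Deterministic for a fixed seed.
    """
    n = len(positives) if n is None else n
    if n == 0:
        return []
    pos_keys = {p.key for p in positives}
    total = len(drug_pool) * len(target_pool) * len(disease_pool)
    available = total - sum(
        1
        for k in pos_keys
        if k[0] in set(drug_pool) and k[1] in set(target_pool) and k[2] in set(disease_pool)
    )
    if available < n:
        raise ValueError(
            f"candidate pools admit only {available} non-positive triplets, "
            f"need {n}"
        )
    rng = np.random.default_rng(seed)
    negatives: list[TripletRecord] = []
    seen: set[tuple[str, str, str]] = set()
    while len(negatives) < n:
        d = drug_pool[rng.integers(len(drug_pool))]
        t = target_pool[rng.integers(len(target_pool))]
        s = disease_pool[rng.integers(len(disease_pool))]
        key = (d, t, s)
        if key in pos_keys or key in seen:
            continue
        seen.add(key)
        negatives.append(TripletRecord(d, t, s, False))
    return negatives


def path_name(path: RelationPath) -> str:
    return "|".join(path)


def write_feature_matrix(
    features: Sequence[TripletFeature],
    paths: Sequence[RelationPath],
    path_out: str | Path,
) -> None:
    """TSV feature matrix: one row per triplet, one column per path feature.

    Columns are ``drug, target, disease``, then ``dt:<path>`` for the
    drug->target leg and ``td:<path>`` for the target->disease leg, then
    ``label`` (empty when unlabelled).
    """
    header = (
        ["drug", "target", "disease"]
        + [f"dt:{path_name(p)}" for p in paths]
        + [f"td:{path_name(p)}" for p in paths]
        + ["label"]
    )
    with Path(path_out).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for f in features:
            t = f.triplet
            lab = "" if f.label is None else str(int(f.label))
            vals = "\t".join(repr(float(v)) for v in f.vector)
            fh.write(f"{t.drug}\t{t.target}\t{t.disease}\t{vals}\t{lab}\n")
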
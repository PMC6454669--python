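"""Shared fixtures and independent brute-force oracles.

The oracles enumerate every walk explicitly and never touch the recursive
implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from pacnn.kg import KnowledgeGraph

G1_EDGES = [("A", "r1", "B"), ("A", "r1", "C"), ("B", "r2", "D"), ("C", "r2", "D")]


@pytest.fixture
def g1() -> KnowledgeGraph:
    """Diamond fixture: A -r1-> {B, C} -r2-> D."""
    return KnowledgeGraph(G1_EDGES)


# -- independent oracles ----------------------------------------------


def oracle_h(g: KnowledgeGraph, source: str, path: tuple[str, ...]) -> dict[str, float]:
    """Typed-walk enumeration: sum of products of uniform step probabilities."""
    endpoints: dict[str, float] = {}
    stack = [(source, 0, 1.0)]
    while stack:
        node, depth, prob = stack.pop()
        if depth == len(path):
            endpoints[node] = endpoints.get(node, 0.0) + prob
            continue
        rel = path[depth]
        objs = g.objects(node, rel)
        if not objs:
            continue  # dead end: mass dropped
        for obj in objs:
            stack.append((obj, depth + 1, prob / len(objs)))
    return endpoints


def oracle_walk_prob(g: KnowledgeGraph, source: str, target: str, t: int) -> float:
    """Untyped-walk enumeration of the t-step reach probability."""
    total = 0.0
    stack = [(source, 0, 1.0)]
    while stack:
        node, depth, prob = stack.pop()
        if depth == t:
            if node == target:
                total += prob
            continue
        nbrs = sorted(g.out_neighbors(node))
        if not nbrs:
            continue
        for nbr in nbrs:
            stack.append((nbr, depth + 1, prob / len(nbrs)))
    return total


def random_graph(
    rng: np.random.Generator,
    n_nodes: int = 8,
    n_edges: int = 40,
    n_relations: int = 3,
) -> KnowledgeGraph:
    """Random typed graph for oracle-equivalence checks."""
    nodes = [f"n{i}" for i in range(n_nodes)]
    rels = [f"r{i}" for i in range(n_relations)]
    edges = set()
    attempts = 0
    while len(edges) < n_edges and attempts < 20 * n_edges:
        attempts += 1
        edges.add(
            (
                nodes[rng.integers(n_nodes)],
                rels[rng.integers(n_relations)],
                nodes[rng.integers(n_nodes)],
            )
        )
    return KnowledgeGraph(sorted(edges), relation_vocab=rels, entities=nodes)
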
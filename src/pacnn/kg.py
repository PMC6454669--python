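"""Typed knowledge-graph container and edge-list / triplet-file I/O.

The graph is a set of directed, typed edges ``(subject, relation, object)``
over opaque string entity identifiers, as produced by predication extraction
from biomedical text (e.g. ``Triamterene TREATS Edema``).  All downstream
feature extraction (relation-path random walks, Markov-chain baselines)
builds on the elementary queries defined here.

Conventions:

* entity identifiers are case-sensitive opaque strings; no vocabulary
  normalisation is attempted;
* multi-edges collapse to a single edge and edges carry no weights — the
  random-walk transition probability out of a node is uniform over its
  out-neighbours under the given relation;
* a node with no outgoing edge of a relation is a dead end for that
  relation: the transition probability is defined as 0, so walk mass is
  silently dropped rather than raising.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "KnowledgeGraph",
    "TripletRecord",
    "GraphFormatError",
    "UnknownEntityError",
    "load_graph",
    "save_graph",
    "load_triplets",
    "save_triplets",
]


class GraphFormatError(ValueError):
    """Raised for malformed edge-list or triplet files."""


class UnknownEntityError(KeyError):
    """Raised when a query names an entity or relation absent from the graph."""


@dataclass(frozen=True)
class TripletRecord:
    """A drug–target–disease case, optionally labelled.

    ``label`` is ``True`` for a known therapeutic triplet (gold standard),
    ``False`` for a sampled negative, and ``None`` for unlabelled candidate
    cases.  Entity resolution against a graph happens when features are
    requested, not at load time.
    """

    drug: str
    target: str
    disease: str
    label: Optional[bool] = None

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.drug, self.target, self.disease)


class KnowledgeGraph:
    """Directed typed multigraph with deduplicated edges.

    Parameters
    ----------
    edges
        Iterable of ``(subject, relation, object)`` string triples.
    relation_vocab
        Optional explicit relation ordering.  The feature-vector layout of
        every downstream module depends on this ordering, so it is fixed at
        construction: either the supplied vocabulary or first-appearance
        order in ``edges``.  Relations in the vocabulary that never occur in
        an edge are kept (they contribute all-zero feature entries).
    entities
        Optional entity pre-registration (fixes index order and keeps
        isolated entities, e.g. candidate drugs with no extracted
        predications, as graph members).
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str, str]],
        relation_vocab: Optional[Sequence[str]] = None,
        entities: Optional[Sequence[str]] = None,
    ) -> None:
        self._entities: list[str] = []
        self._entity_index: dict[str, int] = {}
        self._relations: list[str] = []
        self._relation_index: dict[str, int] = {}
        self._edges: set[tuple[str, str, str]] = set()
        # (subject, relation) -> objects in insertion order
        self._fwd: dict[tuple[str, str], list[str]] = {}
        # subject -> all out-neighbours, relation-agnostic
        self._out: dict[str, set[str]] = {}

        if entities is not None:
            for e in entities:
                self._add_entity(e)
        if relation_vocab is not None:
            for r in relation_vocab:
                self._add_relation(r)
            self._vocab_locked = True
        else:
            self._vocab_locked = False

        n_dup = 0
        for s, r, o in edges:
            if (s, r, o) in self._edges:
                n_dup += 1
                continue
            self._add_entity(s)
            self._add_entity(o)
            if r not in self._relation_index:
                if self._vocab_locked:
                    raise GraphFormatError(
                        f"relation {r!r} not in the supplied vocabulary"
                    )
                self._add_relation(r)
            self._edges.add((s, r, o))
            self._fwd.setdefault((s, r), []).append(o)
            self._out.setdefault(s, set()).add(o)
        if n_dup:
            logger.warning("dropped %d duplicate edge(s)", n_dup)

    def _add_entity(self, e: str) -> None:
        if e not in self._entity_index:
            self._entity_index[e] = len(self._entities)
            self._entities.append(e)

    def _add_relation(self, r: str) -> None:
        if r not in self._relation_index:
            self._relation_index[r] = len(self._relations)
            self._relations.append(r)

    # -- introspection -------------------------------------------------

    @property
    def entities(self) -> list[str]:
        """Entity identifiers in first-appearance order."""
        return list(self._entities)

    @property
    def relation_types(self) -> list[str]:
        """Relation vocabulary in canonical (feature-layout) order."""
        return list(self._relations)

    @property
    def n_entities(self) -> int:
        return len(self._entities)

    @property
    def n_relations(self) -> int:
        return len(self._relations)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def edges(self) -> set[tuple[str, str, str]]:
        return set(self._edges)

    def __contains__(self, entity: str) -> bool:
        return entity in self._entity_index

    def entity_index(self, entity: str) -> int:
        try:
            return self._entity_index[entity]
        except KeyError:
            raise UnknownEntityError(f"unknown entity {entity!r}") from None

    def has_edge(self, subject: str, relation: str, obj: str) -> bool:
        return (subject, relation, obj) in self._edges

    # -- elementary queries --------------------------------------------

    def objects(self, subject: str, relation: str) -> list[str]:
        """Out-neighbours of ``subject`` under ``relation`` (may be empty)."""
        return self._fwd.get((subject, relation), [])

    def out_neighbors(self, subject: str) -> set[str]:
        """Relation-agnostic out-neighbour set (empty for sinks)."""
        return self._out.get(subject, set())

    def out_degree(self, node: str, relation: str) -> int:
        """Number of edges ``(node, relation, ·)``."""
        if node not in self._entity_index:
            raise UnknownEntityError(f"unknown entity {node!r}")
        if relation not in self._relation_index:
            raise UnknownEntityError(f"unknown relation {relation!r}")
        return len(self._fwd.get((node, relation), ()))

    def transition_prob(self, src: str, dst: str, relation: str) -> float:
        """One-step typed walk probability from ``src`` to ``dst``.

        Uniform over the out-neighbours of ``src`` under ``relation``; 0 when
        ``src`` has no such out-edge (dead-end convention) or no edge reaches
        ``dst``.
        """
        if dst not in self._entity_index:
            raise UnknownEntityError(f"unknown entity {dst!r}")
        deg = self.out_degree(src, relation)
        if deg == 0:
            return 0.0
        return (1.0 if (src, relation, dst) in self._edges else 0.0) / deg


# -- file I/O ----------------------------------------------------------


def _read_vocab(path: Path) -> list[str]:
    vocab = []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            vocab.append(line)
    return vocab


def load_graph(
    path: str | Path,
    relation_vocab_path: str | Path | None = None,
    entities_path: str | Path | None = None,
) -> KnowledgeGraph:
    """Load a TSV edge list ``subject<TAB>relation<TAB>object``.

    ``#``-prefixed comment lines and blank lines are skipped.  Duplicate
    edges collapse with a logged warning.  If a relation vocabulary sidecar
    is given (one relation id per line) it fixes the relation ordering;
    otherwise relations are ordered by first appearance.  An optional
    entities sidecar pre-registers (possibly isolated) entities.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vocab = _read_vocab(Path(relation_vocab_path)) if relation_vocab_path else None
    ents = _read_vocab(Path(entities_path)) if entities_path else None

    edges: list[tuple[str, str, str]] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GraphFormatError(
                    f"{path}: line {lineno}: expected 3 fields, got {len(fields)}"
                )
            edges.append((fields[0], fields[1], fields[2]))
    if not edges:
        raise GraphFormatError(f"{path}: empty edge list")
    g = KnowledgeGraph(edges, relation_vocab=vocab, entities=ents)
    logger.info(
        "loaded graph: %d entities, %d relation types, %d edges",
        g.n_entities, g.n_relations, g.n_edges,
    )
    return g


def save_graph(g: KnowledgeGraph, path: str | Path, vocab_path: str | Path | None = None) -> None:
    """Write the edge list (deterministic order) and optional vocabulary sidecar."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for s in g.entities:
            for r in g.relation_types:
                for o in g.objects(s, r):
                    fh.write(f"{s}\t{r}\t{o}\n")
    if vocab_path is not None:
        Path(vocab_path).write_text(
            "".join(r + "\n" for r in g.relation_types), encoding="utf-8"
        )


_TRUE = {"1", "true"}
_FALSE = {"0", "false"}


def load_triplets(path: str | Path, labeled: bool = True) -> list[TripletRecord]:
    """Load a drug–target–disease TSV, 3 columns (unlabelled) or 4 (labelled)."""
    path = Path(path)
    records: list[TripletRecord] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if labeled:
                if len(fields) < 4:
                    raise GraphFormatError(
                        f"{path}: line {lineno}: expected 4 fields "
                        f"(drug, target, disease, label), got {len(fields)}"
                    )
                lab = fields[3].strip().lower()
                if lab in _TRUE:
                    label: Optional[bool] = True
                elif lab in _FALSE:
                    label = False
                else:
                    raise GraphFormatError(
                        f"{path}: line {lineno}: label must be 0/1/true/false, "
                        f"got {fields[3]!r}"
                    )
            else:
                if len(fields) < 3:
                    raise GraphFormatError(
                        f"{path}: line {lineno}: expected 3 fields, got {len(fields)}"
                    )
                label = None
            records.append(TripletRecord(fields[0], fields[1], fields[2], label))
    if not records:
        warnings.warn(f"{path}: no triplet records", stacklevel=2)
    return records


def save_triplets(records: Sequence[TripletRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for t in records:
            if t.label is None:
                fh.write(f"{t.drug}\t{t.target}\t{t.disease}\n")
            else:
                fh.write(f"{t.drug}\t{t.target}\t{t.disease}\t{int(t.label)}\n")
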
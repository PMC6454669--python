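"""Markov-chain random-walk baseline (RW-k).

The baseline ignores relation types: the transition matrix P is uniform
over each node's relation-agnostic out-neighbours (P_ij = 1/d_i for j
adjacent to i, else 0), sink rows are all zero, and the probability that a
walk from i reaches j in exactly t steps is (P^t)_ij.  A candidate drug's
score for a disease is the cumulative reach probability over steps 1..k
(per-step scoring is also available); a drug with zero probability for
every step up to k is *not found* within k steps.
"""

from __future__ import annotations

from typing import Literal, Optional, Sequence

import numpy as np

from .kg import KnowledgeGraph
from .scoring import CandidateRanking, rank_from_scores

__all__ = [
    "transition_matrix",
    "walk_probability",
    "rw_score",
    "rw_rank",
    "step_probabilities",
]


def transition_matrix(g: KnowledgeGraph) -> np.ndarray:
    """Row-stochastic (sink rows zero) uniform transition matrix.

    Rows/columns follow the graph's entity ordering.
    """
    if g.n_entities == 0:
        raise ValueError("graph has no entities")
    n = g.n_entities
    P = np.zeros((n, n), dtype=np.float64)
    for i, node in enumerate(g.entities):
        nbrs = g.out_neighbors(node)
        if not nbrs:
            continue
        w = 1.0 / len(nbrs)
        for o in nbrs:
            P[i, g.entity_index(o)] = w
    return P


def _powers(P: np.ndarray, t_max: int) -> list[np.ndarray]:
    out = [P]
    for _ in range(1, t_max):
        out.append(out[-1] @ P)
    return out


def walk_probability(P: np.ndarray, source: int, target: int, t: int) -> float:
    """(P^t)[source, target]: probability of reaching target in exactly t steps."""
    if t < 1:
        raise ValueError(f"t must be >= 1, got {t}")
    return float(np.linalg.matrix_power(P, t)[source, target])


def step_probabilities(
    P: np.ndarray, source: int, target: int, t_max: int
) -> list[float]:
    """[(P^t)[source, target] for t = 1..t_max]."""
    if t_max < 1:
        raise ValueError(f"t_max must be >= 1, got {t_max}")
    return [float(M[source, target]) for M in _powers(P, t_max)]


def rw_score(
    P: np.ndarray,
    source: int,
    target: int,
    k: int,
    mode: Literal["cumulative", "per-step"] = "cumulative",
) -> Optional[float]:
    """RW-k score of a (drug, disease) index pair; ``None`` = not found.

    ``cumulative`` (default) sums the per-step reach probabilities over
    t = 1..k; ``per-step`` returns the step-k probability alone.  Either
    way, a drug whose probability is zero for every t <= k cannot reach
    the disease within k steps and is reported not found.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    probs = step_probabilities(P, source, target, k)
    if all(p == 0.0 for p in probs):
        return None
    return probs[-1] if mode == "per-step" else float(sum(probs))


def rw_rank(
    g: KnowledgeGraph,
    disease: str,
    candidate_drugs: Sequence[str],
    k: int,
    mode: Literal["cumulative", "per-step"] = "cumulative",
    P: Optional[np.ndarray] = None,
) -> CandidateRanking:
    """Rank candidate drugs for a disease by their RW-k scores.

    Shares the fractional-tie ranking convention with the classifier
    pipeline; not-found drugs are listed last, unranked.  A precomputed
    transition matrix may be passed to amortise the powers across diseases.
    """
    if P is None:
        P = transition_matrix(g)
    j = g.entity_index(disease)
    powers = _powers(P, k)
    scores: dict[str, Optional[float]] = {}
    for drug in candidate_drugs:
        i = g.entity_index(drug)
        probs = [M[i, j] for M in powers]
        if all(p == 0.0 for p in probs):
            scores[drug] = None
        else:
            scores[drug] = float(probs[-1] if mode == "per-step" else sum(probs))
    return rank_from_scores(disease, scores, eta=1.0)
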
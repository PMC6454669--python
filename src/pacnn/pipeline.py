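"""End-to-end orchestration: featurise, train, score, benchmark.

Thin glue used by the command-line interface, the test suite and the
reproduction script.  Each function is deterministic given its seed.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np

from .evaluation import rediscovery_eval, RediscoveryReport
from .kg import TripletRecord
from .nn import PacnnClassifier
from .pra import PathFeaturizer
from .random_walk import rw_rank, transition_matrix
from .scoring import CandidateCaseSet, CandidateRanking, rank_candidates
from .synthetic import SynthBundle

__all__ = [
    "feature_matrix",
    "train_classifier",
    "build_case_sets",
    "pacnn_rediscovery",
    "rw_rediscovery",
]

DEFAULT_ETA = 0.2  # the eta setting that performs best in sensitivity sweeps


def feature_matrix(
    featurizer: PathFeaturizer, triplets: Sequence[TripletRecord]
) -> tuple[np.ndarray, np.ndarray]:
    """Stack triplet feature vectors into (X, y); y entries -1 when unlabelled."""
    feats = featurizer.featurize(triplets)
    X = np.vstack([f.vector for f in feats])
    y = np.array(
        [-1 if f.label is None else int(f.label) for f in feats], dtype=np.int64
    )
    return X, y


def train_classifier(
    X: np.ndarray, y: np.ndarray, seed: int, **model_overrides
) -> PacnnClassifier:
    clf = PacnnClassifier(seed=seed, **model_overrides)
    clf.fit(X, y)
    return clf


def build_case_sets(
    bundle: SynthBundle,
    clf: PacnnClassifier,
    featurizer: PathFeaturizer,
) -> dict[str, list[CandidateCaseSet]]:
    """Classify every candidate drug–target–disease case of the benchmark.

    All cases across diseases are batched through one forward pass.
    """
    rows: list[np.ndarray] = []
    index: list[tuple[str, str, str]] = []  # (disease, drug, target)
    for case in bundle.rediscovery:
        td = {
            t: featurizer.pair_vector(t, case.disease)
            for t in case.candidate_targets
        }
        for drug in case.candidate_drugs:
            for target in case.candidate_targets:
                rows.append(
                    np.concatenate(
                        [featurizer.pair_vector(drug, target), td[target]]
                    )
                )
                index.append((case.disease, drug, target))
    probs = clf.predict_proba(np.vstack(rows))[:, 1]

    by_pair: dict[tuple[str, str], list[tuple[str, float]]] = {}
    for (disease, drug, target), p in zip(index, probs):
        by_pair.setdefault((disease, drug), []).append((target, float(p)))
    out: dict[str, list[CandidateCaseSet]] = {}
    for case in bundle.rediscovery:
        out[case.disease] = [
            CandidateCaseSet(drug, case.disease, by_pair[(case.disease, drug)])
            for drug in case.candidate_drugs
        ]
    return out


def pacnn_rediscovery(
    bundle: SynthBundle,
    clf: PacnnClassifier,
    featurizer: PathFeaturizer,
    eta: float = DEFAULT_ETA,
    case_sets: Optional[Mapping[str, Sequence[CandidateCaseSet]]] = None,
) -> tuple[dict[str, CandidateRanking], RediscoveryReport]:
    """Rank the candidate drugs of every benchmark disease and evaluate."""
    if case_sets is None:
        case_sets = build_case_sets(bundle, clf, featurizer)
    rankings = {
        disease: rank_candidates(list(sets), eta)
        for disease, sets in case_sets.items()
    }
    known = {case.disease: case.known_drug for case in bundle.rediscovery}
    return rankings, rediscovery_eval(rankings, known)


def rw_rediscovery(
    bundle: SynthBundle, k: int, mode: str = "cumulative"
) -> tuple[dict[str, CandidateRanking], RediscoveryReport]:
    """RW-k baseline rankings and rediscovery metrics on the same benchmark."""
    P = transition_matrix(bundle.graph)
    rankings = {
        case.disease: rw_rank(
            bundle.graph, case.disease, case.candidate_drugs, k, mode=mode, P=P
        )
        for case in bundle.rediscovery
    }
    known = {case.disease: case.known_drug for case in bundle.rediscovery}
    return rankings, rediscovery_eval(rankings, known)
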
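"""Two-phase feature selection: mRMR ranking + backward elimination.

Phase 1 ranks all M features with the greedy minimum-redundancy
maximum-relevance (mRMR) criterion, evaluates the nested groups of the
top-m ranked features (m = 1..M) with a cross-validated SVM scored by
the Matthews correlation coefficient, and keeps the smallest group
attaining the maximum MCC as the candidate group.

Phase 2 refines the candidate by backward elimination: each iteration
temporarily drops every remaining feature, permanently removes the drop
that yields the highest MCC provided it does not fall below the current
MCC, and stops when every single removal strictly hurts (or one feature
remains).  The MCC trace along accepted removals is non-decreasing by
construction.

Mutual information is estimated after discretizing each feature into
three states at mean +/- one standard deviation (the canonical mRMR
recipe); the mRMR criterion is the MID (difference) form
relevance - mean redundancy.  Tie-breaks favor smaller feature sets and,
among equally scoring removals, discard the feature ranked least
relevant by mRMR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SelectionResult",
    "discretize_three_state",
    "mutual_information",
    "mrmr_rank",
    "phase1_candidate",
    "backward_eliminate",
    "select_features",
]


def discretize_three_state(x: np.ndarray) -> np.ndarray:
    """Discretize a feature into {0,1,2} at mean - std / mean + std.

    A constant feature maps entirely to the middle state.
    """
    x = np.asarray(x, dtype=float)
    mu, sd = x.mean(), x.std()
    out = np.ones(len(x), dtype=np.intp)
    out[x < mu - sd] = 0
    out[x > mu + sd] = 2
    return out


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """MI (nats) between two small-alphabet discrete variables."""
    a = np.asarray(a, dtype=np.intp)
    b = np.asarray(b, dtype=np.intp)
    ka, kb = a.max() + 1, b.max() + 1
    joint = np.zeros((ka, kb))
    np.add.at(joint, (a, b), 1.0)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    return float(np.sum(joint[mask] * np.log(joint[mask] / (pa @ pb)[mask])))


@dataclass
class SelectionResult:
    ranked_names: list[str]
    group_mcc_curve: list[float]
    candidate_size: int
    candidate_names: list[str]
    final_names: list[str]
    elimination_trace: list[tuple[str, float]]
    final_mcc: float

    def to_dict(self) -> dict:
        return {
            "ranked_names": self.ranked_names,
            "group_mcc_curve": self.group_mcc_curve,
            "candidate_size": self.candidate_size,
            "candidate_names": self.candidate_names,
            "final_names": self.final_names,
            "elimination_trace": [[n, m] for n, m in self.elimination_trace],
            "final_mcc": self.final_mcc,
        }


def mrmr_rank(features: pd.DataFrame, labels) -> list[str]:
    """Full greedy mRMR (MID) ordering of the feature columns.

    The first feature maximizes MI with the labels; each subsequent pick
    maximizes relevance minus mean MI with the already-selected
    features.  Ties keep the earliest column (stable).
    """
    y = np.asarray(labels)
    if y.dtype.kind in "USO":
        y = (y == "malignant").astype(np.intp)
    else:
        y = y.astype(np.intp)
    if len(np.bincount(y, minlength=2).nonzero()[0]) < 2 or np.bincount(y).min() < 2:
        raise ValueError("need >= 2 samples per class")
    names = list(features.columns)
    disc = {n: discretize_three_state(features[n].to_numpy()) for n in names}
    relevance = np.array([mutual_information(disc[n], y) for n in names])

    m = len(names)
    selected: list[int] = []
    remaining = list(range(m))
    red_sum = np.zeros(m)  # sum of MI(feature, s) over selected s
    first = int(np.argmax(relevance))
    selected.append(first)
    remaining.remove(first)
    while remaining:
        last = selected[-1]
        for j in remaining:
            red_sum[j] += mutual_information(disc[names[j]], disc[names[last]])
        scores = [relevance[j] - red_sum[j] / len(selected) for j in remaining]
        pick = remaining[int(np.argmax(scores))]
        selected.append(pick)
        remaining.remove(pick)
    return [names[i] for i in selected]


def phase1_candidate(
    ranked_names: list[str], evaluator
) -> tuple[list[str], list[float]]:
    """Sweep nested top-m groups and keep the smallest argmax of the MCC curve."""
    curve = [evaluator(ranked_names[:m]) for m in range(1, len(ranked_names) + 1)]
    best_m = int(np.argmax(curve)) + 1  # argmax returns the first (smallest) maximum
    return ranked_names[:best_m], curve


def backward_eliminate(
    candidate_names: list[str], evaluator, ranked_names: list[str] | None = None
) -> tuple[list[str], list[tuple[str, float]]]:
    """Greedy backward elimination of the candidate group.

    Each iteration removes the feature whose deletion gives the highest
    MCC, accepted while that MCC does not drop below the current one
    (ties favor the smaller set).  Equal-MCC removals discard the
    feature with the worst mRMR rank.  Returns the final subset and the
    (removed feature, MCC after removal) trace.
    """
    if not candidate_names:
        raise ValueError("candidate group is empty")
    rank_of = {n: i for i, n in enumerate(ranked_names or candidate_names)}
    current = list(candidate_names)
    current_mcc = evaluator(current)
    trace: list[tuple[str, float]] = []
    while len(current) > 1:
        results = []
        for name in current:
            subset = [n for n in current if n != name]
            results.append((evaluator(subset), rank_of.get(name, -1), name))
        # highest MCC; among ties discard the least-relevant (largest rank index)
        best_mcc, _, best_name = max(results, key=lambda r: (r[0], r[1]))
        if best_mcc >= current_mcc:
            current.remove(best_name)
            current_mcc = best_mcc
            trace.append((best_name, best_mcc))
        else:
            break
    return current, trace


def select_features(
    features: pd.DataFrame, labels, evaluator
) -> SelectionResult:
    """Run both phases end-to-end and package the result."""
    ranked = mrmr_rank(features, labels)
    candidate, curve = phase1_candidate(ranked, evaluator)
    final, trace = backward_eliminate(candidate, evaluator, ranked)
    final_mcc = trace[-1][1] if trace else curve[len(candidate) - 1]
    return SelectionResult(
        ranked_names=ranked,
        group_mcc_curve=curve,
        candidate_size=len(candidate),
        candidate_names=candidate,
        final_names=final,
        elimination_trace=trace,
        final_mcc=final_mcc,
    )


def selection_provenance(final_names: list[str]) -> dict[str, int]:
    """Per-layer/family counts of a selected subset, e.g. {'CONV5_4': 14}."""
    counts: dict[str, int] = {}
    for name in final_names:
        origin = name.split(":")[0]
        counts[origin] = counts.get(origin, 0) + 1
    return counts
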
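"""Most-probable-path (MPP) lumping of microstates into macrostates.

At a fixed lag time, the metastability of a state is its self-transition
probability T_ii.  MPP lumping repeatedly merges the least metastable
state into the state it most probably transitions to, rebuilding the
transition matrix after every merge; the recorded merge events form a
dendrogram.  The improved variant additionally absorbs states below a
population floor regardless of their metastability, so that the final
macrostates satisfy both T_ii >= q_min and population >= pop_min.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .msm import count_transitions, transition_matrix

__all__ = [
    "MergeEvent",
    "MergeTree",
    "mpp_lump",
    "mpp_improved",
    "MostProbablePathLumping",
    "macrostate_profile",
]


@dataclass(frozen=True)
class MergeEvent:
    """One MPP merge: ``source`` relabelled to ``target``."""

    source: int
    target: int
    metastability: float   # T_ii of the source at the merge
    population: float      # population of the source at the merge
    reason: str            # "metastability" or "population"


@dataclass
class MergeTree:
    """Ordered record of MPP merges (the lumping dendrogram)."""

    events: list = field(default_factory=list)
    leaves: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_merges(self) -> int:
        return len(self.events)

    @property
    def final_states(self) -> np.ndarray:
        merged = {e.source for e in self.events}
        return np.array([s for s in self.leaves if s not in merged])

    def to_json(self, path=None) -> str:
        payload = {
            "leaves": [int(s) for s in self.leaves],
            "events": [
                {"source": int(e.source), "target": int(e.target),
                 "metastability": e.metastability,
                 "population": e.population, "reason": e.reason}
                for e in self.events
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _merge_target(T: np.ndarray, i: int) -> int:
    """Most probable target j != i; ties -> lower index."""
    row = T[i].copy()
    row[i] = -np.inf
    return int(np.argmax(row))


def mpp_lump(states: np.ndarray, lag: int, q_min: float,
             pop_min: float = 0.0):
    """Lump microstates by iterative most-probable-path merging.

    Loop: build the (unsymmetrized, row-normalized) transition matrix at
    ``lag``; if any state's population is below ``pop_min`` merge the
    smallest such state into its most probable target; otherwise, if any
    state's metastability T_ii is below ``q_min``, merge the least
    metastable state likewise.  The matrix is rebuilt after every merge;
    iteration stops when all states satisfy both floors or one state
    remains.

    Returns ``(macrostates, tree)``: the relabelled trajectory (labels
    are the surviving microstate labels) and the MergeTree.
    """
    s = np.asarray(states).squeeze().astype(np.int64).copy()
    if len(s) == 0 or not (s >= 0).any():
        raise ValueError("empty state trajectory")
    if not 0 <= q_min <= 1:
        raise ValueError("q_min must be in [0, 1]")
    tree = MergeTree(leaves=np.unique(s[s >= 0]))
    while True:
        counts, labels = count_transitions(s, lag)
        if len(labels) <= 1:
            break
        sv = s[s >= 0]
        sv = sv[np.isin(sv, labels)]
        pop = np.bincount(np.searchsorted(labels, sv),
                          minlength=len(labels)).astype(float)
        pop /= pop.sum()
        rows = counts.sum(axis=1)
        if (rows == 0).any():
            # state never observed as a transition source at this lag:
            # absorb it into the most populated other state
            i = int(np.argmin(np.where(rows == 0, pop, np.inf)))
            other = pop.copy()
            other[i] = -np.inf
            j = int(np.argmax(other))
            tree.events.append(MergeEvent(int(labels[i]), int(labels[j]),
                                          0.0, float(pop[i]), "population"))
            s[s == labels[i]] = labels[j]
            continue
        T = transition_matrix(counts, symmetrize=False)
        diag = np.diag(T)
        if pop_min > 0 and (pop < pop_min).any():
            i = int(np.argmin(np.where(pop < pop_min, pop, np.inf)))
            reason = "population"
        elif (diag < q_min).any():
            i = int(np.argmin(diag))
            reason = "metastability"
        else:
            break
        j = _merge_target(T, i)
        tree.events.append(MergeEvent(int(labels[i]), int(labels[j]),
                                      float(diag[i]), float(pop[i]), reason))
        s[s == labels[i]] = labels[j]
    return s, tree


def mpp_improved(states: np.ndarray, lag: int, q_min: float = 0.5,
                 pop_min: float = 0.005):
    """MPP lumping with metastability and population floors.

    Defaults correspond to requiring a minimum metastability of 0.5 and
    a minimum population of 0.5% for every macrostate.
    """
    return mpp_lump(states, lag, q_min, pop_min=pop_min)


class MostProbablePathLumping(BaseEstimator):
    """sklearn-style estimator for MPP lumping.

    Parameters
    ----------
    lag : lag time (frames) of the microstate transition matrix.
    q_min : metastability floor (self-transition probability).
    pop_min : population floor (fraction of frames); 0 disables it.

    Attributes (after ``fit``)
    --------------------------
    labels_ : macrostate trajectory (surviving microstate labels).
    merge_tree_ : MergeTree of the merges performed.
    n_macrostates_ : number of final macrostates.
    """

    def __init__(self, lag: int = 1, q_min: float = 0.5,
                 pop_min: float = 0.0):
        self.lag = lag
        self.q_min = q_min
        self.pop_min = pop_min

    def fit(self, X, y=None):
        labels, tree = mpp_lump(X, self.lag, self.q_min, self.pop_min)
        self.labels_ = labels
        self.merge_tree_ = tree
        self.n_macrostates_ = len(np.unique(labels[labels >= 0]))
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def _tukey_hinges(v: np.ndarray):
    """Quartiles as Tukey hinges (median of each half, median included)."""
    v = np.sort(v)
    n = len(v)
    med = np.median(v)
    half = (n + 1) // 2
    q1 = np.median(v[:half])
    q3 = np.median(v[n - half:])
    return q1, med, q3


def macrostate_profile(states: np.ndarray,
                       features: np.ndarray,
                       feature_names=None) -> pd.DataFrame:
    """Boxplot-style summary of feature distributions per macrostate.

    For every (state, feature) pair: median, Tukey-hinge quartiles Q1
    and Q3, IQR = Q3 - Q1, and whiskers at the most extreme data points
    within [Q1 - 1.5 IQR, Q3 + 1.5 IQR].  Also reports the state
    population.
    """
    s = np.asarray(states).squeeze()
    X = np.asarray(features, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if len(s) != len(X):
        raise ValueError("states and features must have equal length")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    rows = []
    for state in np.unique(s[s >= 0]):
        sel = X[s == state]
        pop = sel.shape[0] / len(s)
        for k, name in enumerate(feature_names):
            v = sel[:, k]
            q1, med, q3 = _tukey_hinges(v)
            iqr = q3 - q1
            inside = v[(v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)]
            rows.append({"state": int(state), "feature": name,
                         "population": pop, "median": med,
                         "q1": q1, "q3": q3, "iqr": iqr,
                         "lo": float(inside.min()), "hi": float(inside.max())})
    return pd.DataFrame(rows)
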
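"""Markov state models: transition matrices and implied time scales.

Transition counts are sliding-window counts C_ij = #{t : s(t)=i,
s(t+lag)=j}.  By default the counts are symmetrized, (C + C^T)/2, which
enforces detailed balance and real spectra (equilibrium estimator);
diagonalization of the row-normalized matrix yields the implied time
scales t_i = -lag / ln|lambda_i|, whose independence of the lag time
indicates Markovian dynamics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "count_transitions",
    "transition_matrix",
    "implied_timescales",
    "MarkovStateModel",
    "its_vs_lag",
]


def count_transitions(states: np.ndarray, lag: int):
    """Sliding-window transition counts at a lag time.

    Frames labelled -1 are excluded from both the source and target
    role.  Returns ``(counts, labels)`` where ``labels`` maps matrix
    indices to the original state labels.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    s = np.asarray(states).squeeze().astype(np.int64)
    if s.ndim != 1:
        raise ValueError("state trajectory must be one-dimensional")
    if len(s) <= lag:
        raise ValueError("trajectory shorter than the lag time")
    a, b = s[:-lag], s[lag:]
    ok = (a >= 0) & (b >= 0)
    if not ok.any():
        raise ValueError("no valid transition pairs at this lag")
    a, b = a[ok], b[ok]
    labels = np.unique(np.concatenate([a, b]))
    index = np.searchsorted(labels, np.arange(labels.max() + 1))
    counts = np.zeros((len(labels), len(labels)), dtype=np.float64)
    np.add.at(counts, (index[a], index[b]), 1.0)
    return counts, labels


def transition_matrix(counts: np.ndarray, symmetrize: bool = True) -> np.ndarray:
    """Row-normalize (optionally symmetrized) transition counts."""
    C = np.asarray(counts, dtype=np.float64)
    if symmetrize:
        C = 0.5 * (C + C.T)
    rows = C.sum(axis=1)
    if np.any(rows == 0):
        raise ValueError("state(s) with no outgoing counts: %s"
                         % np.where(rows == 0)[0].tolist())
    return C / rows[:, None]


def implied_timescales(T: np.ndarray, lag: int, n_timescales: int | None = None
                       ) -> np.ndarray:
    """Implied time scales t_i = -lag / ln|lambda_i| of a transition matrix.

    Eigenvalues are sorted by modulus; the stationary eigenvalue
    (lambda_0 = 1) is skipped.  An eigenvalue >= 1 maps to +inf, a
    non-positive real one to NaN (undefined at this lag).
    """
    T = np.asarray(T, dtype=np.float64)
    K = T.shape[0]
    if n_timescales is None:
        n_timescales = min(K - 1, 5)
    ev = np.linalg.eigvals(T)
    order = np.argsort(-np.abs(ev))
    ev = ev[order][1:n_timescales + 1]
    out = np.empty(len(ev))
    for i, lam in enumerate(ev):
        if abs(lam.imag) < 1e-12 and lam.real <= 0:
            out[i] = np.nan
        elif abs(lam) >= 1.0:
            out[i] = np.inf
        else:
            out[i] = -lag / np.log(abs(lam))
    return out


class MarkovStateModel(BaseEstimator):
    """Markov state model estimated from a discrete state trajectory.

    Parameters
    ----------
    lag : lag time in frames.
    symmetrize : use the equilibrium (detailed-balance) count estimator
        (C + C^T)/2.
    n_timescales : number of implied time scales to report
        (default min(K-1, 5)).

    Attributes (after ``fit``)
    --------------------------
    counts_ : raw sliding-window count matrix.
    transition_matrix_ : row-stochastic transition matrix.
    populations_ : state populations (fractions of counted frames).
    eigenvalues_ : eigenvalues sorted by decreasing modulus.
    timescales_ : implied time scales in frames, descending.
    states_ : original state labels for each matrix index.
    dropped_states_ : labels visited fewer than ``lag`` frames, which
        are excluded from the model.
    """

    def __init__(self, lag: int = 1, symmetrize: bool = True,
                 n_timescales: int | None = None):
        self.lag = lag
        self.symmetrize = symmetrize
        self.n_timescales = n_timescales

    def fit(self, X, y=None):
        s = np.asarray(X).squeeze().astype(np.int64)
        # states visited fewer than lag frames are too poorly sampled to
        # count at this lag; mask them as unassigned
        vals, cnts = np.unique(s[s >= 0], return_counts=True)
        rare = vals[cnts < self.lag]
        if len(rare):
            s = s.copy()
            s[np.isin(s, rare)] = -1
        self.dropped_states_ = rare
        counts, labels = count_transitions(s, self.lag)
        self.counts_ = counts
        self.states_ = labels
        self.transition_matrix_ = transition_matrix(counts, self.symmetrize)
        sym = 0.5 * (counts + counts.T)
        self.populations_ = sym.sum(axis=1) / sym.sum()
        ev = np.linalg.eigvals(self.transition_matrix_)
        self.eigenvalues_ = ev[np.argsort(-np.abs(ev))]
        self.timescales_ = implied_timescales(self.transition_matrix_,
                                              self.lag, self.n_timescales)
        return self

    def score(self, X=None, y=None):
        """Negative relative deviation of the leading eigenvalue from 1."""
        return -abs(1.0 - np.abs(self.eigenvalues_[0]))


def its_vs_lag(states: np.ndarray, lags, n_timescales: int = 2,
               symmetrize: bool = True, rel_tol: float = 0.1) -> pd.DataFrame:
    """Implied time scales as a function of the lag time.

    One model per lag over the same state definition.  The returned
    frame has one row per lag with columns ``its_1..its_n`` and a
    ``converged`` flag (relative change of every ITS below ``rel_tol``
    with respect to the previous lag).  Per-lag failures are recorded
    as NaN rows.
    """
    lags = list(lags)
    if any(b <= a for a, b in zip(lags, lags[1:])):
        raise ValueError("lags must be ascending")
    rows = []
    prev = None
    for lag in lags:
        row = {"lag": lag}
        try:
            m = MarkovStateModel(lag=lag, symmetrize=symmetrize,
                                 n_timescales=n_timescales).fit(states)
            its = m.timescales_
        except (ValueError, np.linalg.LinAlgError) as err:
            its = np.full(n_timescales, np.nan)
            row["error"] = str(err)
        for i in range(n_timescales):
            row[f"its_{i + 1}"] = its[i] if i < len(its) else np.nan
        if prev is not None and np.all(np.isfinite(its)) and \
                np.all(np.isfinite(prev)) and len(prev) == len(its):
            row["converged"] = bool(
                np.all(np.abs(its - prev) / np.abs(prev) <= rel_tol))
        else:
            row["converged"] = False
        prev = its
        rows.append(row)
    return pd.DataFrame(rows)
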
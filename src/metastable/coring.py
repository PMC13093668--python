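"""Dynamical and iterative coring of state trajectories.

A transition into a new state is accepted only if the trajectory dwells
at least ``t_cor`` frames in that state; frames of rejected excursions
are reassigned to the last accepted state.  Iterative coring applies an
ascending schedule of coring times (the default 2..10 frames), which
reassigns fewer frames than a single pass at the final coring time
while smoothing with the same time resolution.

Unassigned frames (label -1, e.g. noise frames from density clustering)
are transparent: they neither break a dwell nor start one, and are
reassigned to the currently accepted state.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "dynamical_core",
    "iterative_core",
    "DynamicalCoring",
    "staying_probability",
    "recommend_coring_time",
]


def _core_assigned(s: np.ndarray, t_cor: int) -> np.ndarray:
    """Core a fully-assigned (no -1) state sequence."""
    T = len(s)
    out = np.empty(T, dtype=s.dtype)
    cur = s[0]
    out[0] = cur
    i = 1
    while i < T:
        if s[i] == cur:
            out[i] = cur
            i += 1
            continue
        # candidate transition into s[i]: find the visit length
        j = i
        while j < T and s[j] == s[i]:
            j += 1
        # accepted if the dwell reaches t_cor frames, or persists to the
        # end of the trajectory (the data cannot disprove the dwell)
        if (j - i) >= t_cor or j == T:
            cur = s[i]
        out[i:j] = cur
        i = j
    return out


def dynamical_core(states: np.ndarray, t_cor: int) -> np.ndarray:
    """Remove state visits shorter than ``t_cor`` frames.

    The first frame's state is accepted unconditionally.  A visit that
    reaches the final frame is kept even if shorter than ``t_cor``
    (the trajectory end cannot disprove the dwell).  Unassigned (-1)
    frames are transparent and are reassigned to the accepted state.
    """
    if t_cor < 1:
        raise ValueError("t_cor must be >= 1")
    s = np.asarray(states)
    if s.ndim != 1:
        raise ValueError("state trajectory must be one-dimensional")
    assigned = s >= 0
    if not assigned.any():
        raise ValueError("all frames unassigned")
    if assigned.all():
        return _core_assigned(s.astype(np.int64), int(t_cor))
    comp = _core_assigned(s[assigned].astype(np.int64), int(t_cor))
    out = np.empty(len(s), dtype=np.int64)
    out[assigned] = comp
    # -1 frames take the accepted state current at their position;
    # leading -1 frames take the first accepted state
    idx = np.where(assigned)[0]
    fill = np.searchsorted(idx, np.where(~assigned)[0], side="right") - 1
    out[~assigned] = comp[np.maximum(fill, 0)]
    return out


def iterative_core(states: np.ndarray, times) -> np.ndarray:
    """Apply dynamical coring successively with ascending coring times."""
    times = list(times)
    if not times:
        raise ValueError("empty coring schedule")
    if any(t < 1 for t in times) or any(b <= a for a, b in
                                        zip(times, times[1:])):
        raise ValueError("coring times must be >= 1 and strictly ascending")
    out = np.asarray(states)
    for t in times:
        out = dynamical_core(out, t)
    return out


class DynamicalCoring(TransformerMixin, BaseEstimator):
    """sklearn-style transformer for (iterative) dynamical coring.

    Parameters
    ----------
    t_cor : final coring time in frames.
    iterative : when True (default), apply the ascending schedule
        2..t_cor instead of a single pass.

    After ``transform``, ``n_reassigned_`` holds the number of frames
    whose label changed.
    """

    def __init__(self, t_cor: int = 10, iterative: bool = True):
        self.t_cor = t_cor
        self.iterative = iterative

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        s = np.asarray(X).squeeze()
        if self.iterative and self.t_cor >= 2:
            out = iterative_core(s, range(2, int(self.t_cor) + 1))
        else:
            out = dynamical_core(s, int(self.t_cor))
        self.n_reassigned_ = int(np.sum(out != s))
        return out


def _visit_lengths(states: np.ndarray) -> dict[int, np.ndarray]:
    """Length (in frames) of every visit, per state; -1 frames transparent."""
    s = np.asarray(states)
    s = s[s >= 0]
    if len(s) == 0:
        return {}
    change = np.where(np.diff(s) != 0)[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(s)]])
    out: dict[int, list] = {}
    for a, b in zip(starts, ends):
        out.setdefault(int(s[a]), []).append(b - a)
    return {k: np.asarray(v) for k, v in out.items()}


def staying_probability(states: np.ndarray,
                        t_cors,
                        max_time: int | None = None) -> pd.DataFrame:
    """Probability W_i(t) of staying in state i for at least t frames.

    For each coring time the trajectory is cored (iteratively, schedule
    2..t_cor) and W_i(t) is the fraction of visits to state i lasting at
    least ``t`` frames.  Returns a tidy frame with columns
    ``t_cor, state, t, W``.
    """
    t_cors = sorted(set(int(t) for t in t_cors))
    if any(t < 1 for t in t_cors):
        raise ValueError("coring times must be >= 1")
    rows = []
    for tc in t_cors:
        cored = np.asarray(states) if tc == 1 else \
            iterative_core(states, range(2, tc + 1)) if tc >= 2 else states
        visits = _visit_lengths(cored)
        tmax = max_time or max((v.max() for v in visits.values()), default=1)
        for state, lens in sorted(visits.items()):
            for t in range(1, int(tmax) + 1):
                rows.append({"t_cor": tc, "state": state, "t": t,
                             "W": float(np.mean(lens >= t))})
    return pd.DataFrame(rows)


def recommend_coring_time(states: np.ndarray,
                          t_cors,
                          decay_ratio_tol: float = 2.0) -> int:
    """Shortest coring time whose W_i(t) lacks a rapid initial decay.

    For each coring time the initial decay rate of W_i(t) (over the
    first few frames past t_cor) is compared to the tail rate; the
    smallest t_cor for which the initial rate is no more than
    ``decay_ratio_tol`` times the tail rate, for every state, is
    recommended.  Falls back to the largest scanned time when no value
    qualifies.
    """
    t_cors = sorted(set(int(t) for t in t_cors))
    table = staying_probability(states, t_cors)
    for tc in t_cors:
        ok = True
        sub = table[table.t_cor == tc]
        for state, grp in sub.groupby("state"):
            W = grp.sort_values("t")["W"].to_numpy()
            # usable part of the curve (tail counts get too sparse)
            L = int(np.argmax(W < 0.05)) or len(W)
            if L < tc + 4:
                continue
            # initial decay just past the coring time (W = 1 for
            # t <= t_cor by construction) vs the bulk decay rate
            rate_init = _decay_rate(W, tc - 1, tc + 3)
            rate_tail = _decay_rate(W, (tc - 1 + L) // 2, L)
            if rate_tail <= 0:
                continue
            if rate_init > decay_ratio_tol * rate_tail:
                ok = False
                break
        if ok:
            return tc
    return t_cors[-1]


def _decay_rate(W: np.ndarray, a: int, b: int) -> float:
    """Mean decay rate of -d ln W / dt over the window [a, b)."""
    a = max(a, 0)
    b = min(b, len(W))
    if b - a < 2:
        return 0.0
    w = np.clip(W[a:b], 1e-12, None)
    return float(-(np.log(w[-1]) - np.log(w[0])) / (b - 1 - a))
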
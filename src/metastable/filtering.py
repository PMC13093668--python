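"""Gaussian low-pass filtering of feature trajectories.

Each feature column is convolved with a truncated Gaussian kernel of
standard deviation ``sigma`` frames (window ``t_gf = 2 sigma``).  Where
the kernel overhangs the trajectory ends, the truncated kernel is
renormalized so the applied weights always sum to one — no data is
invented by padding, and a constant signal stays exactly constant.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["GaussianSmoother", "gaussian_filter", "scan_filter_window"]


def _resolve_sigma(sigma, window):
    if (sigma is None) == (window is None):
        raise ValueError("specify exactly one of sigma or window")
    if window is not None:
        sigma = window / 2.0
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return float(sigma)


def gaussian_filter(traj: np.ndarray,
                    sigma: float | None = None,
                    window: float | None = None,
                    truncate: float = 4.0) -> np.ndarray:
    """Low-pass filter a (T,) or (T, D) feature trajectory.

    Parameters
    ----------
    sigma : kernel standard deviation in frames.
    window : filter window ``t_gf`` in frames; ``sigma = window / 2``.
        Give exactly one of ``sigma`` or ``window``.
    truncate : kernel half-width in units of sigma (weights beyond
        ``truncate * sigma`` frames are dropped and the kernel is
        renormalized).

    A zero sigma returns the input unchanged.
    """
    sigma = _resolve_sigma(sigma, window)
    x = np.asarray(traj, dtype=np.float64)
    if x.ndim not in (1, 2):
        raise ValueError("trajectory must be 1D or 2D (frames x features)")
    T = x.shape[0]
    if T < 2:
        raise ValueError("trajectory must have more than one frame")
    if sigma == 0.0:
        return x.copy()
    if truncate < 1:
        raise ValueError("truncate must be >= 1")
    if truncate * sigma >= T:
        warnings.warn("filter kernel covers the whole trajectory; the "
                      "output is close to a global average", stacklevel=2)
    # edge renormalization: divide by the filtered indicator function
    norm = gaussian_filter1d(np.ones(T), sigma, mode="constant", cval=0.0,
                             truncate=truncate)
    out = gaussian_filter1d(x, sigma, axis=0, mode="constant", cval=0.0,
                            truncate=truncate)
    return out / (norm if x.ndim == 1 else norm[:, None])


class GaussianSmoother(TransformerMixin, BaseEstimator):
    """sklearn-style transformer applying the Gaussian low-pass filter.

    Parameters
    ----------
    window : filter window t_gf in frames (sigma = window / 2).
    truncate : kernel half-width in units of sigma.

    The transformer is stateless; ``fit`` only validates input.
    """

    def __init__(self, window: float = 10.0, truncate: float = 4.0):
        self.window = window
        self.truncate = truncate

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        return gaussian_filter(X, window=self.window, truncate=self.truncate)


def scan_filter_window(traj: np.ndarray,
                       windows,
                       count_states,
                       rel_tol: float = 0.1) -> pd.DataFrame:
    """Scan filter windows and report downstream state counts and ITS.

    For each window ``t_gf`` the trajectory is filtered and handed to
    ``count_states``, a callable returning either ``n_states`` or a
    tuple ``(n_states, its)`` where ``its`` is the leading implied time
    scale.  The recommended window (smallest at which both the state
    count and the ITS have plateaued, i.e. relative change below
    ``rel_tol`` between consecutive windows) is stored in
    ``df.attrs["recommended_window"]`` (None when no plateau is seen or
    only a single window was scanned).

    A failure of the downstream procedure for one window is recorded as
    NaN in that row rather than aborting the scan.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("windows must be non-empty")
    if any(b < a for a, b in zip(windows, windows[1:])):
        raise ValueError("windows must be ascending")
    rows = []
    for w in windows:
        filt = gaussian_filter(traj, window=w) if w > 0 else np.asarray(traj, float)
        try:
            res = count_states(filt)
        except Exception as err:  # recorded, not fatal
            rows.append({"window": w, "n_states": np.nan, "its": np.nan,
                         "error": str(err)})
            continue
        if np.isscalar(res):
            n, its = res, np.nan
        else:
            n, its = res
        rows.append({"window": w, "n_states": float(n), "its": float(its),
                     "error": ""})
    df = pd.DataFrame(rows)
    df.attrs["recommended_window"] = _recommend(df, rel_tol)
    return df


def _recommend(df: pd.DataFrame, rel_tol: float):
    if len(df) < 2:
        return None
    for i in range(1, len(df)):
        a, b = df.iloc[i - 1], df.iloc[i]
        if np.isnan(a["n_states"]) or np.isnan(b["n_states"]):
            continue
        same_states = a["n_states"] == b["n_states"]
        if np.isnan(a["its"]) or np.isnan(b["its"]):
            its_ok = True
        else:
            denom = max(abs(a["its"]), 1e-12)
            its_ok = abs(b["its"] - a["its"]) / denom <= rel_tol
        if same_states and its_ok:
            return float(a["window"])
    return None
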
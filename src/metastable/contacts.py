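"""Native contacts, fraction of native contacts Q(t), and folding events.

Operates on per-frame residue-pair minimum heavy-atom distances (in
Angstrom), so synthetic inputs and pre-extracted distance matrices both
work.  A contact is formed when the distance is below the cutoff
(default 4.5 A) for residue pairs separated by more than ``min_seq_sep``
in sequence (default |i-j| > 3); native contacts are the pairs formed
for more than ``min_population`` (default 30%) of the frames.  Folding
events are counted on Q(t) with a hysteresis rule: a passage from the
unfolded region (Q <= 0.3) to the native basin (Q >= 0.7).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .filtering import gaussian_filter

__all__ = [
    "ContactDefinition",
    "FoldingThresholds",
    "identify_native_contacts",
    "fraction_native",
    "count_folding_events",
    "scan_folding_vs_filter",
    "read_distance_file",
    "write_distance_file",
]


@dataclass(frozen=True)
class ContactDefinition:
    """Contact criteria: distance cutoff (A), sequence separation, and
    the minimum fraction of frames a native contact must be formed."""

    cutoff: float = 4.5
    min_seq_sep: int = 3
    min_population: float = 0.30

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.min_seq_sep < 0:
            raise ValueError("min_seq_sep must be >= 0")
        if not 0 <= self.min_population <= 1:
            raise ValueError("min_population must be in [0, 1]")


@dataclass(frozen=True)
class FoldingThresholds:
    """Q thresholds bounding the unfolded region and the native basin."""

    unfolded_max: float = 0.3
    native_min: float = 0.7

    def __post_init__(self):
        if not self.unfolded_max < self.native_min:
            raise ValueError("unfolded_max must be below native_min")


def identify_native_contacts(distances: np.ndarray,
                             pairs,
                             cdef: ContactDefinition = ContactDefinition()
                             ) -> np.ndarray:
    """Indices of native contact pairs.

    ``distances`` is (T, P) in Angstrom, ``pairs`` a length-P sequence
    of residue index pairs (i, j).  Pairs violating the sequence
    separation are dropped with a warning; of the rest, those formed
    (distance < cutoff) in strictly more than ``min_population`` of the
    frames are returned.
    """
    D = np.asarray(distances, dtype=np.float64)
    if D.ndim != 2:
        raise ValueError("distances must be 2D (frames x pairs)")
    pairs = np.asarray(pairs)
    if pairs.shape != (D.shape[1], 2):
        raise ValueError("pairs must be (P, 2) matching the distance columns")
    if np.mean(D < 1.0) > 0.99:
        warnings.warn("almost all distances are < 1; input may be in nm "
                      "instead of Angstrom", stacklevel=2)
    sep_ok = np.abs(pairs[:, 0] - pairs[:, 1]) > cdef.min_seq_sep
    if not sep_ok.all():
        warnings.warn("%d pair(s) violate the sequence-separation criterion "
                      "and were dropped" % int((~sep_ok).sum()), stacklevel=2)
    formed_frac = (D < cdef.cutoff).mean(axis=0)
    return np.where(sep_ok & (formed_frac > cdef.min_population))[0]


def fraction_native(distances: np.ndarray,
                    cdef: ContactDefinition = ContactDefinition()
                    ) -> np.ndarray:
    """Per-frame fraction of native contacts formed, Q(t) in [0, 1].

    ``distances`` holds only the selected native-contact columns.
    """
    D = np.asarray(distances, dtype=np.float64)
    if D.ndim == 1:
        D = D[:, None]
    if D.shape[1] < 1:
        raise ValueError("need at least one selected pair")
    return (D < cdef.cutoff).mean(axis=1)


def count_folding_events(q: np.ndarray,
                         thr: FoldingThresholds = FoldingThresholds()) -> int:
    """Count folding events along Q(t) with a hysteresis rule.

    An event is a passage that enters the unfolded region
    (Q <= unfolded_max) and subsequently reaches the native basin
    (Q >= native_min); intermediate values are transparent, and
    re-entering the unfolded region before folding does not reset
    progress.
    """
    q = np.atleast_1d(np.asarray(q, dtype=np.float64).squeeze())
    events = 0
    armed = False
    for v in q:
        if v <= thr.unfolded_max:
            armed = True
        elif v >= thr.native_min and armed:
            events += 1
            armed = False
    return events


def scan_folding_vs_filter(distances: np.ndarray,
                           pairs,
                           windows,
                           cdef: ContactDefinition = ContactDefinition(),
                           thr: FoldingThresholds = FoldingThresholds(),
                           rel_tol: float = 0.1) -> pd.DataFrame:
    """Folding-event counts for a range of filter windows.

    For each window ``t_gf`` (frames) the distances are Gaussian
    filtered, the native contacts identified on the raw distances are
    re-evaluated on the filtered ones, and the events on Q(t) counted.
    The plateau window (first at which the count stops changing by more
    than ``rel_tol``) is stored in ``df.attrs["plateau_window"]``.
    """
    windows = list(windows)
    if any(b < a for a, b in zip(windows, windows[1:])):
        raise ValueError("windows must be ascending")
    D = np.asarray(distances, dtype=np.float64)
    native = identify_native_contacts(D, pairs, cdef)
    if len(native) == 0:
        raise ValueError("no native contacts found")
    rows = []
    for w in windows:
        Df = gaussian_filter(D[:, native], window=w) if w > 0 else D[:, native]
        q = fraction_native(Df, cdef)
        rows.append({"window": w, "n_events": count_folding_events(q, thr)})
    df = pd.DataFrame(rows)
    plateau = None
    for i in range(1, len(df)):
        a, b = df.n_events.iloc[i - 1], df.n_events.iloc[i]
        if a > 0 and abs(b - a) / a <= rel_tol:
            plateau = float(df.window.iloc[i - 1])
            break
    df.attrs["plateau_window"] = plateau
    df.attrs["native_pairs"] = native
    return df


def read_distance_file(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a whitespace-delimited T x P distance matrix.

    The first comment line of the form ``# pairs: i-j i-j ...`` names
    the residue pairs.  Returns ``(distances, pairs)``.
    """
    pairs = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "pairs:" in line:
                toks = line.split("pairs:", 1)[1].split()
                pairs = np.array([[int(a) for a in t.split("-")]
                                  for t in toks])
                break
    D = np.loadtxt(path)
    if pairs is None:
        raise ValueError("missing '# pairs: i-j ...' header in %s" % path)
    return np.atleast_2d(D), pairs


def write_distance_file(path, distances: np.ndarray, pairs) -> None:
    header = "pairs: " + " ".join("%d-%d" % (i, j) for i, j in pairs)
    np.savetxt(path, np.asarray(distances), header=header)
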
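"""Two-dimensional three-well toy landscape and overdamped Langevin sampling.

The model is a minimal caricature of a free energy landscape with three
metastable conformational states: a sum of inverted isotropic Gaussians
(one per well) plus a weak quartic confinement that keeps the Boltzmann
density normalizable.  The default parameters are calibrated such that

* the potential barrier along the piecewise-linear path ``s`` connecting
  the well minima is 4 kBT, and
* the barrier of the 1D free energy ``dG(x)`` obtained by marginalizing
  the Boltzmann density over ``y`` is 1 kBT,

so that projecting onto ``x`` (and worse, onto a tilted axis ``r``)
produces the classic projection artifacts: lowered barriers, spurious
recrossings, and — for ``r`` — complete loss of one state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "ThreeWellPotential",
    "LangevinConfig",
    "simulate_langevin",
    "project_axis",
    "project_path",
    "axis_vector",
    "DEFAULT_R_ANGLE_DEG",
]

#: Default tilt angle (degrees) of the suboptimal projection axis r.
#: Chosen so that two of the three projected well centers are separated
#: by less than the intrawell fluctuation width (states merge without
#: filtering) but are resolved once the trajectory is low-pass filtered.
DEFAULT_R_ANGLE_DEG = 40.0


@dataclass(frozen=True)
class ThreeWellPotential:
    """Sum of inverted isotropic Gaussian wells with optional confinement.

    V(p) = -sum_k A_k exp(-|p - c_k|^2 / (2 sigma_k^2))
           + k_conf * |p - c_conf|^4

    Parameters are in thermal units: depths ``A_k`` in kBT, lengths
    dimensionless.  The defaults are the calibrated three-well landscape
    (path barrier 4 kBT, marginal x barrier 1 kBT).
    """

    centers: tuple = ((-1.0, 1.844), (0.0, 0.0), (1.0, 1.844))
    depths: tuple = (8.0, 8.0, 8.0)
    widths: tuple = (0.622, 0.622, 0.622)
    kBT: float = 1.0
    confinement: float = 0.02
    confinement_center: tuple = (0.0, 0.922)

    def __post_init__(self):
        if len(self.centers) < 2:
            raise ValueError("need at least two wells")
        if len(self.depths) != len(self.centers) or len(self.widths) != len(self.centers):
            raise ValueError("centers, depths and widths must have equal length")
        if any(a <= 0 for a in self.depths) or any(w <= 0 for w in self.widths):
            raise ValueError("depths and widths must be positive")
        if self.kBT < 0:
            raise ValueError("kBT must be non-negative")

    # -- array views used by the numba kernel ------------------------------
    @property
    def _arrays(self):
        c = np.asarray(self.centers, dtype=np.float64)
        a = np.asarray(self.depths, dtype=np.float64)
        w = np.asarray(self.widths, dtype=np.float64)
        c0 = np.asarray(self.confinement_center, dtype=np.float64)
        return c, a, w, float(self.confinement), c0

    def energy(self, points: np.ndarray) -> np.ndarray:
        """Potential energy V (kBT units) at one point or an (N, 2) array."""
        p = np.atleast_2d(np.asarray(points, dtype=np.float64))
        c, a, w, kc, c0 = self._arrays
        d2 = ((p[:, None, :] - c[None, :, :]) ** 2).sum(axis=2)
        v = -(a[None, :] * np.exp(-d2 / (2.0 * w[None, :] ** 2))).sum(axis=1)
        if kc != 0.0:
            v = v + kc * (((p - c0) ** 2).sum(axis=1)) ** 2
        return v[0] if np.asarray(points).ndim == 1 else v

    def gradient(self, points: np.ndarray) -> np.ndarray:
        """Analytic gradient of V, shape like the input."""
        p = np.atleast_2d(np.asarray(points, dtype=np.float64))
        c, a, w, kc, c0 = self._arrays
        diff = p[:, None, :] - c[None, :, :]          # (N, K, 2)
        d2 = (diff ** 2).sum(axis=2)
        g = (a[None, :] / w[None, :] ** 2 * np.exp(-d2 / (2.0 * w[None, :] ** 2)))[..., None] * diff
        grad = g.sum(axis=1)
        if kc != 0.0:
            dp = p - c0
            grad = grad + 4.0 * kc * ((dp ** 2).sum(axis=1, keepdims=True)) * dp
        return grad[0] if np.asarray(points).ndim == 1 else grad

    @property
    def path_waypoints(self) -> np.ndarray:
        """Well centers, in order: the waypoints of the optimal coordinate s."""
        return np.asarray(self.centers, dtype=np.float64)


@dataclass(frozen=True)
class LangevinConfig:
    """Overdamped (Brownian) Euler-Maruyama integration settings.

    One saved frame corresponds to ``dt * save_stride`` time units; with
    the defaults a frame is 0.05 time units, which puts the mean
    interwell dwell time of the default potential near 150 frames.
    """

    dt: float = 0.005
    friction: float = 1.0
    n_steps: int = 10_000_000
    save_stride: int = 10
    seed: int | None = None

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.friction <= 0:
            raise ValueError("friction must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.save_stride < 1:
            raise ValueError("save_stride must be >= 1")


@njit(cache=False)
def _integrate(centers, depths, widths, kc, c0, kBT, dt, gamma,
               n_steps, stride, seed, x0, y0, bound):  # pragma: no cover
    np.random.seed(seed)
    n_frames = n_steps // stride
    out = np.empty((n_frames, 2))
    x, y = x0, y0
    amp = math.sqrt(2.0 * kBT * dt / gamma)
    k = 0
    for i in range(n_steps):
        fx = 0.0
        fy = 0.0
        for w in range(centers.shape[0]):
            dx = x - centers[w, 0]
            dy = y - centers[w, 1]
            s2 = widths[w] * widths[w]
            e = depths[w] * math.exp(-(dx * dx + dy * dy) / (2.0 * s2))
            fx -= e * dx / s2
            fy -= e * dy / s2
        if kc != 0.0:
            dx = x - c0[0]
            dy = y - c0[1]
            r2 = dx * dx + dy * dy
            fx -= 4.0 * kc * r2 * dx
            fy -= 4.0 * kc * r2 * dy
        x += fx * dt / gamma + amp * np.random.normal()
        y += fy * dt / gamma + amp * np.random.normal()
        if abs(x) > bound or abs(y) > bound:
            return out[:k], False
        if (i + 1) % stride == 0:
            out[k, 0] = x
            out[k, 1] = y
            k += 1
    return out[:k], True


def simulate_langevin(potential: ThreeWellPotential,
                      cfg: LangevinConfig,
                      x0: tuple = (0.0, 0.0),
                      _bound: float = 1e3) -> np.ndarray:
    """Sample the potential with overdamped Langevin dynamics.

    Euler-Maruyama update
    ``p <- p - grad V(p) dt/gamma + sqrt(2 kBT dt/gamma) xi``,
    returning every ``save_stride``-th point as a (T, 2) array.
    Bit-reproducible for a fixed seed.

    Raises
    ------
    RuntimeError
        if the trajectory diverges (a coordinate exceeds ``_bound``),
        which signals a too-large time step.
    """
    c, a, w, kc, c0 = potential._arrays
    seed = cfg.seed
    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0] % (2 ** 31))
    traj, ok = _integrate(c, a, w, kc, c0, float(potential.kBT),
                          float(cfg.dt), float(cfg.friction),
                          int(cfg.n_steps), int(cfg.save_stride),
                          int(seed) % (2 ** 31), float(x0[0]), float(x0[1]),
                          float(_bound))
    if not ok:
        raise RuntimeError(
            "trajectory diverged (|coordinate| > %g); reduce dt" % _bound)
    return traj


def axis_vector(angle_deg: float) -> np.ndarray:
    """Unit vector at the given angle (degrees, counterclockwise from +x)."""
    a = math.radians(angle_deg)
    return np.array([math.cos(a), math.sin(a)])


def project_axis(traj: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Project a (T, 2) trajectory onto a unit vector: returns p . e per frame."""
    axis = np.asarray(axis, dtype=np.float64)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("projection axis must have non-zero norm")
    if abs(n - 1.0) > 1e-8:
        raise ValueError("projection axis must be a unit vector")
    return np.asarray(traj, dtype=np.float64) @ axis


def project_path(traj: np.ndarray, waypoints) -> np.ndarray:
    """Arc-length position of the orthogonal projection onto a polyline.

    Each frame is projected onto every segment of the piecewise-linear
    path through ``waypoints`` (clamped to the segment); the nearest
    segment wins, and the returned coordinate is the cumulative arc
    length of the projected point (s = 0 at the first waypoint).
    """
    W = np.asarray(waypoints, dtype=np.float64)
    if W.ndim != 2 or len(W) < 2:
        raise ValueError("path needs at least two 2D waypoints")
    tr = np.asarray(traj, dtype=np.float64)
    segs = W[1:] - W[:-1]
    seg_len = np.linalg.norm(segs, axis=1)
    if np.any(seg_len == 0):
        raise ValueError("degenerate (zero-length) path segment")
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    best = np.full(len(tr), np.inf)
    s = np.zeros(len(tr))
    for i, (v, L) in enumerate(zip(segs, seg_len)):
        t = np.clip(((tr - W[i]) @ v) / L ** 2, 0.0, 1.0)
        proj = W[i] + t[:, None] * v
        dist = np.linalg.norm(tr - proj, axis=1)
        closer = dist < best
        best[closer] = dist[closer]
        s[closer] = cum[i] + t[closer] * L
    return s
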
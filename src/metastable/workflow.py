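"""End-to-end pipelines and synthetic fixture generators.

``run_toy_benchmark`` reproduces the toy-model study: simulate the 2D
three-well landscape, project onto the optimal coordinate s and the
suboptimal coordinates x and r, derive state trajectories for the raw,
cored and filtered variants, and compare implied time scales against
the s reference.  ``generate_fixture`` produces small synthetic data
sets with documented ground truth (telegraph signals, block-structured
Markov chains, planted folding trajectories, toy 2D trajectories).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from numba import njit

from . import contacts as _contacts
from .clustering import count_states_1d
from .coring import iterative_core
from .filtering import gaussian_filter
from .msm import its_vs_lag
from .toy_model import (DEFAULT_R_ANGLE_DEG, LangevinConfig,
                        ThreeWellPotential, axis_vector, project_axis,
                        project_path, simulate_langevin)

__all__ = [
    "path_barriers",
    "marginal_x_barriers",
    "run_toy_benchmark",
    "generate_fixture",
    "sample_markov_chain",
]


def path_barriers(potential: ThreeWellPotential, n_grid: int = 4001):
    """Potential barriers along the minimum-connecting path s.

    Evaluates V on a dense grid along each path segment; the barrier of
    a segment is its maximum minus the higher of the two adjacent
    minimum values.  Returns one barrier per segment, in kBT.
    """
    W = potential.path_waypoints
    out = []
    t = np.linspace(0.0, 1.0, n_grid)[:, None]
    for a, b in zip(W[:-1], W[1:]):
        v = potential.energy(a + t * (b - a))
        out.append(float(v.max() - max(v[0], v[-1])))
    return np.asarray(out)


def marginal_x_barriers(potential: ThreeWellPotential,
                        x_range=(-2.5, 2.5), n_x: int = 2001,
                        y_margin: float = 3.0, n_y: int = 3001,
                        min_depth: float = 0.2):
    """Barriers of dG(x) = -ln integral dy exp(-V(x, y) / kBT).

    The Boltzmann density of the potential is marginalized over y by
    numerical quadrature on a dense grid; barriers between adjacent
    minima of the resulting 1D free energy are returned in kBT.
    """
    xs = np.linspace(*x_range, n_x)
    ylo = min(c[1] for c in potential.centers) - y_margin
    yhi = max(c[1] for c in potential.centers) + y_margin
    ys = np.linspace(ylo, yhi, n_y)
    pts = np.stack(np.meshgrid(xs, ys, indexing="ij"), axis=-1).reshape(-1, 2)
    V = potential.energy(pts).reshape(n_x, n_y)
    kBT = potential.kBT if potential.kBT > 0 else 1.0
    P = np.trapezoid(np.exp(-V / kBT), ys, axis=1)
    dG = -np.log(P / P.max())
    # reuse the curve machinery: wrap as a free-energy curve
    from .clustering import FreeEnergyCurve, find_minima_and_barriers
    curve = FreeEnergyCurve(xs, dG, np.ones_like(dG))
    mb = find_minima_and_barriers(curve, min_depth=min_depth)
    return mb.barrier_heights, mb


def run_toy_benchmark(seed: int = 0,
                      n_frames: int = 1_000_000,
                      t_gf: float = 10.0,
                      t_cor: int = 10,
                      lags=(20, 50, 100),
                      r_angle_deg: float = DEFAULT_R_ANGLE_DEG,
                      out_dir=None) -> dict:
    """Run the full toy-model study and return a machine-readable report.

    Deterministic for a fixed seed.  The report contains the potential
    calibration (path and marginal barriers), state counts for the s, x
    and r projections (raw and Gaussian filtered), and implied time
    scale tables for the raw / cored / filtered x states against the s
    reference.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    pot = ThreeWellPotential()
    cfg = LangevinConfig(n_steps=n_frames * 10, save_stride=10, seed=seed)
    traj = simulate_langevin(pot, cfg)

    s = project_path(traj, pot.path_waypoints)
    x = traj[:, 0]
    r = project_axis(traj, axis_vector(r_angle_deg))
    xf = gaussian_filter(x, window=t_gf)
    rf = gaussian_filter(r, window=t_gf)

    n_s, st_s, _ = count_states_1d(s, return_assignment=True)
    n_x, st_x, _ = count_states_1d(x, return_assignment=True)
    n_r_raw, st_r, _ = count_states_1d(r, return_assignment=True)
    n_r_flt, st_rf, _ = count_states_1d(rf, return_assignment=True)
    n_x_flt, st_xf, _ = count_states_1d(xf, return_assignment=True)

    st_x_cored = iterative_core(st_x, range(2, t_cor + 1))

    its = {
        "s": its_vs_lag(st_s, lags),
        "x_raw": its_vs_lag(st_x, lags),
        "x_cored": its_vs_lag(st_x_cored, lags),
        "x_filtered": its_vs_lag(st_xf, lags),
        "r_filtered": its_vs_lag(iterative_core(st_rf, range(2, t_cor + 1)),
                                 lags),
    }

    report = {
        "seed": seed,
        "n_frames": int(len(traj)),
        "barrier_s_kBT": path_barriers(pot).tolist(),
        "barrier_x_kBT": marginal_x_barriers(pot)[0].tolist(),
        "n_states": {"s": n_s, "x_raw": n_x, "x_filtered": n_x_flt,
                     "r_raw": n_r_raw, "r_filtered": n_r_flt},
        "its": {k: v.drop(columns=["error"], errors="ignore")
                     .to_dict(orient="list") for k, v in its.items()},
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savetxt(out / "trajectory.txt", traj,
                   header="toy 2D trajectory (x y), one row per frame")
        for name, st in [("states_s", st_s), ("states_x", st_x),
                         ("states_x_cored", st_x_cored),
                         ("states_r_filtered", st_rf)]:
            np.savetxt(out / f"{name}.txt", st, fmt="%d")
        for k, v in its.items():
            v.to_csv(out / f"its_{k}.tsv", sep="\t", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(report, fh, indent=1)
    return report


@njit(cache=False)
def _sample_chain(cum_T, start, n_steps, seed):  # pragma: no cover
    np.random.seed(seed)
    out = np.empty(n_steps, dtype=np.int64)
    state = start
    for t in range(n_steps):
        out[t] = state
        u = np.random.random()
        row = cum_T[state]
        nxt = 0
        for j in range(row.shape[0]):
            if u <= row[j]:
                nxt = j
                break
        state = nxt
    return out


def sample_markov_chain(T: np.ndarray, n_steps: int, seed: int,
                        start: int = 0) -> np.ndarray:
    """Sample a discrete Markov chain from a row-stochastic matrix."""
    T = np.asarray(T, dtype=np.float64)
    if np.any(np.abs(T.sum(axis=1) - 1.0) > 1e-10):
        raise ValueError("transition matrix rows must sum to 1")
    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.0
    return _sample_chain(cum, int(start), int(n_steps), int(seed) % (2 ** 31))


def generate_fixture(kind: str, params: dict | None = None,
                     seed: int = 0, out_dir=None) -> dict:
    """Generate a synthetic test data set with documented ground truth.

    Kinds
    -----
    ``toy2d`` : short default-potential Langevin trajectory
        (params: n_frames).
    ``telegraph`` : two-state jump process with exponential dwell times
        plus Gaussian observation noise (params: n_frames, dwell,
        noise_sigma, levels).
    ``block_chain`` : Markov chain with planted block structure
        (params: n_steps, n_blocks, states_per_block, p_intra, p_inter).
    ``planted_folding`` : synthetic contact-distance trajectory with a
        known number of folding passages plus fast noise (params:
        n_events, n_pairs, frames_per_segment, noise_sigma).

    Returns a dict with the data and its ground truth; with ``out_dir``
    the arrays are also written as whitespace-delimited text plus a
    ``*_truth.json`` file.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "toy2d":
        n = int(params.pop("n_frames", 50_000))
        pot = ThreeWellPotential()
        traj = simulate_langevin(pot, LangevinConfig(n_steps=n * 10,
                                                     seed=seed))
        result = {"kind": kind, "trajectory": traj,
                  "truth": {"n_wells": len(pot.centers),
                            "well_centers": [list(c) for c in pot.centers]}}
    elif kind == "telegraph":
        n = int(params.pop("n_frames", 20_000))
        dwell = float(params.pop("dwell", 100.0))
        noise = float(params.pop("noise_sigma", 0.0))
        levels = params.pop("levels", (0.0, 1.0))
        labels = np.empty(n, dtype=np.int64)
        t, state = 0, 0
        while t < n:
            length = max(1, int(rng.exponential(dwell)))
            labels[t:t + length] = state
            t += length
            state = 1 - state
        signal = np.asarray(levels, float)[labels] + \
            noise * rng.standard_normal(n)
        result = {"kind": kind, "signal": signal, "labels": labels,
                  "truth": {"dwell": dwell, "noise_sigma": noise,
                            "levels": list(levels)}}
    elif kind == "block_chain":
        n = int(params.pop("n_steps", 100_000))
        n_blocks = int(params.pop("n_blocks", 2))
        spb = int(params.pop("states_per_block", 2))
        p_intra = float(params.pop("p_intra", 0.1))
        p_inter = float(params.pop("p_inter", 0.001))
        K = n_blocks * spb
        T = np.full((K, K), 0.0)
        for i in range(K):
            for j in range(K):
                if i == j:
                    continue
                T[i, j] = p_intra if i // spb == j // spb else p_inter
            T[i, i] = 1.0 - T[i].sum()
        chain = sample_markov_chain(T, n, seed)
        result = {"kind": kind, "states": chain,
                  "transition_matrix": T,
                  "truth": {"blocks": [i // spb for i in range(K)],
                            "eigenvalues":
                                sorted(np.linalg.eigvals(T).real,
                                       reverse=True)}}
    elif kind == "planted_folding":
        n_events = int(params.pop("n_events", 5))
        n_pairs = int(params.pop("n_pairs", 10))
        seg = int(params.pop("frames_per_segment", 200))
        noise = float(params.pop("noise_sigma", 1.5))
        indep = float(params.pop("indep_sigma", 0.3))
        folded, unfolded = 3.0, 8.0
        # alternating unfolded / folded segments: each unfolded->folded
        # passage is one event; start folded so counts are exact
        blocks = [np.full(seg, folded)]
        for _ in range(n_events):
            blocks += [np.full(seg, unfolded), np.full(seg, folded)]
        base = np.concatenate(blocks)
        # white common-mode noise (a collective breathing motion) moves
        # all distances together, so the raw Q(t) shows spurious
        # crossings that low-pass filtering removes
        common = noise * rng.standard_normal(len(base))
        D = (base + common)[:, None] + \
            indep * rng.standard_normal((len(base), n_pairs))
        pairs = np.array([[i, i + 4] for i in range(n_pairs)])
        result = {"kind": kind, "distances": D, "pairs": pairs,
                  "truth": {"n_events": n_events, "folded_distance": folded,
                            "unfolded_distance": unfolded,
                            "noise_sigma": noise, "indep_sigma": indep}}
    else:
        raise ValueError("unknown fixture kind: %r" % kind)
    if params:
        raise ValueError("unknown parameters: %s" % sorted(params))
    if out_dir is not None:
        _write_fixture(result, Path(out_dir))
    return result


def _write_fixture(result: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    kind = result["kind"]
    for key, val in result.items():
        if isinstance(val, np.ndarray):
            fmt = "%d" if np.issubdtype(val.dtype, np.integer) else "%.8g"
            np.savetxt(out / f"{kind}_{key}.txt", val, fmt=fmt)
    with open(out / f"{kind}_truth.json", "w") as fh:
        json.dump(result["truth"], fh, indent=1)
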
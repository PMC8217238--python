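"""Trajectory linking and MSD-based diffusion estimation.

Mobile localizations are linked frame to frame by solving a linear
assignment problem per frame pair (globally optimal in the total squared
displacement), with an adaptive per-trajectory gate derived from the
trajectory's own displacement statistics and a tolerance for up to three
consecutive missing frames.  Diffusion coefficients are estimated per
trajectory by weighted least squares on the mean squared displacement
using the 2D model with motion-blur and localization-error corrections::

    MSD(tau) = 4 D tau - (4/3) D dt + 4 eps^2

where ``tau`` is the time lag, ``dt`` the camera exposure time and ``eps``
the localization precision.  Only lags below 5 frames enter the fit
("instantaneous" D), and only trajectories observed for more than 10
frames are fitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

__all__ = [
    "Trajectory",
    "DiffusionFit",
    "link_trajectories",
    "compute_msd",
    "fit_diffusion",
    "fit_trajectories",
    "trajectories_to_frame",
]


@dataclass
class Trajectory:
    """Time-ordered localizations of one particle (gaps <= 3 frames)."""

    id: int
    frames: np.ndarray  # strictly increasing frame indices
    x: np.ndarray  # um
    y: np.ndarray  # um
    precision: np.ndarray | None = None
    channel: str = "A"
    loc_index: np.ndarray | None = None  # positions in the source table

    def __post_init__(self) -> None:
        if len(self.frames) and (np.diff(self.frames) <= 0).any():
            raise ValueError("frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def span(self) -> int:
        """Temporal extent in frames (first to last, inclusive)."""
        return int(self.frames[-1] - self.frames[0] + 1) if len(self) else 0

    @property
    def n_gaps(self) -> int:
        return self.span - len(self)

    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def contiguous_runs(self) -> list[np.ndarray]:
        """Indices of maximal gap-free runs of consecutive frames."""
        if not len(self):
            return []
        breaks = np.flatnonzero(np.diff(self.frames) != 1)
        return np.split(np.arange(len(self)), breaks + 1)


@dataclass
class DiffusionFit:
    """Result of the weighted MSD fit for one trajectory."""

    d: float  # um^2/s
    epsilon: float  # um
    n_lags_used: int
    residual: float
    negative_eps2: bool
    msd: pd.DataFrame = field(repr=False, default=None)


@dataclass
class _Track:
    tid: int
    frames: list[int]
    xs: list[float]
    ys: list[float]
    precs: list[float]
    idx: list[int]
    r2bar: float  # running mean squared per-frame displacement (2D)
    n_steps: int = 0


def link_trajectories(
    localizations: pd.DataFrame,
    frame_interval: float = 0.032,
    max_gap: int = 3,
    gate_factor: float = 3.0,
    d_init: float = 0.5,
    channel: str | None = None,
) -> list[Trajectory]:
    """Link mobile localizations into trajectories.

    Frame-to-frame correspondences are found by minimizing the total
    squared displacement (rectangular linear assignment per frame pair,
    solved per connected component of the candidate graph).  A pairing is
    admissible only within a per-trajectory gate of
    ``gate_factor * sqrt(r2bar * gap)`` where ``r2bar`` is the running mean
    squared one-frame displacement of that trajectory, initialized from
    ``d_init`` (a generous upper bound on the expected mobility).  Track
    ends persist unmatched for up to ``max_gap`` frames before closing.
    Every localization is used exactly once.
    """
    locs = localizations
    if channel is None:
        channel = str(locs.channel.iloc[0]) if "channel" in locs and len(locs) else "A"
    if len(locs) == 0:
        return []
    frames = locs.frame.to_numpy()
    xy = locs[["x_um", "y_um"]].to_numpy()
    prec = (
        locs.precision_um.to_numpy()
        if "precision_um" in locs
        else np.zeros(len(locs))
    )
    r2_init = 4.0 * d_init * frame_interval

    active: list[_Track] = []
    done: list[_Track] = []
    next_id = 0
    uniq = np.unique(frames)
    pos_by_frame = {int(f): np.flatnonzero(frames == f) for f in uniq}

    for f in uniq:
        f = int(f)
        still: list[_Track] = []
        for tr in active:
            (done if f - tr.frames[-1] > max_gap + 1 else still).append(tr)
        active = still

        pidx = pos_by_frame[f]
        pts = xy[pidx]
        n_p = len(pidx)
        assigned_pt = np.zeros(n_p, dtype=bool)
        if active and n_p:
            tree = cKDTree(pts)
            # candidate edges within each track's gate
            edges: list[tuple[int, int, float]] = []
            for ti, tr in enumerate(active):
                gap = f - tr.frames[-1]
                gate = gate_factor * math.sqrt(max(tr.r2bar, 1e-12) * gap)
                last = np.array([tr.xs[-1], tr.ys[-1]])
                for pi in tree.query_ball_point(last, gate):
                    d2 = float(((pts[pi] - last) ** 2).sum())
                    edges.append((ti, pi, d2))
            if edges:
                for t_group, p_group, cost in _components(edges, len(active), n_p):
                    ri, ci = linear_sum_assignment(cost)
                    for a, b in zip(ri, ci):
                        if cost[a, b] >= 1e11:  # outside every gate
                            continue
                        tr = active[t_group[a]]
                        pi = p_group[b]
                        gi = int(pidx[pi])
                        gap = f - tr.frames[-1]
                        step2 = cost[a, b] / gap
                        tr.n_steps += 1
                        w = min(0.2, 1.0 / tr.n_steps)
                        tr.r2bar = (1 - w) * tr.r2bar + w * step2
                        tr.frames.append(f)
                        tr.xs.append(float(pts[pi, 0]))
                        tr.ys.append(float(pts[pi, 1]))
                        tr.precs.append(float(prec[gi]))
                        tr.idx.append(gi)
                        assigned_pt[pi] = True
        for pi in np.nonzero(~assigned_pt)[0]:
            gi = int(pidx[pi])
            active.append(
                _Track(
                    next_id, [f], [float(pts[pi, 0])], [float(pts[pi, 1])],
                    [float(prec[gi])], [gi], r2_init,
                )
            )
            next_id += 1
    done.extend(active)

    out = [
        Trajectory(
            tr.tid,
            np.array(tr.frames),
            np.array(tr.xs),
            np.array(tr.ys),
            np.array(tr.precs),
            channel,
            np.array(tr.idx),
        )
        for tr in sorted(done, key=lambda t: t.tid)
    ]
    return out


def _components(edges, n_tracks, n_pts):
    """Split candidate edges into connected components; yield per-component
    (track indices, point indices, dense cost matrix)."""
    parent = list(range(n_tracks + n_pts))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for ti, pi, _ in edges:
        ra, rb = find(ti), find(n_tracks + pi)
        if ra != rb:
            parent[ra] = rb
    groups: dict[int, tuple[list[int], list[int], list]] = {}
    for ti, pi, d2 in edges:
        root = find(ti)
        groups.setdefault(root, ([], [], []))
        g = groups[root]
        if ti not in g[0]:
            g[0].append(ti)
        if pi not in g[1]:
            g[1].append(pi)
        g[2].append((ti, pi, d2))
    for t_group, p_group, es in groups.values():
        cost = np.full((len(t_group), len(p_group)), np.inf)
        tmap = {t: i for i, t in enumerate(t_group)}
        pmap = {p: i for i, p in enumerate(p_group)}
        for ti, pi, d2 in es:
            cost[tmap[ti], pmap[pi]] = d2
        big = 1e12
        yield t_group, p_group, np.where(np.isfinite(cost), cost, big)


def compute_msd(traj: Trajectory, max_lag: int = 5, frame_interval: float = 0.032) -> pd.DataFrame:
    """Time-averaged MSD of one trajectory with inverse-variance weights.

    For lag ``k`` frames, all position pairs exactly ``k`` frames apart and
    not spanning a detection gap contribute.  Weights follow the standard
    finite-trajectory variance approximation for free diffusion
    (var ~ msd^2 * (2k^2+1) / (3k * n_pairs)); lags without valid pairs
    are omitted.
    """
    runs = traj.contiguous_runs()
    pos = traj.positions()
    rows = []
    for k in range(1, max_lag + 1):
        sq = []
        for run in runs:
            if len(run) > k:
                d = pos[run[k:]] - pos[run[:-k]]
                sq.append((d * d).sum(axis=1))
        if not sq:
            continue
        sq = np.concatenate(sq)
        msd = float(sq.mean())
        n = len(sq)
        # expected variance under the free-diffusion model (msd ~ lag), so
        # the weights do not depend on the realized msd values: var_k is
        # proportional to k * (2k^2 + 1) / (3 n_k)
        var_shape = k * (2 * k * k + 1) / (3.0 * n)
        rows.append(
            {
                "lag_frames": k,
                "tau_s": k * frame_interval,
                "msd_um2": msd,
                "n_pairs": n,
                "weight": 1.0 / var_shape,
            }
        )
    return pd.DataFrame(rows)


def fit_diffusion(
    msd: pd.DataFrame,
    frame_interval: float = 0.032,
    n_lags: int = 5,
) -> DiffusionFit | None:
    """Weighted least-squares fit of the blur- and noise-corrected MSD model.

    Fits ``msd = (4 D) tau + (4 eps^2 - 4/3 D dt)`` over at most the first
    ``n_lags`` lags, weighting by the inverse expected variances.  Returns
    ``None`` when fewer than two usable lags exist.  A negative implied
    ``eps^2`` is clipped to zero and flagged.
    """
    use = msd[msd.lag_frames <= n_lags]
    if len(use) < 2:
        return None
    tau = use.tau_s.to_numpy()
    y = use.msd_um2.to_numpy()
    w = use.weight.to_numpy()
    if not np.isfinite(w).all() or (w <= 0).any():
        w = np.ones_like(tau)
    X = np.column_stack([tau, np.ones_like(tau)])
    sw = np.sqrt(w)
    beta, res, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    slope, intercept = beta
    d = slope / 4.0
    eps2 = (intercept + (4.0 / 3.0) * d * frame_interval) / 4.0
    negative = bool(eps2 < 0)
    eps = math.sqrt(max(eps2, 0.0))
    resid = float(res[0]) if np.size(res) else 0.0
    return DiffusionFit(float(d), eps, len(use), resid, negative, use)


def fit_trajectories(
    trajectories: list[Trajectory],
    frame_interval: float = 0.032,
    min_obs: int = 10,
    n_lags: int = 5,
) -> tuple[pd.DataFrame, dict]:
    """Per-trajectory MSD fits and the ensemble mobility summary.

    Trajectories observed for more than ``min_obs`` frames are fitted
    individually; the reported ensemble diffusion coefficient is the
    median over trajectories with non-negative fitted D (robust to the
    heavy right tail of short-trajectory estimates).  Trajectories with
    negative fitted D are excluded from the summary and counted.
    """
    rows = []
    for tr in trajectories:
        if len(tr) <= min_obs:
            continue
        fit = fit_diffusion(compute_msd(tr, n_lags, frame_interval), frame_interval, n_lags)
        if fit is None:
            continue
        rows.append(
            {
                "trajectory_id": tr.id,
                "D_um2_s": fit.d,
                "epsilon_um": fit.epsilon,
                "n_frames": len(tr),
                "negative_eps2": fit.negative_eps2,
            }
        )
    fits = pd.DataFrame(
        rows,
        columns=["trajectory_id", "D_um2_s", "epsilon_um", "n_frames",
                 "negative_eps2"],
    )
    valid = fits[fits.D_um2_s >= 0]
    summary = {
        "median_D_um2_s": float(valid.D_um2_s.median()) if len(valid) else float("nan"),
        "iqr_D_um2_s": (
            float(valid.D_um2_s.quantile(0.75) - valid.D_um2_s.quantile(0.25))
            if len(valid)
            else float("nan")
        ),
        "n_fitted": int(len(fits)),
        "n_negative_D": int((fits.D_um2_s < 0).sum()),
    }
    return fits, summary


def trajectories_to_frame(trajectories: list[Trajectory]) -> pd.DataFrame:
    """Flatten trajectories into a (trajectory_id, frame, x, y) table."""
    if not trajectories:
        return pd.DataFrame(columns=["trajectory_id", "frame", "x_um", "y_um"])
    return pd.DataFrame(
        {
            "trajectory_id": np.concatenate(
                [np.full(len(t), t.id) for t in trajectories]
            ),
            "frame": np.concatenate([t.frames for t in trajectories]),
            "x_um": np.concatenate([t.x for t in trajectories]),
            "y_um": np.concatenate([t.y for t in trajectories]),
        }
    )
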
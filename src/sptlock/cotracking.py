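"""Channel registration and dual-color co-tracking.

Two spectral channels observing stochastically labeled receptor complexes
are first registered with an affine transform calibrated on multicolor
bead localizations, then scanned for co-locomotion: pairs of trajectories,
one per channel, that stay within a capture radius (default 150 nm) for a
minimum number of consecutive frames (default 10 frames = 320 ms).  Such
co-trajectories identify complexes carrying at least one label of each
color; the dual-labeled fraction is reported per frame relative to the
total number of localizations of the population (mobile or immobile) and
averaged over time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .tracking import Trajectory, trajectories_to_frame

__all__ = [
    "ChannelTransform",
    "calibrate_transform",
    "cotrack",
    "cotrack_events",
    "CoTrackResult",
]

# Cost multiplier favoring continuation of an existing pairing.  For two
# coincident same-channel emitters (a complex carrying two labels of one
# color) the per-frame distances to the partner are iid noise draws; an
# un-penalized optimal assignment then switches identity with probability
# 1/2 per frame and no pair ever satisfies the consecutive-frames
# criterion.  With factor c the switch probability is c/(1+c) (~5% here),
# small enough that genuine co-movers accumulate qualifying runs while a
# closer *new* partner still wins once it is substantially closer.
PERSISTENCE_FACTOR = 0.05


@dataclass
class ChannelTransform:
    """Affine map from channel-B um coordinates onto channel A."""

    matrix: np.ndarray  # 2x3
    residual_rmse: float
    n_beads: int

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, float))
        return xy @ self.matrix[:, :2].T + self.matrix[:, 2]

    @classmethod
    def identity(cls) -> "ChannelTransform":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]), 0.0, 0)


def calibrate_transform(
    beads_a: np.ndarray, beads_b: np.ndarray
) -> ChannelTransform:
    """Least-squares affine registration from matched bead localizations.

    Requires at least three non-collinear bead pairs; reports the residual
    RMSE (should be at the bead-localization noise level, well below 20 nm
    for a valid calibration).
    """
    a = np.asarray(beads_a, float)
    b = np.asarray(beads_b, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 2:
        raise ValueError("bead arrays must be matched (n, 2) coordinates")
    if len(a) < 3:
        raise ValueError("need at least 3 bead pairs")
    centered = b - b.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValueError("bead positions are collinear; affine fit is degenerate")
    design = np.column_stack([b, np.ones(len(b))])
    coef, *_ = np.linalg.lstsq(design, a, rcond=None)  # (3, 2)
    matrix = coef.T  # (2, 3)
    resid = a - design @ coef
    rmse = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return ChannelTransform(matrix, rmse, len(a))


@dataclass
class CoTrackResult:
    """Co-trajectories and time-averaged dual-labeled fractions."""

    cotrajectories: pd.DataFrame
    dual_fraction: float  # co-locomoting / total localizations (time avg)
    n_frames_used: int

    @property
    def n_cotrajectories(self) -> int:
        return len(self.cotrajectories)


def _pair_frames(
    pos_a: pd.DataFrame, pos_b: pd.DataFrame, radius: float
) -> pd.DataFrame:
    """One-to-one nearest pairing of A and B positions per frame.

    Conflicts are resolved by minimum total squared distance (optimal
    assignment per connected component of the candidate graph), with a
    persistence preference: a combination already paired in the previous
    frame has its cost scaled down by ``PERSISTENCE_FACTOR``.  Without this hysteresis, complexes that
    carry two same-color labels (near-coincident trajectories) make the
    pairing identity flicker between the equidistant twins and break the
    consecutive co-localization runs the co-tracking criterion requires.
    """
    matches = []
    frames = np.intersect1d(pos_a.frame.unique(), pos_b.frame.unique())
    a_by_frame = dict(tuple(pos_a.groupby("frame")))
    b_by_frame = dict(tuple(pos_b.groupby("frame")))
    prev_pairs: set[tuple[int, int]] = set()
    for f in frames:
        da, db = a_by_frame[f], b_by_frame[f]
        pa = da[["x_um", "y_um"]].to_numpy()
        pb = db[["x_um", "y_um"]].to_numpy()
        ids_a = da.trajectory_id.to_numpy()
        ids_b = db.trajectory_id.to_numpy()
        tree = cKDTree(pb)
        neighbor_lists = tree.query_ball_point(pa, radius)
        edges = []
        true_d2 = {}
        for i, nb in enumerate(neighbor_lists):
            for j in nb:
                d2 = float(((pa[i] - pb[j]) ** 2).sum())
                true_d2[i, j] = d2
                if (int(ids_a[i]), int(ids_b[j])) in prev_pairs:
                    d2 *= PERSISTENCE_FACTOR
                edges.append((i, j, d2))
        if not edges:
            prev_pairs = set()
            continue
        cur_pairs = set()
        for ia, jb, _ in _assign(edges):
            ta, tb = int(ids_a[ia]), int(ids_b[jb])
            cur_pairs.add((ta, tb))
            matches.append(
                {
                    "frame": int(f),
                    "traj_a": ta,
                    "traj_b": tb,
                    "sep_um": math.sqrt(true_d2[ia, jb]),
                }
            )
        prev_pairs = cur_pairs
    return pd.DataFrame(matches, columns=["frame", "traj_a", "traj_b", "sep_um"])


def _assign(edges):
    a_ids = sorted({e[0] for e in edges})
    b_ids = sorted({e[1] for e in edges})
    amap = {a: i for i, a in enumerate(a_ids)}
    bmap = {b: i for i, b in enumerate(b_ids)}
    big = 1e12
    cost = np.full((len(a_ids), len(b_ids)), big)
    for i, j, d2 in edges:
        cost[amap[i], bmap[j]] = d2
    ri, ci = linear_sum_assignment(cost)
    for r, c in zip(ri, ci):
        if cost[r, c] < big:
            yield a_ids[r], b_ids[c], cost[r, c]


def cotrack(
    trajectories_a: list[Trajectory],
    trajectories_b: list[Trajectory],
    transform: ChannelTransform | None = None,
    radius: float = 0.150,
    min_coframes: int = 10,
    max_break: int = 0,
    total_localizations: pd.DataFrame | None = None,
) -> CoTrackResult:
    """Identify co-locomoting trajectory pairs across the two channels.

    Channel-B positions are mapped through ``transform`` before pairing.
    A co-trajectory is a maximal run of at least ``min_coframes``
    consecutive frames in which the same (A, B) trajectory pair is matched
    within ``radius``; by default any interruption breaks the run
    (``max_break`` frames of interruption can be tolerated by
    configuration).

    The dual-labeled fraction is computed per frame as the number of
    localizations participating in a co-trajectory divided by the total
    number of localizations in both channels, averaged over frames.
    """
    if transform is None:
        transform = ChannelTransform.identity()
    pos_a = trajectories_to_frame(trajectories_a)
    pos_b = trajectories_to_frame(trajectories_b)
    if len(pos_b):
        mapped = transform.apply(pos_b[["x_um", "y_um"]].to_numpy())
        pos_b = pos_b.assign(x_um=mapped[:, 0], y_um=mapped[:, 1])
    n_total = len(pos_a) + len(pos_b)
    if n_total == 0:
        return CoTrackResult(
            pd.DataFrame(
                columns=["co_id", "traj_a", "traj_b", "start_frame",
                         "end_frame", "n_frames", "mean_sep_nm", "class"]
            ),
            0.0,
            0,
        )

    matches = _pair_frames(pos_a, pos_b, radius)
    runs = []
    if len(matches):
        for (ta, tb), grp in matches.groupby(["traj_a", "traj_b"]):
            fr = np.sort(grp.frame.to_numpy())
            sep = grp.sort_values("frame").sep_um.to_numpy()
            breaks = np.flatnonzero(np.diff(fr) > max_break + 1)
            for seg in np.split(np.arange(len(fr)), breaks + 1):
                if len(seg) >= min_coframes:
                    runs.append(
                        {
                            "traj_a": ta,
                            "traj_b": tb,
                            "start_frame": int(fr[seg[0]]),
                            "end_frame": int(fr[seg[-1]]),
                            "n_frames": len(seg),
                            "mean_sep_nm": float(sep[seg].mean() * 1e3),
                        }
                    )
    coords = pd.DataFrame(
        runs,
        columns=["traj_a", "traj_b", "start_frame", "end_frame", "n_frames",
                 "mean_sep_nm"],
    ).sort_values(["start_frame", "traj_a"], ignore_index=True)
    coords.insert(0, "co_id", np.arange(len(coords)))
    coords["class"] = "mobile"  # immobile pairs come from cotrack_events

    # per-frame dual-labeled fraction over the union of both channels
    count_by_frame = pd.concat([pos_a.frame, pos_b.frame]).value_counts()
    co_by_frame: dict[int, int] = {}
    for run in coords.itertuples(index=False):
        grp = matches[
            (matches.traj_a == run.traj_a)
            & (matches.traj_b == run.traj_b)
            & (matches.frame >= run.start_frame)
            & (matches.frame <= run.end_frame)
        ]
        for f in grp.frame:
            co_by_frame[int(f)] = co_by_frame.get(int(f), 0) + 2
    frac = pd.Series(co_by_frame, dtype=float).reindex(
        count_by_frame.index, fill_value=0.0
    ) / count_by_frame
    return CoTrackResult(coords, float(frac.mean()), int(len(count_by_frame)))


def cotrack_events(
    events_a: pd.DataFrame,
    events_b: pd.DataFrame,
    transform: ChannelTransform | None = None,
    radius: float = 0.150,
    min_coframes: int = 10,
) -> pd.DataFrame:
    """Co-classify immobilization events across channels.

    Events from the two channels are paired (one-to-one, minimum centroid
    distance) when their centroids fall within ``radius`` after mapping
    channel B through ``transform`` and their frame spans overlap by at
    least ``min_coframes`` frames.
    """
    if transform is None:
        transform = ChannelTransform.identity()
    cols = ["event_a", "event_b", "centroid_dist_nm", "overlap_frames"]
    if len(events_a) == 0 or len(events_b) == 0:
        return pd.DataFrame(columns=cols)
    ca = events_a[["centroid_x_um", "centroid_y_um"]].to_numpy()
    cb = transform.apply(events_b[["centroid_x_um", "centroid_y_um"]].to_numpy())
    edges = []
    for i in range(len(ca)):
        for j in range(len(cb)):
            d2 = float(((ca[i] - cb[j]) ** 2).sum())
            if d2 > radius * radius:
                continue
            lo = max(events_a.start_frame.iloc[i], events_b.start_frame.iloc[j])
            hi = min(events_a.end_frame.iloc[i], events_b.end_frame.iloc[j])
            if hi - lo + 1 >= min_coframes:
                edges.append((i, j, d2))
    rows = [
        {
            "event_a": int(events_a.event_id.iloc[i]),
            "event_b": int(events_b.event_id.iloc[j]),
            "centroid_dist_nm": math.sqrt(d2) * 1e3,
            "overlap_frames": int(
                min(events_a.end_frame.iloc[i], events_b.end_frame.iloc[j])
                - max(events_a.start_frame.iloc[i], events_b.start_frame.iloc[j])
                + 1
            ),
        }
        for i, j, d2 in _assign(edges)
    ]
    return pd.DataFrame(rows, columns=cols)
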
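"""Spatiotemporal clustering of localizations into immobilization events.

Before trajectory linking, the localization table is scanned for transient
immobilization: dense clusters of localizations from consecutive frames
that stay within a small search radius (default 120 nm) for longer than a
minimum duration (default 20 frames, i.e. 640 ms at 32 ms/frame).  The
approach adapts the density-based clustering (DBSCAN) idea to the time
axis: a cluster grows frame by frame while the nearest next-frame
localization lies within ``eps_radius`` of the running centroid, tolerating
short detection gaps.  Localizations belonging to accepted events form the
immobile population; the remainder are handed to the tracker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = ["ImmobileResult", "find_immobile"]


@dataclass
class _Cluster:
    start_frame: int
    last_frame: int
    centroid: np.ndarray
    members: list[int] = field(default_factory=list)

    @property
    def span(self) -> int:
        return self.last_frame - self.start_frame + 1


@dataclass
class ImmobileResult:
    """Outcome of immobilization-event detection on one channel."""

    events: pd.DataFrame  # event_id, centroid, start/end frame, n_localizations
    immobile_mask: pd.Series  # bool, aligned with the input index
    per_frame_fraction: pd.Series  # immobile / total localizations per frame
    immobile_fraction: float  # time average of per-frame fractions (NaN if empty)

    @property
    def n_events(self) -> int:
        return len(self.events)


def find_immobile(
    localizations: pd.DataFrame,
    eps_radius: float = 0.120,
    min_frames: int = 20,
    max_gap: int = 3,
) -> ImmobileResult:
    """Detect transient immobilization events in a localization table.

    Parameters
    ----------
    localizations:
        One channel's table with columns ``frame``, ``x_um``, ``y_um``.
    eps_radius:
        Search radius in um around the running cluster centroid.
    min_frames:
        Minimum temporal extent; an event must span *more* than this many
        frames (default 20 frames = 640 ms at 32 ms/frame) and contain
        more than this many member localizations.
    max_gap:
        Number of consecutive missing frames tolerated inside an event.

    Returns
    -------
    ImmobileResult
        Events table, per-localization immobile flag, per-frame immobile
        fraction and its time average.  The mobile subset and the event
        members partition the input exactly.
    """
    if eps_radius <= 0:
        raise ValueError("eps_radius must be positive")
    if min_frames < 1:
        raise ValueError("min_frames must be >= 1")
    locs = localizations
    mask = pd.Series(False, index=locs.index)
    if len(locs) == 0:
        empty = pd.DataFrame(
            columns=["event_id", "centroid_x_um", "centroid_y_um",
                     "start_frame", "end_frame", "n_localizations"]
        )
        return ImmobileResult(empty, mask, pd.Series(dtype=float), float("nan"))

    frames = locs.frame.to_numpy()
    xy = locs[["x_um", "y_um"]].to_numpy()
    order = np.argsort(frames, kind="stable")
    idx_by_frame: dict[int, np.ndarray] = {}
    for f in np.unique(frames):
        idx_by_frame[int(f)] = order[frames[order] == f]

    active: list[_Cluster] = []
    finished: list[_Cluster] = []

    def _close_stale(frame: int) -> None:
        nonlocal active
        still = []
        for cl in active:
            if frame - cl.last_frame > max_gap + 1:
                finished.append(cl)
            else:
                still.append(cl)
        active = still

    for f in sorted(idx_by_frame):
        _close_stale(f)
        pts_idx = idx_by_frame[f]
        pts = xy[pts_idx]
        assigned = np.zeros(len(pts_idx), dtype=bool)
        if active and len(pts_idx):
            tree = cKDTree(pts)
            # candidate (distance, cluster, point) triples within eps of the
            # running centroids, resolved greedily by increasing distance
            pairs: list[tuple[float, int, int]] = []
            for ci, cl in enumerate(active):
                for pi in tree.query_ball_point(cl.centroid, eps_radius):
                    d = float(np.hypot(*(pts[pi] - cl.centroid)))
                    pairs.append((d, ci, pi))
            pairs.sort()
            taken_cl: set[int] = set()
            for d, ci, pi in pairs:
                if ci in taken_cl or assigned[pi]:
                    continue
                cl = active[ci]
                gi = int(pts_idx[pi])
                n = len(cl.members)
                cl.centroid = (cl.centroid * n + pts[pi]) / (n + 1)
                cl.members.append(gi)
                cl.last_frame = f
                taken_cl.add(ci)
                assigned[pi] = True
        for pi in np.nonzero(~assigned)[0]:
            gi = int(pts_idx[pi])
            active.append(_Cluster(f, f, xy[gi].copy(), [gi]))
    finished.extend(active)

    rows = []
    for cl in sorted(finished, key=lambda c: (c.start_frame, -c.span)):
        # an event must both span more than min_frames and be supported by
        # more than min_frames member localizations; the latter keeps
        # gap-bridged chance encounters of mobile particles from
        # accumulating into spurious events
        if cl.span > min_frames and len(cl.members) > min_frames:
            rows.append(cl)
            mask.iloc[cl.members] = True
    events = pd.DataFrame(
        {
            "event_id": np.arange(len(rows)),
            "centroid_x_um": [c.centroid[0] for c in rows],
            "centroid_y_um": [c.centroid[1] for c in rows],
            "start_frame": [c.start_frame for c in rows],
            "end_frame": [c.last_frame for c in rows],
            "n_localizations": [len(c.members) for c in rows],
        }
    )

    per_frame = (
        pd.DataFrame({"frame": frames, "immobile": mask.to_numpy()})
        .groupby("frame")["immobile"]
        .mean()
    )
    return ImmobileResult(events, mask, per_frame, float(per_frame.mean()))
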
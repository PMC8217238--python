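"""Confinement-index analysis of transient arrest within trajectories.

Alternation between free diffusion and nanodomain trapping is detected by
probing, in a sliding window (default 10 frames = 320 ms), how improbable
the window's maximal excursion would be under free Brownian motion with a
null diffusion coefficient (the mobility of the unperturbed receptor
monomer, 0.19 um^2/s by default).  The Simson-Sheetz approximation

    log10(psi) = 0.2048 - 2.5117 * (D_null * t_w) / R_w^2

gives the probability psi that free motion stays within the observed
excursion radius ``R_w`` over the window duration ``t_w``; the confinement
index is ``L = max(0, -log10 psi)``.  The arrest threshold ``L*`` is not
taken from the analytic form but calibrated by Monte-Carlo simulation of
free Brownian motion (with localization noise) at a fixed false-positive
rate (default 1e-3), which absorbs any miscalibration of the
approximation.  Thresholded state sequences yield maximum-likelihood
transition probabilities of the two-state (mobile/arrested) chain, and the
nanodomain diameter follows from the MSD plateau of arrested segments
(plateau = R^2 + 4 eps^2 for uniform positions in a disc of radius R).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracking import Trajectory

__all__ = [
    "ConfinementProfile",
    "TransitionEstimate",
    "confinement_index",
    "calibrate_threshold",
    "segment_states",
    "confined_fraction",
    "estimate_transitions",
    "estimate_domain_size",
]

# Simson-Sheetz coefficients for the stay-inside probability of 2D
# Brownian motion; any residual inaccuracy of this closed form is absorbed
# by the Monte-Carlo threshold calibration.
_SS_INTERCEPT = 0.2048
_SS_SLOPE = 2.5117

MIN_TRAJECTORY_FRAMES = 100  # confinement is probed only on long trajectories


@dataclass
class ConfinementProfile:
    """Per-frame confinement index of one trajectory.

    ``l_index`` is aligned with ``frames``; window edges (and frames whose
    window spans a detection gap) are NaN.
    """

    trajectory_id: int
    frames: np.ndarray
    l_index: np.ndarray
    window: int
    d_null: float


@dataclass
class TransitionEstimate:
    """ML estimates of the two-state mobile/arrested chain."""

    p_arrest: float  # per-frame mobile -> arrested
    p_release: float  # per-frame arrested -> mobile
    counts: np.ndarray  # 2x2 transition counts [from, to]
    dwell_mobile_frames: np.ndarray
    dwell_arrested_frames: np.ndarray

    def mean_dwell_arrested(self, frame_interval: float) -> float:
        if len(self.dwell_arrested_frames) == 0:
            return float("nan")
        return float(self.dwell_arrested_frames.mean() * frame_interval)


def _window_l(
    pos: np.ndarray, window: int, d_null: float, frame_interval: float
) -> np.ndarray:
    """Confinement index per window start for a gap-free position array."""
    n = len(pos)
    n_win = n - window + 1
    if n_win <= 0:
        return np.empty(0)
    t_w = window * frame_interval
    # maximal excursion from the window's first point, vectorized over starts
    win = np.lib.stride_tricks.sliding_window_view(pos, (window,), axis=0)
    d = win[:, :, 1:] - win[:, :, :1]  # (n_win, 2, window-1)
    r2 = (d * d).sum(axis=1).max(axis=1)
    log_psi = _SS_INTERCEPT - _SS_SLOPE * d_null * t_w / np.maximum(r2, 1e-12)
    return np.maximum(0.0, -log_psi)


def confinement_index(
    traj: Trajectory,
    window: int = 10,
    d_null: float = 0.19,
    frame_interval: float = 0.032,
) -> ConfinementProfile:
    """Sliding-window confinement index along one trajectory.

    The profile is aligned to window centers; frames within half a window
    of the trajectory ends, or whose window would span a detection gap,
    are NaN.  Only trajectories longer than 100 frames are analyzed.
    """
    if d_null <= 0:
        raise ValueError("d_null must be positive")
    if len(traj) < window:
        raise ValueError("trajectory shorter than the window")
    if traj.span <= MIN_TRAJECTORY_FRAMES:
        raise ValueError(
            f"confinement is only probed on trajectories spanning more than "
            f"{MIN_TRAJECTORY_FRAMES} frames"
        )
    l_of_frame = np.full(len(traj), np.nan)
    pos = traj.positions()
    for run in traj.contiguous_runs():
        lw = _window_l(pos[run], window, d_null, frame_interval)
        for i, val in enumerate(lw):
            l_of_frame[run[i + window // 2]] = val
    return ConfinementProfile(traj.id, traj.frames.copy(), l_of_frame, window, d_null)


def calibrate_threshold(
    d_null: float = 0.19,
    window: int = 10,
    n_sim: int = 200_000,
    alpha_conf: float = 1e-3,
    loc_noise_sigma: float = 0.020,
    frame_interval: float = 0.032,
    seed: int = 12345,
) -> float:
    """Monte-Carlo calibration of the arrest threshold ``L*``.

    Simulates ``n_sim`` independent windows of free Brownian motion with
    ``d_null`` plus per-axis localization noise, and returns the empirical
    ``1 - alpha_conf`` quantile of the confinement index: the threshold at
    which free motion is falsely called arrested at rate ``alpha_conf``.
    Deterministic given the seed.
    """
    if not 0 < alpha_conf < 1:
        raise ValueError("alpha_conf must be in (0, 1)")
    required = int(math.ceil(100.0 / alpha_conf))
    if n_sim < required:
        raise ValueError(
            f"n_sim = {n_sim} too small for a stable quantile at "
            f"alpha_conf = {alpha_conf}; need at least {required}"
        )
    rng = np.random.default_rng(seed)
    sd = math.sqrt(2.0 * d_null * frame_interval)
    steps = rng.normal(0.0, sd, (n_sim, window - 1, 2))
    pos = np.concatenate(
        [np.zeros((n_sim, 1, 2)), np.cumsum(steps, axis=1)], axis=1
    )
    if loc_noise_sigma > 0:
        pos = pos + rng.normal(0.0, loc_noise_sigma, pos.shape)
    d = pos[:, 1:, :] - pos[:, :1, :]
    r2 = (d * d).sum(axis=2).max(axis=1)
    t_w = window * frame_interval
    l_vals = np.maximum(
        0.0, _SS_SLOPE * d_null * t_w / np.maximum(r2, 1e-12) - _SS_INTERCEPT
    )
    return float(np.quantile(l_vals, 1.0 - alpha_conf))


def segment_states(
    profile: ConfinementProfile,
    l_star: float,
    min_arrest_frames: int = 10,
) -> np.ndarray:
    """Threshold a confinement profile into mobile (0)/arrested (1) states.

    Frames whose window index exceeds ``l_star`` are marked arrested;
    arrest runs shorter than ``min_arrest_frames`` (default one full
    window) are discarded.  NaN frames count as mobile.
    """
    arrested = np.where(np.isnan(profile.l_index), False, profile.l_index > l_star)
    states = arrested.astype(np.uint8)
    if min_arrest_frames > 1 and states.any():
        edges = np.flatnonzero(np.diff(np.r_[0, states, 0]))
        for a, b in zip(edges[::2], edges[1::2]):
            if b - a < min_arrest_frames:
                states[a:b] = 0
    return states


def confined_fraction(state_sequences: list[np.ndarray]) -> float:
    """Fraction of analyzed trajectories containing >= 1 arrest event."""
    if not state_sequences:
        return float("nan")
    return float(np.mean([s.any() for s in state_sequences]))


def estimate_transitions(state_sequences: list[np.ndarray]) -> TransitionEstimate:
    """Fully-observed ML transition probabilities of the two-state chain.

    Transition counts are pooled over trajectories; transitions are never
    counted across trajectory boundaries.  If a state has zero occupancy
    its outgoing probability is reported as NaN.
    """
    seqs = [np.asarray(s).astype(int) for s in state_sequences if len(s) >= 2]
    if not seqs:
        raise ValueError("need at least one state sequence with >= 2 frames")
    counts = np.zeros((2, 2), dtype=np.int64)
    dwell_m, dwell_a = [], []
    for s in seqs:
        np.add.at(counts, (s[:-1], s[1:]), 1)
        edges = np.flatnonzero(np.diff(np.r_[-1, s, -1]) != 0)
        for a, b in zip(edges[:-1], edges[1:]):
            (dwell_a if s[a] == 1 else dwell_m).append(b - a)
    row0, row1 = counts.sum(axis=1)
    p_arrest = counts[0, 1] / row0 if row0 > 0 else float("nan")
    p_release = counts[1, 0] / row1 if row1 > 0 else float("nan")
    return TransitionEstimate(
        float(p_arrest),
        float(p_release),
        counts,
        np.array(dwell_m),
        np.array(dwell_a),
    )


def estimate_domain_size(
    arrested_segments: list[np.ndarray],
    loc_noise_sigma: float,
    min_lag: int = 6,
    max_lag: int = 20,
) -> dict:
    """Nanodomain diameter from the MSD plateau of arrested segments.

    For positions uniformly distributed in a disc of radius R observed
    with per-axis localization error eps, the MSD at decorrelated lags
    plateaus at ``R^2 + 4 eps^2`` (pair-displacement identity
    ``E|x1 - x2|^2 = R^2`` for a uniform disc).  The plateau is estimated
    as the pooled mean squared displacement over lags beyond 5 frames and
    the diameter is ``2 * sqrt(plateau - 4 eps^2)``; a negative radicand
    is reported as diameter 0 with a flag.
    """
    total = 0.0
    n_pairs = 0
    for seg in arrested_segments:
        seg = np.asarray(seg, float)
        for k in range(min_lag, max_lag + 1):
            if len(seg) > k:
                d = seg[k:] - seg[:-k]
                total += float((d * d).sum())
                n_pairs += len(d)
    if n_pairs == 0:
        return {
            "diameter_um": float("nan"),
            "plateau_um2": float("nan"),
            "n_pairs": 0,
            "negative_radicand": False,
        }
    plateau = total / n_pairs
    radicand = plateau - 4.0 * loc_noise_sigma**2
    negative = radicand < 0
    diameter = 0.0 if negative else 2.0 * math.sqrt(radicand)
    return {
        "diameter_um": diameter,
        "plateau_um2": plateau,
        "n_pairs": n_pairs,
        "negative_radicand": bool(negative),
    }
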
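"""Reproducible end-to-end runs binding the pipeline stages together.

``run_pipeline`` executes simulate -> (density QC) -> immobile clustering
-> tracking -> MSD fitting -> co-tracking -> confinement analysis on a
synthetic scenario described by a :class:`RunConfig`, writes the stage
artifacts (CSV/JSON) when an output directory is given, and returns a
summary with the headline quantities: immobile fraction, median mobile D,
dual-labeled fractions, confined fraction, transition probabilities and
nanodomain diameter.  Given the same configuration and seed the summary is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, confinement, cotracking, detection, synthetic, tracking
from .io import write_localizations, write_summary

__all__ = ["RunConfig", "PipelineQCError", "run_pipeline"]

log = logging.getLogger("sptlock")


class PipelineQCError(RuntimeError):
    """Raised when the particle-density QC gate rejects the data."""


@dataclass
class RunConfig:
    """Parameters of one pipeline run (defaults match the reference assay)."""

    scenario: synthetic.SimScenario = field(default_factory=synthetic.SimScenario)
    seed: int = 0
    outdir: str | None = None
    stop_after: str | None = None  # simulate|qc|cluster|track|cotrack|confine

    # stage parameters
    max_density: float = 1.0
    eps_radius: float = 0.120
    cluster_min_frames: int = 20
    cluster_max_gap: int = 3
    track_max_gap: int = 3
    gate_factor: float = 3.0
    d_init: float = 0.5
    cotrack_radius: float = 0.150
    min_coframes: int = 10
    window: int = 10
    alpha_conf: float = 1e-3
    d_null: float = 0.19
    min_arrest_frames: int = 10
    threshold_n_sim: int = 200_000

    _SCENARIO_KEYS = {f.name for f in dataclasses.fields(synthetic.SimScenario)}
    _TRAP_KEYS = {f.name for f in dataclasses.fields(synthetic.TrapModel)}

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        cfg = dict(cfg)
        known = {f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        sc_cfg = dict(cfg.pop("scenario", {}))
        unknown_sc = set(sc_cfg) - cls._SCENARIO_KEYS
        if unknown_sc:
            raise ValueError(f"unknown scenario keys: {sorted(unknown_sc)}")
        if "trap" in sc_cfg:
            trap_cfg = dict(sc_cfg["trap"])
            unknown_trap = set(trap_cfg) - cls._TRAP_KEYS
            if unknown_trap:
                raise ValueError(f"unknown trap keys: {sorted(unknown_trap)}")
            sc_cfg["trap"] = synthetic.TrapModel(**trap_cfg)
        if "fov" in sc_cfg:
            sc_cfg["fov"] = tuple(sc_cfg["fov"])
        if "oligomer_size_dist" in sc_cfg:
            sc_cfg["oligomer_size_dist"] = {
                int(k): float(v) for k, v in sc_cfg["oligomer_size_dist"].items()
            }
        scenario = synthetic.SimScenario(**sc_cfg)
        return cls(scenario=scenario, **cfg)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenario"]["fov"] = list(self.scenario.fov)
        return d


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline on a simulated scenario and summarize it."""
    sc = config.scenario.with_seed(config.seed)
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: seed=%d config=%s", config.seed, config.echo())

    summary: dict = {"seed": config.seed, "stage_reached": "simulate"}

    # --- simulate -----------------------------------------------------------
    observed, truth = synthetic.simulate_trajectories(sc)
    summary["n_complexes"] = truth.n_complexes
    if outdir:
        for ch, df in observed.items():
            write_localizations(df, outdir / f"localizations_{ch}.csv")
        truth.to_frame().to_csv(outdir / "ground_truth.csv", index=False)
        with open(outdir / "run_config.yaml", "w") as fh:
            yaml.safe_dump(config.echo(), fh, sort_keys=True)
    if config.stop_after == "simulate":
        return summary

    # --- density QC ---------------------------------------------------------
    qc = detection.density_qc(observed, sc.area, sc.n_frames, config.max_density)
    summary["density_um2"] = qc["density_um2"]
    summary["qc_accepted"] = qc["accepted"]
    summary["stage_reached"] = "qc"
    if not qc["accepted"]:
        log.warning("density QC rejected: %s", qc["density_um2"])
        raise PipelineQCError(
            f"observable particle density exceeds {config.max_density} um^-2: "
            f"{qc['density_um2']}"
        )
    if config.stop_after == "qc":
        return summary

    # --- immobile clustering ------------------------------------------------
    immobile: dict[str, clustering.ImmobileResult] = {}
    mobile: dict[str, pd.DataFrame] = {}
    for ch, df in observed.items():
        res = clustering.find_immobile(
            df, config.eps_radius, config.cluster_min_frames, config.cluster_max_gap
        )
        immobile[ch] = res
        mobile[ch] = df[~res.immobile_mask.to_numpy()] if len(df) else df
        if outdir:
            res.events.to_csv(outdir / f"immobile_events_{ch}.csv", index=False)
    summary["immobile_fraction"] = {
        ch: res.immobile_fraction for ch, res in immobile.items()
    }
    summary["stage_reached"] = "cluster"
    if config.stop_after == "cluster":
        return summary

    # --- tracking + MSD -----------------------------------------------------
    trajs: dict[str, list[tracking.Trajectory]] = {}
    for ch, df in mobile.items():
        trajs[ch] = tracking.link_trajectories(
            df,
            sc.frame_interval,
            config.track_max_gap,
            config.gate_factor,
            config.d_init,
            channel=ch,
        )
        if outdir:
            tracking.trajectories_to_frame(trajs[ch]).to_csv(
                outdir / f"trajectories_{ch}.csv", index=False
            )
    fits, mob = tracking.fit_trajectories(trajs["A"], sc.frame_interval)
    if outdir:
        fits.to_csv(outdir / "diffusion_fits_A.csv", index=False)
    summary["mobility"] = mob
    summary["stage_reached"] = "track"
    if config.stop_after == "track":
        return summary

    # --- co-tracking --------------------------------------------------------
    co = cotracking.cotrack(
        trajs["A"],
        trajs["B"],
        cotracking.ChannelTransform.identity(),
        config.cotrack_radius,
        config.min_coframes,
    )
    co_im = cotracking.cotrack_events(
        immobile["A"].events,
        immobile["B"].events,
        cotracking.ChannelTransform.identity(),
        config.cotrack_radius,
        config.min_coframes,
    )
    n_im_locs = int(
        immobile["A"].immobile_mask.sum() + immobile["B"].immobile_mask.sum()
    )
    co_im_locs = 0
    if len(co_im):
        for ev in co_im.itertuples(index=False):
            for res, col in ((immobile["A"], "event_a"), (immobile["B"], "event_b")):
                row = res.events[res.events.event_id == getattr(ev, col)]
                co_im_locs += int(row.n_localizations.iloc[0])
    summary["dual_fraction_mobile"] = co.dual_fraction
    summary["dual_fraction_immobile"] = (
        co_im_locs / n_im_locs if n_im_locs else float("nan")
    )
    summary["n_cotrajectories"] = co.n_cotrajectories
    if outdir:
        co.cotrajectories.to_csv(outdir / "cotrajectories.csv", index=False)
    summary["stage_reached"] = "cotrack"
    if config.stop_after == "cotrack":
        return summary

    # --- confinement --------------------------------------------------------
    # confinement analysis runs on unbiased trajectories (all localizations,
    # no immobile pre-filter): removing immobilization events first would
    # chop exactly the trajectories whose arrests are of interest
    unbiased = tracking.link_trajectories(
        observed["A"],
        sc.frame_interval,
        config.track_max_gap,
        config.gate_factor,
        config.d_init,
        channel="A",
    )
    l_star = confinement.calibrate_threshold(
        config.d_null,
        config.window,
        config.threshold_n_sim,
        config.alpha_conf,
        sc.loc_noise_sigma,
        sc.frame_interval,
        seed=config.seed + 997,
    )
    states = []
    arrested_segments: list[np.ndarray] = []
    for tr in unbiased:
        if tr.span <= confinement.MIN_TRAJECTORY_FRAMES or len(tr) < config.window:
            continue
        prof = confinement.confinement_index(
            tr, config.window, config.d_null, sc.frame_interval
        )
        s = confinement.segment_states(prof, l_star, config.min_arrest_frames)
        states.append(s)
        pos = tr.positions()
        edges = np.flatnonzero(np.diff(np.r_[0, s, 0]))
        for a, b in zip(edges[::2], edges[1::2]):
            arrested_segments.append(pos[a:b])
    summary["l_star"] = l_star
    summary["n_trajectories_confinement"] = len(states)
    if states:
        summary["confined_fraction"] = confinement.confined_fraction(states)
        try:
            est = confinement.estimate_transitions(states)
            summary["p_arrest"] = est.p_arrest
            summary["p_release"] = est.p_release
            summary["mean_dwell_arrested_s"] = est.mean_dwell_arrested(
                sc.frame_interval
            )
        except ValueError:
            summary["p_arrest"] = summary["p_release"] = float("nan")
        dom = confinement.estimate_domain_size(arrested_segments, sc.loc_noise_sigma)
        summary["domain_diameter_nm"] = (
            dom["diameter_um"] * 1e3 if np.isfinite(dom["diameter_um"]) else float("nan")
        )
    else:
        summary["confined_fraction"] = float("nan")
        summary["p_arrest"] = summary["p_release"] = float("nan")
        summary["domain_diameter_nm"] = float("nan")
    summary["stage_reached"] = "confine"

    if outdir:
        write_summary(summary, outdir / "summary.json")
    return summary
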
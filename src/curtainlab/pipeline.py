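"""End-to-end synthetic pipeline: simulate -> track -> MSD -> D -> salt fit
-> dwell kinetics -> report.

The pipeline is configured by a single declarative mapping (usually read
from YAML) with blocks: ``geometry``, ``optics``, ``simulation``,
``analysis``, ``buffer``/``conditions``, ``seed``.  Every run echoes the
config (with its hash) and the seed into the report, so results are
reproducible byte-for-byte given the same inputs.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from . import diffusion, ionic, kinetics
from .geometry import DnaGeometry
from .io import config_hash, write_report, write_trajectories
from .simulate import (
    SimulationConfig,
    observe_positions,
    simulate_dwell_times,
    simulate_population,
)
from .tracking import Trajectory, filter_trajectories

DEFAULT_STAGES = ("simulate", "msd", "dfit", "ionic", "saltfit", "dwell")


def synthetic_condition_tracks(
    d_um2_s: float,
    n_molecules: int,
    n_frames: int = 150,
    geometry: DnaGeometry = DnaGeometry(),
    loc_sigma_bp: float = 250.0,
    seed: int = 0,
) -> List[Trajectory]:
    """Pure-sliding population observed with localization noise."""
    cfg = SimulationConfig(
        d_slide_um2_s=d_um2_s, n_frames=n_frames, seed=seed, loc_sigma_bp=loc_sigma_bp
    )
    tracks = []
    for truth in simulate_population(cfg, n_molecules, geometry):
        rng = np.random.default_rng([seed, 1, truth.molecule_id])
        obs_bp = observe_positions(truth, loc_sigma_bp, rng=rng)
        tracks.append(
            Trajectory.from_positions_bp(
                obs_bp,
                frame_interval_s=cfg.frame_interval_s,
                geometry=geometry,
                molecule_id=truth.molecule_id,
            )
        )
    return tracks


def run_pipeline(
    config: dict,
    stages: Sequence[str] = DEFAULT_STAGES,
    outdir: Optional[str] = None,
) -> dict:
    """Execute the requested stages on synthetic data and return the report.

    ``conditions`` is a list of mappings with ``label``, ``d_um2_s``,
    ``n``, and optionally ``nacl_mM``; the salt-dependence fit consumes the
    per-condition mean D values of conditions that declare ``nacl_mM``.
    """
    stages = list(stages)
    known = {"simulate", "msd", "dfit", "ionic", "saltfit", "dwell"}
    unknown = set(stages) - known
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    if ("msd" in stages or "dfit" in stages) and "simulate" not in stages:
        raise ValueError("msd/dfit stages require the simulate stage")
    if "saltfit" in stages and "dfit" not in stages:
        raise ValueError("saltfit requires the dfit stage")

    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    geo_cfg = config.get("geometry", {})
    geometry = DnaGeometry(
        length_bp=int(geo_cfg.get("length_bp", 48502)),
        tether_span_um=float(geo_cfg.get("tether_span_um", 13.0)),
    )
    analysis = config.get("analysis", {})
    min_frames = int(analysis.get("min_frames", 50))
    n_lags = int(analysis.get("n_lags", 10))
    report: dict = {"stages": stages}

    summaries = []
    if "simulate" in stages:
        per_condition = []
        for ci, cond in enumerate(config.get("conditions", [])):
            tracks = synthetic_condition_tracks(
                d_um2_s=float(cond["d_um2_s"]),
                n_molecules=int(cond["n"]),
                n_frames=int(cond.get("n_frames", 150)),
                geometry=geometry,
                loc_sigma_bp=float(cond.get("loc_sigma_bp", 250.0)),
                seed=seed + ci,
            )
            kept, n_removed = filter_trajectories(tracks, min_frames)
            per_condition.append((cond, kept))
            if outdir is not None:
                write_trajectories(
                    Path(outdir) / f"trajectories_{cond['label']}.csv", kept, geometry
                )
        if "dfit" in stages:
            cond_reports = []
            for cond, kept in per_condition:
                est = diffusion.MsdDiffusionEstimator(n_lags=n_lags).fit(kept)
                summary = diffusion.summarize_population(est.estimates_, cond["label"])
                summaries.append((cond, summary))
                cond_reports.append(
                    {
                        "label": summary.label,
                        "mean_d_um2_s": summary.mean_d,
                        "sd_d_um2_s": summary.sd_d,
                        "n": summary.n,
                        "nacl_mM": cond.get("nacl_mM"),
                    }
                )
            report["conditions"] = cond_reports

    if "ionic" in stages:
        buf_cfg = config.get("buffer", {})
        buf = ionic.BufferComposition(
            tris_mM=float(buf_cfg.get("tris_mM", 40.0)),
            pH=float(buf_cfg.get("pH", 8.0)),
            tris_pKa=float(buf_cfg.get("tris_pKa", 8.1)),
            nacl_mM=float(buf_cfg.get("nacl_mM", 25.0)),
            mgcl2_mM=float(buf_cfg.get("mgcl2_mM", 2.0)),
        )
        mode = buf_cfg.get("mode", ionic.MODE_PAPER)
        res = ionic.total_ionic_strength(buf, mode)
        report["ionic"] = {
            "total_mM": res.total_mM,
            "contributions_mM": res.contributions_mM,
            "mode": res.mode,
        }

    if "saltfit" in stages:
        pts = []
        for cond, summary in summaries:
            if cond.get("nacl_mM") is None:
                continue
            buf = ionic.BufferComposition(nacl_mM=float(cond["nacl_mM"]))
            mode = config.get("buffer", {}).get("mode", ionic.MODE_PAPER)
            I = ionic.total_ionic_strength(buf, mode).total_mM
            pts.append((I, summary.mean_d))
        if len(pts) >= 2:
            fit = ionic.fit_salt_dependence(pts)
            report["salt_fit"] = {
                "slope": fit.slope,
                "slope_se": fit.slope_se,
                "screened_charges": fit.screened_charges,
                "screened_charges_se": fit.screened_charges_se,
                "points": fit.points,
            }

    if "dwell" in stages:
        dw_cfg = config.get("dwell", {})
        t_half = float(dw_cfg.get("t_half_s", 76.0))
        n = int(dw_cfg.get("n", 50))
        censor = float(dw_cfg.get("censor_at_s", np.inf))
        records = simulate_dwell_times(t_half, n, censor, seed=seed + 1000)
        fit = kinetics.fit_survival(records, method=dw_cfg.get("method", "lsq"))
        report["dwell"] = {
            "half_life_s": fit.half_life_s,
            "se_s": fit.se_s,
            "n": fit.n,
            "method": fit.method,
            "input_t_half_s": t_half,
        }

    report["config_hash"] = config_hash(config)
    report["seed"] = seed
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        write_report(Path(outdir) / "report.json", report, cfg=config, seed=seed)
    return report
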
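"""End-to-end simulation studies: simulate -> classify -> fit -> TILD -> dwell.

A :class:`StudyConfig` fully determines a study: the simulator settings,
how many replicate trajectories, which analyses to run, and the seed.  The
resulting :class:`StudyReport` carries the summary numbers (mode fractions,
ensemble fit parameters, dwell lifetimes, TILD counts, detectability /
accuracy) plus provenance (a hash of the configuration and the seed), and
every stochastic output is reproducible from (config, seed).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .msd import (
    compute_msd,
    ensemble_msd,
    estimate_short_term,
    fit_hop_diffusion,
    rd_null_thresholds,
    rd_statistic,
)
from .simulate import (
    HopSimConfig,
    add_localization_noise,
    simulate_brownian_trajectory,
    simulate_hop_ensemble,
    true_residencies,
)
from .tild import (
    TildParams,
    detect_tilds,
    fit_dwell_lifetime,
    hop_detection_scores,
    residency_durations,
)

log = logging.getLogger("spthop.study")


@dataclass
class StudyConfig:
    """One reproducible simulation study."""

    scenario: str  # "hop" or "brownian"
    n_trajectories: int
    seed: int
    sim: HopSimConfig | None = None  # hop scenarios
    brownian_d: float | None = None  # um^2/s, brownian scenarios
    frame_time: float = 1e-4
    n_frames: int = 1000
    loc_error_sd: float = 0.0
    rd_lag: int = 100
    n_null: int = 5000
    classify: bool = True
    degenerate_policy: str = "suppressed"
    fit_ensemble: bool = True
    run_tild: bool = False
    tild: TildParams = field(default_factory=TildParams)
    tild_match_tol_s: float = 2e-3
    dwell_method: str = "window"  # corrects finite-recording length bias
    max_lag_frames: int = 250
    out_dir: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    scenario: str
    config_hash: str
    seed: int
    n_trajectories: int
    summary: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_study(config: StudyConfig) -> StudyReport:
    """Run a study and return its report.

    Hop scenarios additionally measure ground-truth dwell lifetimes and,
    when TILD is enabled, per-hop detectability/accuracy against the ground
    truth under the +/-`tild_match_tol_s` one-to-one matching rule.
    """
    summary: dict = {}
    log.info("study %s: %d trajectories, seed %d", config.scenario,
             config.n_trajectories, config.seed)

    if config.scenario == "hop":
        if config.sim is None:
            raise ValueError("hop scenario requires a simulator config")
        sims = simulate_hop_ensemble(config.sim, config.n_trajectories)
        clean = [s.trajectory for s in sims]
        frame_time = config.sim.frame_time
        sigma = config.sim.loc_error_sd
    elif config.scenario == "brownian":
        if config.brownian_d is None:
            raise ValueError("brownian scenario requires brownian_d")
        sims = None
        clean = [
            simulate_brownian_trajectory(
                config.brownian_d, config.n_frames, config.frame_time,
                seed=config.seed, traj_id=i,
            )
            for i in range(config.n_trajectories)
        ]
        frame_time = config.frame_time
        sigma = config.loc_error_sd
    else:
        raise ValueError(f"unknown scenario {config.scenario!r}")

    if sigma > 0:
        observed = [
            add_localization_noise(tr, sigma, seed=config.seed + 1, traj_id=i)
            for i, tr in enumerate(clean)
        ]
    else:
        observed = clean

    n_frames = clean[0].n_frames
    window_s = (n_frames - 1) * frame_time
    dwell_kwargs = (
        {"method": "window", "window_s": window_s}
        if config.dwell_method == "window"
        else {"method": config.dwell_method}
    )

    if sims is not None:
        truth_res = np.concatenate(
            [true_residencies(s, config.tild.min_residency_s) for s in sims]
        )
        if len(truth_res) >= 20:
            fit = fit_dwell_lifetime(
                truth_res, config.tild.min_residency_s, **dwell_kwargs
            )
            summary["truth_dwell_tau_s"] = fit.tau
            summary["truth_dwell_se_s"] = fit.se
            summary["truth_dwell_n"] = fit.n_durations

    modes = None
    if config.classify:
        log.info("computing RD null thresholds (n_sim=%d)", config.n_null)
        thr = rd_null_thresholds(
            N=observed[0].n_frames, n=config.rd_lag, frame_time=frame_time,
            n_sim=config.n_null, seed=config.seed + 2,
        )
        rds = np.array([rd_statistic(tr, config.rd_lag) for tr in observed])
        modes = np.where(
            np.isnan(rds), config.degenerate_policy,
            np.where(rds < thr.rd_min, "suppressed",
                     np.where(rds > thr.rd_max, "directed", "brownian")),
        )
        summary["rd_min"] = thr.rd_min
        summary["rd_max"] = thr.rd_max
        summary["n_suppressed"] = int(np.sum(modes == "suppressed"))
        summary["n_brownian"] = int(np.sum(modes == "brownian"))
        summary["n_directed"] = int(np.sum(modes == "directed"))

    if config.fit_ensemble:
        curves = [compute_msd(tr, config.max_lag_frames) for tr in observed]
        ens = ensemble_msd(curves)
        st = estimate_short_term(ens)
        offset = 4.0 * sigma**2 if sigma > 0 else False
        hop_fit = fit_hop_diffusion(ens, subtract_offset=offset)
        summary["ensemble_d_2_4_um2s"] = st.d_2_4
        summary["ensemble_offset_nm2"] = st.offset
        summary["hop_fit_d_micro_um2s"] = hop_fit.d_micro
        summary["hop_fit_d_macro_um2s"] = hop_fit.d_macro
        summary["hop_fit_L_nm"] = hop_fit.L
        summary["hop_fit_converged"] = hop_fit.converged

    if config.run_tild:
        log.info("running TILD detection on %d trajectories", len(observed))
        tol_frames = int(round(config.tild_match_tol_s / frame_time))
        tild_params = dataclasses.replace(config.tild, loc_error_sd=sigma)
        results = [detect_tilds(tr, tild_params) for tr in observed]
        counts = np.array([len(r.hop_frames) for r in results], dtype=float)
        summary["tild_mean_per_trajectory"] = float(np.mean(counts))
        pooled = np.concatenate(
            [residency_durations(r, config.tild.min_residency_s) for r in results]
        )
        summary["tild_n_residencies"] = int(len(pooled))
        if len(pooled) >= 20:
            fit = fit_dwell_lifetime(
                pooled, config.tild.min_residency_s, **dwell_kwargs
            )
            summary["tild_dwell_tau_s"] = fit.tau
            summary["tild_dwell_se_s"] = fit.se
        if sims is not None:
            sel = (
                range(len(sims))
                if modes is None
                else [i for i in range(len(sims)) if modes[i] == "suppressed"]
            )
            hits_true = hits_det = n_true = n_det = 0
            for i in sel:
                ht, hd = hop_detection_scores(
                    results[i].hop_frames, sims[i].hop_frames, tol_frames
                )
                hits_true += ht
                hits_det += hd
                n_true += len(sims[i].hop_frames)
                n_det += len(results[i].hop_frames)
            summary["tild_detectability_pct"] = (
                100.0 * hits_true / n_true if n_true else float("nan")
            )
            summary["tild_accuracy_pct"] = (
                100.0 * hits_det / n_det if n_det else float("nan")
            )

    report = StudyReport(
        scenario=config.scenario,
        config_hash=config.config_hash(),
        seed=config.seed,
        n_trajectories=config.n_trajectories,
        summary=summary,
    )
    if config.out_dir:
        from .io import write_json_report, write_trajectories

        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_trajectories(observed, out / "trajectories.csv")
        write_json_report(report.to_dict(), out / "report.json")
    return report


def verify_report_hash(report: dict, config: StudyConfig) -> bool:
    """True when the report's embedded config hash matches ``config``."""
    return report.get("config_hash") == config.config_hash()
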
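"""Stimulation protocols: global (three states) and local (occipital) trials.

A protocol run selects, per frequency configuration, the three coupling
states from an unstimulated sweep, then executes stimulation trials.  Per
(configuration, state) one long unstimulated *carrier* simulation provides
the ongoing activity; each trial reads its onset state from the carrier and
branches at the onset into a stimulated segment (50-ms pulse plus 500-ms
analysis window, fresh noise), while ``n_baseline_iterations`` independent
noise realizations of the 1-s prestimulus segment provide the pooled
baseline for binarizing the perturbation response.

All randomness derives from a single master seed through a spawning tree,
so every trial is individually reproducible and two runs with the same
seed produce identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from critresp.analysis import (
    OnsetFeatures,
    classify_groups,
    compare_states,
    onset_features,
)
from critresp.connectome import Connectome, sample_natural_frequencies, select_local_targets
from critresp.criticality import CriticalityProfile, sweep_coupling
from critresp.model import ModelParams, StimulusSpec, integrate
from critresp.response import (
    NodeSyncSeries,
    baseline_stats,
    binarize_response,
    lzc_spatial,
    lzc_temporal,
    node_phase_sync,
    responsivity,
)

logger = logging.getLogger(__name__)

__all__ = ["ProtocolConfig", "StudyResult", "LocalResult", "run_global_protocol", "run_local_protocol"]

STATE_NAMES = ("C_b", "C_p", "C_a")
_STATE_KEY = {"C_b": "K_b", "C_p": "K_p", "C_a": "K_a"}

EFFECTIVE = "effective"
LESS_EFFECTIVE = "less_effective"
RANDOM = "random"


def _seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class ProtocolConfig:
    """Trial design and model parameters of a stimulation protocol.

    Defaults follow the full study design: 20 frequency configurations x 30
    stimulus timings = 600 trials per state, 10 baseline iterations per
    trial, pulse strength 10 (global) / 30 (local) for 50 ms, a 500-ms
    response window, and a coupling grid from 0 to 0.4.  ``scale``
    multiplies the number of frequency configurations for desk-scale runs
    (scale=0.1 keeps 2 configurations, i.e. 60 trials per state).
    """

    n_freq_configs: int = 20
    n_timings: int = 30
    n_baseline_iterations: int = 10
    states: tuple = STATE_NAMES
    stim_strength_global: float = 10.0
    stim_strength_local: float = 30.0
    stim_duration: float = 0.05
    window: float = 0.5
    alpha: float = 0.05
    k_min: float = 0.0
    k_max: float = 0.4
    dk: float = 0.002
    lam: float = 1.0
    noise_sd: float = 0.05
    conduction_speed: float = 7.0
    dt: float = 1e-3
    burn_in: float = 10.0
    record_len: float = 25.0
    mean_hz: float = 10.0
    sd_hz: float = 0.5
    local_center_label: str = "lh.cuneus"
    local_radius_mm: float = 50.0
    master_seed: int = 0
    scale: float = 1.0

    def validate(self) -> None:
        for name in ("n_freq_configs", "n_timings", "n_baseline_iterations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not set(self.states) <= set(STATE_NAMES):
            raise ValueError(f"states must be a subset of {STATE_NAMES}")
        if self.dk <= 0 or self.k_max <= self.k_min:
            raise ValueError("invalid coupling grid")
        if self.window <= 0 or self.stim_duration <= 0:
            raise ValueError("window and stim_duration must be positive")

    @property
    def k_grid(self) -> np.ndarray:
        n = int(round((self.k_max - self.k_min) / self.dk)) + 1
        return self.k_min + self.dk * np.arange(n)

    @property
    def n_configs_effective(self) -> int:
        return max(1, int(round(self.n_freq_configs * self.scale)))

    @property
    def n_trials_per_state(self) -> int:
        return self.n_configs_effective * self.n_timings

    def model_params(self, omega=None, coupling: float = 0.0, rng_seed: int = 0) -> ModelParams:
        return ModelParams(
            omega=omega,
            coupling=coupling,
            lam=self.lam,
            noise_sd=self.noise_sd,
            conduction_speed=self.conduction_speed,
            dt=self.dt,
            burn_in=self.burn_in,
            record_len=self.record_len,
            rng_seed=rng_seed,
        )

    def manifest(self, extra: dict | None = None) -> dict:
        from critresp import __version__

        cfg = asdict(self)
        cfg["states"] = list(cfg["states"])
        digest = hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()
        out = {"config": cfg, "config_hash": digest, "version": __version__}
        if extra:
            out.update(extra)
        return out


@dataclass
class StudyResult:
    """Outputs of a global-stimulation protocol."""

    profile: CriticalityProfile
    trials: pd.DataFrame
    node_trials: pd.DataFrame
    avg_pr: dict  # state -> (n_trials, n_window) per-trial node-mean PR series
    config: ProtocolConfig

    def export(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.profile.export(out / "sweep.csv", out / "states.json")
        self.trials.to_csv(out / "trials.csv", index=False)
        self.node_trials.to_csv(out / "node_trials.csv", index=False)
        np.savez(out / "avg_pr.npz", **{k: v for k, v in self.avg_pr.items()})
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.config.manifest(), fh, indent=2)


def _simulate_trial(conn, cfg: ProtocolConfig, params: ModelParams, carrier, onset_idx: int,
                    h_steps: int, stim_targets, stim_strength: float, trial_ss):
    dt = cfg.dt
    n_pre = int(round(1.0 / dt))
    n_window = int(round(cfg.window / dt))
    pre_idx = onset_idx - n_pre

    # The carrier is the ongoing activity: onset features are read from it,
    # and the stimulated segment branches at the onset itself, so the trial's
    # instantaneous state carries the carrier's full slow history.  Only the
    # baseline iterations re-run the prestimulus second with fresh noise.
    children = trial_ss.spawn(1 + cfg.n_baseline_iterations)
    seg_params = replace(
        params, burn_in=0.0, record_len=cfg.stim_duration + cfg.window,
        rng_seed=_seed(children[0]),
    )
    stim = StimulusSpec(
        strength=stim_strength, onset=0.0, duration=cfg.stim_duration, targets=stim_targets
    )
    seg = integrate(
        conn, seg_params, stim,
        init_history=carrier.states[onset_idx - h_steps : onset_idx + 1],
    )

    base_segments = []
    base_params = replace(seg_params, record_len=1.0)
    base_hist = carrier.states[pre_idx - h_steps : pre_idx + 1]
    for b in range(cfg.n_baseline_iterations):
        bseg = integrate(
            conn, replace(base_params, rng_seed=_seed(children[1 + b])), init_history=base_hist
        )
        base_segments.append(node_phase_sync(bseg, conn).values)

    base = baseline_stats(base_segments, alpha=cfg.alpha)
    sync = node_phase_sync(seg, conn)
    post = NodeSyncSeries(
        values=sync.values[:n_window],
        neighbor_counts=sync.neighbor_counts,
        dt=dt,
    )
    prm = binarize_response(post, base)
    r_j, r_mean = responsivity(prm)
    _, lzc_mean = lzc_spatial(prm)
    lzc_j = np.array([lzc_temporal(row) for row in prm.values])
    feat = onset_features(carrier, onset_idx * dt)
    avg_pr_series = prm.values.mean(axis=0)
    return feat, r_j, r_mean, lzc_j, lzc_mean, avg_pr_series


def _onset_bounds(cfg: ProtocolConfig, h_steps: int) -> tuple[float, float]:
    # >= 1 s of carrier for the prestimulus branch (plus the delay history),
    # and room for stimulus + response window before the record ends.
    t_min = 1.0 + (h_steps + 1) * cfg.dt
    t_max = cfg.record_len - (cfg.stim_duration + cfg.window + 0.05)
    if t_max <= t_min:
        raise ValueError("record_len too short for the stimulation window")
    return t_min, t_max


def _h_steps(conn: Connectome, cfg: ProtocolConfig) -> int:
    from critresp.connectome import delay_matrix

    tau = delay_matrix(conn, cfg.conduction_speed, cfg.dt)
    return max(int(tau[conn.adjacency > 0].max()), 1)


def run_global_protocol(
    conn: Connectome, cfg: ProtocolConfig, profile: CriticalityProfile | None = None
) -> StudyResult:
    """Run the global-stimulation protocol over the selected states.

    Per state and frequency configuration, ``n_timings`` pulses (strength
    ``stim_strength_global``, all nodes) are applied at uniformly random
    onsets of independent trials; each trial yields onset features, the
    binarized perturbation response, responsivity and both LZ complexities.
    """
    cfg.validate()
    master = np.random.SeedSequence(cfg.master_seed)
    sweep_ss, proto_ss = master.spawn(2)

    if profile is None:
        sweep_params = cfg.model_params(rng_seed=_seed(sweep_ss))
        profile = sweep_coupling(
            conn, sweep_params, cfg.k_grid, cfg.n_configs_effective, cfg.mean_hz, cfg.sd_hz
        )
    n_configs = profile.n_configs
    h_steps = _h_steps(conn, cfg)
    t_min, t_max = _onset_bounds(cfg, h_steps)

    trial_rows = []
    node_rows = []
    avg_pr: dict[str, list] = {s: [] for s in cfg.states}
    failures = []
    config_children = proto_ss.spawn(n_configs)
    trial_id = 0
    for c in range(n_configs):
        omega = sample_natural_frequencies(
            conn.n_nodes, cfg.mean_hz, cfg.sd_hz, rng_seed=profile.freq_seeds[c]
        )
        state_children = config_children[c].spawn(len(cfg.states))
        for s_i, state in enumerate(cfg.states):
            coupling = profile.selected[c][_STATE_KEY[state]]
            ss = state_children[s_i]
            carrier_ss, timing_ss, trials_ss = ss.spawn(3)
            params = cfg.model_params(omega=omega, coupling=coupling, rng_seed=_seed(carrier_ss))
            carrier = integrate(conn, params)
            onsets = np.random.default_rng(_seed(timing_ss)).uniform(
                t_min, t_max, cfg.n_timings
            )
            trial_children = trials_ss.spawn(cfg.n_timings)
            for t_i, onset in enumerate(onsets):
                onset_idx = int(round(onset / cfg.dt))
                try:
                    feat, r_j, r_mean, lzc_j, lzc_mean, pr_series = _simulate_trial(
                        conn, cfg, params, carrier, onset_idx, h_steps,
                        None, cfg.stim_strength_global, trial_children[t_i],
                    )
                except Exception as err:  # pragma: no cover - defensive
                    logger.error("trial %d (%s, config %d) failed: %s", trial_id, state, c, err)
                    failures.append({"trial": trial_id, "state": state, "error": str(err)})
                    trial_id += 1
                    continue
                trial_rows.append(
                    {
                        "trial": trial_id, "state": state, "config_id": c,
                        "onset_time": onset_idx * cfg.dt, "r_s": feat.r_s,
                        "mean_amp": float(feat.amp.mean()),
                        "R_mean": r_mean, "LZc_mean": lzc_mean,
                    }
                )
                for j in range(conn.n_nodes):
                    node_rows.append(
                        {
                            "trial": trial_id, "state": state, "config_id": c, "node": j,
                            "amp": feat.amp[j], "phase": feat.phase[j],
                            "R": r_j[j], "LZc": lzc_j[j],
                        }
                    )
                avg_pr[state].append(pr_series)
                trial_id += 1

    trials = pd.DataFrame(trial_rows)
    node_trials = pd.DataFrame(node_rows)
    if failures:
        logger.warning("%d trial(s) failed and were skipped", len(failures))

    # Per-state HS/LS / HA/LA / phase-bin / regime classification.
    node_trials["sync_class"] = ""
    node_trials["amp_class"] = ""
    node_trials["phase_bin"] = 0
    node_trials["regime"] = ""
    for state in cfg.states:
        t_mask = trials["state"] == state
        n_mask = node_trials["state"] == state
        if not t_mask.any():
            continue
        st_trials = trials.loc[t_mask]
        feats = OnsetFeatures(
            r_s=st_trials["r_s"].to_numpy(),
            amp=node_trials.loc[n_mask, "amp"].to_numpy().reshape(t_mask.sum(), conn.n_nodes),
            phase=node_trials.loc[n_mask, "phase"].to_numpy().reshape(t_mask.sum(), conn.n_nodes),
        )
        labels = classify_groups(feats)
        node_trials.loc[n_mask, "sync_class"] = np.repeat(
            np.where(labels.sync_high, "HS", "LS"), conn.n_nodes
        )
        node_trials.loc[n_mask, "amp_class"] = np.where(labels.amp_high.ravel(), "HA", "LA")
        node_trials.loc[n_mask, "phase_bin"] = labels.phase_bin.ravel()
        node_trials.loc[n_mask, "regime"] = labels.regime.ravel()
        trials.loc[t_mask, "sync_class"] = np.where(labels.sync_high, "HS", "LS")

    return StudyResult(
        profile=profile,
        trials=trials,
        node_trials=node_trials,
        avg_pr={s: np.asarray(v) for s, v in avg_pr.items()},
        config=cfg,
    )


@dataclass
class LocalResult:
    """Outputs of the local (occipital) stimulation protocol."""

    profile: CriticalityProfile
    node_trials: pd.DataFrame  # target-node trials with condition labels
    targets: np.ndarray
    counts: dict
    stats_r: object | None
    stats_lzc: object | None
    medians: pd.DataFrame
    config: ProtocolConfig

    def export(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.node_trials.to_csv(out / "local_node_trials.csv", index=False)
        self.medians.to_csv(out / "local_medians.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.config.manifest({"targets": self.targets.tolist()}), fh, indent=2)


def run_local_protocol(
    conn: Connectome, cfg: ProtocolConfig, profile: CriticalityProfile | None = None
) -> LocalResult:
    """Occipital stimulation at the critical state C_p.

    Pulses of strength ``stim_strength_local`` hit the nodes within
    ``local_radius_mm`` of the occipital seed region.  Target node-trials
    are classified post hoc: effective (LS & LA & phases 240-60), less
    effective (HS & HA & phases 60-240), and a random draw of node-trials
    sized to the mean of the two condition counts.  Responsivity and
    temporal LZc are compared across conditions with Kruskal-Wallis and
    Tukey-Kramer tests.
    """
    cfg.validate()
    targets = select_local_targets(conn, cfg.local_center_label, cfg.local_radius_mm)
    master = np.random.SeedSequence(cfg.master_seed)
    sweep_ss, proto_ss = master.spawn(2)

    if profile is None:
        sweep_params = cfg.model_params(rng_seed=_seed(sweep_ss))
        profile = sweep_coupling(
            conn, sweep_params, cfg.k_grid, cfg.n_configs_effective, cfg.mean_hz, cfg.sd_hz
        )
    n_configs = profile.n_configs
    h_steps = _h_steps(conn, cfg)
    t_min, t_max = _onset_bounds(cfg, h_steps)

    rows = []
    config_children = proto_ss.spawn(n_configs)
    trial_id = 0
    r_s_all = []
    for c in range(n_configs):
        omega = sample_natural_frequencies(
            conn.n_nodes, cfg.mean_hz, cfg.sd_hz, rng_seed=profile.freq_seeds[c]
        )
        coupling = profile.selected[c]["K_p"]
        carrier_ss, timing_ss, trials_ss = config_children[c].spawn(3)
        params = cfg.model_params(omega=omega, coupling=coupling, rng_seed=_seed(carrier_ss))
        carrier = integrate(conn, params)
        onsets = np.random.default_rng(_seed(timing_ss)).uniform(t_min, t_max, cfg.n_timings)
        trial_children = trials_ss.spawn(cfg.n_timings)
        for t_i, onset in enumerate(onsets):
            onset_idx = int(round(onset / cfg.dt))
            feat, r_j, _, lzc_j, _, _ = _simulate_trial(
                conn, cfg, params, carrier, onset_idx, h_steps,
                targets, cfg.stim_strength_local, trial_children[t_i],
            )
            r_s_all.append(feat.r_s)
            for j in targets:
                rows.append(
                    {
                        "trial": trial_id, "config_id": c, "node": int(j),
                        "r_s": feat.r_s, "amp": feat.amp[j], "phase": feat.phase[j],
                        "R": r_j[j], "LZc": lzc_j[j],
                    }
                )
            trial_id += 1

    node_trials = pd.DataFrame(rows)
    mean_rs = float(np.mean(r_s_all))
    mean_amp = float(node_trials["amp"].mean())
    from critresp.analysis import REGIME_HIGH, REGIME_LOW, regime_split

    node_trials["sync_class"] = np.where(node_trials["r_s"] > mean_rs, "HS", "LS")
    node_trials["amp_class"] = np.where(node_trials["amp"] > mean_amp, "HA", "LA")
    node_trials["regime"] = regime_split(node_trials["phase"].to_numpy())

    eff_mask = (
        (node_trials["sync_class"] == "LS")
        & (node_trials["amp_class"] == "LA")
        & (node_trials["regime"] == REGIME_HIGH)
    )
    less_mask = (
        (node_trials["sync_class"] == "HS")
        & (node_trials["amp_class"] == "HA")
        & (node_trials["regime"] == REGIME_LOW)
    )
    node_trials["condition"] = "other"
    node_trials.loc[eff_mask, "condition"] = EFFECTIVE
    node_trials.loc[less_mask, "condition"] = LESS_EFFECTIVE

    n_eff, n_less = int(eff_mask.sum()), int(less_mask.sum())
    n_random = int(round(0.5 * (n_eff + n_less)))
    rng = np.random.default_rng(_seed(master.spawn(1)[0]))
    random_idx = rng.choice(node_trials.index.to_numpy(), size=min(n_random, len(node_trials)),
                            replace=False)
    node_trials["random_draw"] = False
    node_trials.loc[random_idx, "random_draw"] = True

    counts = {EFFECTIVE: n_eff, LESS_EFFECTIVE: n_less, RANDOM: int(len(random_idx))}
    stats_r = stats_lzc = None
    if n_eff >= 2 and n_less >= 2 and len(random_idx) >= 2:
        groups_r = {
            EFFECTIVE: node_trials.loc[eff_mask, "R"],
            RANDOM: node_trials.loc[random_idx, "R"],
            LESS_EFFECTIVE: node_trials.loc[less_mask, "R"],
        }
        groups_lzc = {
            EFFECTIVE: node_trials.loc[eff_mask, "LZc"],
            RANDOM: node_trials.loc[random_idx, "LZc"],
            LESS_EFFECTIVE: node_trials.loc[less_mask, "LZc"],
        }
        stats_r = compare_states(groups_r)
        stats_lzc = compare_states(groups_lzc)
    else:
        logger.warning("a stimulation condition has too few node-trials; comparison skipped")

    medians = pd.DataFrame(
        [
            {
                "condition": cond,
                "n": counts[cond],
                "median_R": float(np.median(vals["R"])) if len(vals) else np.nan,
                "median_LZc": float(np.median(vals["LZc"])) if len(vals) else np.nan,
            }
            for cond, vals in (
                (EFFECTIVE, node_trials.loc[eff_mask]),
                (RANDOM, node_trials.loc[random_idx]),
                (LESS_EFFECTIVE, node_trials.loc[less_mask]),
            )
        ]
    )
    return LocalResult(
        profile=profile, node_trials=node_trials, targets=targets, counts=counts,
        stats_r=stats_r, stats_lzc=stats_lzc, medians=medians, config=cfg,
    )
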
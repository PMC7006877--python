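"""Order parameter, pair correlation function, coupling sweep, state selection.

The instantaneous global synchronization is the Kuramoto order parameter
r(t) = |N^-1 sum_k exp(i theta_k(t))|: 1 when all phases coincide and of
order 1/sqrt(N) for incoherent phases.  The pair correlation function
(PCF) is the N-scaled variance of r(t) over time, the susceptibility
analogue that peaks at the critical coupling.  A coupling sweep yields, per
frequency configuration, three representative states: C_p at the coupling
maximizing the PCF, and C_b / C_a at the couplings whose time-averaged r is
nearest the 10th / 90th percentile of the averaged order parameters over
the sweep.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from critresp.connectome import Connectome, sample_natural_frequencies
from critresp.model import ModelParams, Trajectory, integrate

logger = logging.getLogger(__name__)

__all__ = [
    "OrderParameterSeries",
    "CriticalityProfile",
    "global_order_parameter",
    "pcf",
    "sweep_coupling",
    "select_states",
]


@dataclass
class OrderParameterSeries:
    """r(t) in [0, 1] per recorded step."""

    values: np.ndarray
    dt: float = 1e-3

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.values.shape[0]) * self.dt


def global_order_parameter(phases) -> OrderParameterSeries:
    """Kuramoto order parameter of a (n_steps, n_nodes) phase array or Trajectory."""
    if isinstance(phases, Trajectory):
        u = phases.phase_factors()
        dt = phases.dt
    else:
        phases = np.asarray(phases, dtype=float)
        if phases.ndim != 2:
            raise ValueError("phases must be a (n_steps, n_nodes) array")
        u = np.exp(1j * phases)
        dt = 1e-3
    if u.shape[1] < 2:
        raise ValueError("order parameter requires at least 2 nodes")
    r = np.abs(u.mean(axis=1))
    return OrderParameterSeries(values=r, dt=dt)


def pcf(series: OrderParameterSeries | np.ndarray, n_nodes: int) -> float:
    """Pair correlation function: N * Var[r(t)] over time."""
    values = series.values if isinstance(series, OrderParameterSeries) else np.asarray(series)
    if values.shape[0] < 2:
        raise ValueError("PCF requires at least 2 samples")
    return float(n_nodes * np.var(values))


@dataclass
class CriticalityProfile:
    """Per-configuration mean synchronization and PCF over a coupling grid."""

    k_grid: np.ndarray  # (n_k,), strictly increasing
    mean_r: np.ndarray  # (n_configs, n_k)
    pcf: np.ndarray  # (n_configs, n_k)
    freq_seeds: list[int] = field(default_factory=list)
    selected: list[dict] = field(default_factory=list)  # per config: K_b, K_p, K_a (+ indices)

    @property
    def n_configs(self) -> int:
        return self.mean_r.shape[0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in range(self.n_configs):
            for i, k in enumerate(self.k_grid):
                rows.append(
                    {"config_id": c, "K": k, "mean_r": self.mean_r[c, i], "pcf": self.pcf[c, i]}
                )
        return pd.DataFrame(rows)

    def export(self, csv_path, json_path=None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(
                    {"freq_seeds": [int(s) for s in self.freq_seeds],
                     "selected": [
                         {k: (float(v) if isinstance(v, (float, np.floating)) else int(v))
                          for k, v in sel.items()}
                         for sel in self.selected
                     ]},
                    fh,
                    indent=2,
                )


def select_states(profile: CriticalityProfile, config: int = 0) -> dict:
    """Pick {K_b, K_p, K_a} for one frequency configuration.

    K_p maximizes the PCF (lowest K on ties); K_b and K_a are the couplings
    whose mean r is nearest the 10th and 90th percentiles of the mean-r
    values over the whole grid (lowest K on ties).
    """
    mean_r = profile.mean_r[config]
    pcf_row = profile.pcf[config]
    k = np.asarray(profile.k_grid)

    max_pcf = pcf_row.max()
    peaks = np.flatnonzero(pcf_row == max_pcf)
    if peaks.size > 1:
        logger.info("config %d: %d PCF maxima; choosing lowest K", config, peaks.size)
    i_p = int(peaks[0])

    def nearest(target: float) -> int:
        return int(np.argmin(np.abs(mean_r - target)))  # first (= lowest K) on ties

    i_b = nearest(np.percentile(mean_r, 10))
    i_a = nearest(np.percentile(mean_r, 90))
    return {
        "K_b": float(k[i_b]), "K_p": float(k[i_p]), "K_a": float(k[i_a]),
        "i_b": i_b, "i_p": i_p, "i_a": i_a,
    }


def sweep_coupling(
    conn: Connectome,
    params: ModelParams,
    k_grid: np.ndarray,
    n_configs: int = 20,
    mean_hz: float = 10.0,
    sd_hz: float = 0.5,
) -> CriticalityProfile:
    """Unstimulated runs over a coupling grid for several frequency configurations.

    ``params.omega`` and ``params.coupling`` are ignored; per configuration a
    fresh Gaussian frequency vector is drawn and one run per K yields the
    time-averaged order parameter and the PCF.  ``params.rng_seed`` is the
    master seed for both frequency and noise streams.
    """
    k_grid = np.asarray(k_grid, dtype=float)
    if k_grid.size == 0:
        raise ValueError("k_grid must be nonempty")
    if np.any(np.diff(k_grid) <= 0):
        raise ValueError("k_grid must be strictly increasing")

    master = np.random.SeedSequence(params.rng_seed)
    freq_ss, noise_ss = master.spawn(2)
    freq_children = freq_ss.spawn(n_configs)
    noise_children = noise_ss.spawn(n_configs)

    mean_r = np.empty((n_configs, k_grid.size))
    pcf_vals = np.empty((n_configs, k_grid.size))
    freq_seeds = []
    for c in range(n_configs):
        f_seed = int(freq_children[c].generate_state(1)[0] % 2**31)
        freq_seeds.append(f_seed)
        omega = sample_natural_frequencies(conn.n_nodes, mean_hz, sd_hz, rng_seed=f_seed)
        k_seeds = noise_children[c].spawn(k_grid.size)
        for i, k in enumerate(k_grid):
            run_params = replace(
                params,
                omega=omega,
                coupling=float(k),
                rng_seed=int(k_seeds[i].generate_state(1)[0] % 2**31),
            )
            try:
                traj = integrate(conn, run_params)
            except RuntimeError as err:
                raise RuntimeError(f"sweep failed at K={k} (config {c}): {err}") from err
            r = global_order_parameter(traj)
            mean_r[c, i] = r.values.mean()
            pcf_vals[c, i] = pcf(r, conn.n_nodes)

    profile = CriticalityProfile(
        k_grid=k_grid, mean_r=mean_r, pcf=pcf_vals, freq_seeds=freq_seeds
    )
    profile.selected = [select_states(profile, c) for c in range(n_configs)]
    return profile
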
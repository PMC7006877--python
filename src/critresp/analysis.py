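"""Onset features, synchronization/amplitude/phase grouping, and statistics.

Trials and nodes are characterized by the ongoing oscillation at stimulus
onset: the global order parameter r_s, the node amplitude |Z_sj|, and the
node phase theta_sj in degrees.  Node-trials are classified high/low
synchronization (HS/LS) and high/low amplitude (HA/LA) against the
respective averages, binned into 30 half-open 12-degree phase bins, and
split into the two phase regimes [60, 240) and [240, 60).  Statistical
comparisons mirror standard nonparametric practice: Spearman correlation,
Kruskal-Wallis with Tukey-Kramer pairwise comparisons on rank-transformed
data, Wilcoxon rank-sum, and per-timepoint sign tests for persistence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from critresp.criticality import global_order_parameter
from critresp.model import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "TrialOnset",
    "OnsetFeatures",
    "GroupLabels",
    "onset_features",
    "classify_groups",
    "phase_bin",
    "regime_split",
    "spearman",
    "compare_states",
    "wilcoxon_ranksum",
    "pr_persistence",
    "PersistenceResult",
]

REGIME_LOW = "60-240"  # phases [60, 240): the low-responsiveness window in HS&HA
REGIME_HIGH = "240-60"  # phases [240, 360) and [0, 60)


@dataclass
class TrialOnset:
    """Instantaneous oscillation properties of one trial at stimulus onset."""

    r_s: float
    amp: np.ndarray  # |Z_sj| per node
    phase: np.ndarray  # theta_sj per node, degrees in [0, 360)


@dataclass
class OnsetFeatures:
    """Onset properties stacked over trials."""

    r_s: np.ndarray  # (n_trials,)
    amp: np.ndarray  # (n_trials, n_nodes)
    phase: np.ndarray  # (n_trials, n_nodes), degrees in [0, 360)

    @classmethod
    def from_trials(cls, trials: list[TrialOnset]) -> "OnsetFeatures":
        return cls(
            r_s=np.array([t.r_s for t in trials]),
            amp=np.vstack([t.amp for t in trials]),
            phase=np.vstack([t.phase for t in trials]),
        )


def onset_features(trajectory: Trajectory, onset: float) -> TrialOnset:
    """Read r_s, |Z_sj| and theta_sj (degrees) at the onset step.

    Off-grid onsets are snapped to the nearest step (logged).
    """
    idx = int(round(onset / trajectory.dt))
    if abs(idx * trajectory.dt - onset) > 1e-9:
        logger.info("onset %.6f s snapped to step %d (%.6f s)", onset, idx, idx * trajectory.dt)
    if not 0 <= idx < trajectory.n_steps:
        raise ValueError(f"onset {onset} s outside the recorded window")
    z = trajectory.states[idx]
    r_s = float(np.abs((z / np.abs(z)).mean()))
    amp = np.abs(z)
    phase = np.degrees(np.angle(z)) % 360.0
    return TrialOnset(r_s=r_s, amp=amp, phase=phase)


@dataclass
class GroupLabels:
    """Per trial x node classification tuple."""

    sync_high: np.ndarray  # (n_trials,) bool: HS
    amp_high: np.ndarray  # (n_trials, n_nodes) bool: HA
    phase_bin: np.ndarray  # (n_trials, n_nodes) int in 1..30
    regime: np.ndarray  # (n_trials, n_nodes) str

    def to_frame(self) -> pd.DataFrame:
        n_trials, n_nodes = self.amp_high.shape
        t_idx, n_idx = np.meshgrid(np.arange(n_trials), np.arange(n_nodes), indexing="ij")
        return pd.DataFrame(
            {
                "trial": t_idx.ravel(),
                "node": n_idx.ravel(),
                "sync_class": np.where(self.sync_high, "HS", "LS")[t_idx.ravel()],
                "amp_class": np.where(self.amp_high.ravel(), "HA", "LA"),
                "phase_bin": self.phase_bin.ravel(),
                "regime": self.regime.ravel(),
            }
        )


def phase_bin(theta) -> np.ndarray | int:
    """Half-open 12-degree bins: bin = floor(theta / 12) + 1, in 1..30.

    Out-of-range phases are normalized modulo 360.
    """
    theta = np.asarray(theta, dtype=float) % 360.0
    bins = (np.floor(theta / 12.0) + 1).astype(int)
    return bins if bins.ndim else int(bins)


def regime_split(theta) -> np.ndarray | str:
    """"60-240" iff 60 <= theta < 240 (mod 360), else "240-60"."""
    theta = np.asarray(theta, dtype=float) % 360.0
    out = np.where((theta >= 60.0) & (theta < 240.0), REGIME_LOW, REGIME_HIGH)
    return out if out.ndim else str(out)


def classify_groups(features: OnsetFeatures) -> GroupLabels:
    """HS iff r_s above the trial average; HA iff |Z_sj| above the pooled
    trial x node average; equality goes to the low class."""
    if features.r_s.shape[0] < 2:
        raise ValueError("classification requires at least 2 trials")
    sync_high = features.r_s > features.r_s.mean()
    amp_high = features.amp > features.amp.mean()
    bins = phase_bin(features.phase)
    regime = regime_split(features.phase)
    return GroupLabels(sync_high=sync_high, amp_high=amp_high, phase_bin=bins, regime=regime)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties and two-sided p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("spearman requires two equal-length samples of size >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("spearman is undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class StateComparison:
    """Kruskal-Wallis omnibus plus Tukey-Kramer pairwise flags on ranks."""

    h: float
    p: float
    pairwise: pd.DataFrame  # group1, group2, p_adj, sig_005, sig_0001


def compare_states(groups: dict) -> StateComparison:
    """Kruskal-Wallis across >= 2 samples, then Tukey-Kramer multiple
    comparisons on the rank-transformed pooled data."""
    names = list(groups)
    samples = [np.asarray(groups[n], float) for n in names]
    if len(samples) < 2:
        raise ValueError("compare_states requires at least 2 groups")
    for name, s in zip(names, samples):
        if s.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    h, p = stats.kruskal(*samples)

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    pooled = np.concatenate(samples)
    labels = np.concatenate([[n] * s.size for n, s in zip(names, samples)])
    ranks = stats.rankdata(pooled)
    tk = pairwise_tukeyhsd(ranks, labels)
    frame = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    frame = frame.rename(columns={"p-adj": "p_adj"})
    frame["p_adj"] = frame["p_adj"].astype(float)
    frame["sig_005"] = frame["p_adj"] < 0.005
    frame["sig_0001"] = frame["p_adj"] < 0.001
    return StateComparison(h=float(h), p=float(p), pairwise=frame)


def wilcoxon_ranksum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test; returns (U, p)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("wilcoxon_ranksum requires nonempty samples")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


@dataclass
class PersistenceResult:
    time: float  # earliest time (s, stimulus-aligned) of sustained significance
    direction: str  # "A>B" or "B>A"


def _sustained_onset(a: np.ndarray, b: np.ndarray, alpha: float) -> int | None:
    """First timepoint from which the paired sign test for a > b stays
    significant for all later points."""
    n_time = a.shape[1]
    sig = np.zeros(n_time, dtype=bool)
    for t in range(n_time):
        d = a[:, t] - b[:, t]
        n_pos = int((d > 0).sum())
        n_nonzero = int((d != 0).sum())
        if n_nonzero == 0:
            continue
        sig[t] = stats.binomtest(n_pos, n_nonzero, 0.5, alternative="greater").pvalue < alpha
    if not sig.any():
        return None
    not_sig = np.flatnonzero(~sig)
    first = 0 if not_sig.size == 0 else int(not_sig[-1]) + 1
    return first if first < n_time else None


def pr_persistence(a, b, dt: float = 1e-3, alpha: float = 0.05) -> PersistenceResult | None:
    """Earliest time after which one state's response exceeds the other's
    with a sustained per-timepoint sign test across trials.

    ``a`` and ``b`` are (n_trials, n_time) per-trial mean PR series aligned
    at stimulus onset with equal trial counts.  Significance must hold at
    every later timepoint of the window.  Returns None when no such time
    exists.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("a and b must be aligned (n_trials, n_time) arrays")
    onset_ab = _sustained_onset(a, b, alpha)
    if onset_ab is not None:
        return PersistenceResult(time=onset_ab * dt, direction="A>B")
    onset_ba = _sustained_onset(b, a, alpha)
    if onset_ba is not None:
        return PersistenceResult(time=onset_ba * dt, direction="B>A")
    return None
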
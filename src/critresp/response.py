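"""Perturbation responses: node synchronization, binarization, R and LZc.

A node's instantaneous phase synchronization |S_j(t)| is the modulus of the
average pairwise phase factor over its N_j neighbors.  Post-stimulus values
are z-scored against a pooled prestimulus baseline and binarized at the
one-tailed (1 - alpha) empirical quantile, giving the binary perturbation
response PR_j(t).  Responsivity R_j averages PR_j over the response window;
perturbational complexity applies the Lempel-Ziv 1976 phrase-counting
parser either along time per node (temporal LZc) or across nodes per time
point (spatial LZc), normalized by n / log2(n).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from critresp.connectome import Connectome
from critresp.model import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "NodeSyncSeries",
    "BaselineStats",
    "PRMatrix",
    "node_phase_sync",
    "baseline_stats",
    "binarize_response",
    "responsivity",
    "lz76",
    "lzc_temporal",
    "lzc_spatial",
    "amplitude_response",
]


@dataclass
class NodeSyncSeries:
    """|S_j(t)| per node per step, with each node's neighbor count N_j.

    Isolated nodes carry NaN values and are excluded downstream.
    """

    values: np.ndarray  # (n_steps, n_nodes)
    neighbor_counts: np.ndarray  # (n_nodes,)
    dt: float = 1e-3


def node_phase_sync(trajectory: Trajectory, conn: Connectome) -> NodeSyncSeries:
    """|S_j(t)| = |N_j^-1 sum_k A_jk e^{i(theta_j - theta_k)(t)}|.

    The modulus does not depend on theta_j, so this reduces to the modulus
    of the mean neighbor phasor.
    """
    u = trajectory.phase_factors()
    a = conn.adjacency.astype(float)
    counts = conn.adjacency.sum(axis=1)
    vals = np.abs(u @ a)  # A symmetric: column j sums over neighbors of j
    isolated = counts == 0
    if isolated.any():
        warnings.warn(
            f"{int(isolated.sum())} isolated node(s) excluded from synchronization",
            stacklevel=2,
        )
        vals[:, isolated] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = vals / np.where(isolated, np.nan, counts)[None, :]
    return NodeSyncSeries(values=vals, neighbor_counts=counts, dt=trajectory.dt)


@dataclass
class BaselineStats:
    """Per-node baseline mean/sd and one-tailed z-score threshold."""

    mean: np.ndarray
    sd: np.ndarray
    threshold: np.ndarray  # per-node threshold on z-scored values
    alpha: float
    n_samples: int
    degenerate: np.ndarray  # nodes with zero baseline variance; PR forced to 0


def _as_value_array(segment) -> np.ndarray:
    return segment.values if isinstance(segment, NodeSyncSeries) else np.asarray(segment, float)


def baseline_stats(segments, alpha: float = 0.05, method: str = "empirical") -> BaselineStats:
    """Pool prestimulus segments and derive per-node significance thresholds.

    ``segments`` is a sequence of (n_steps, n_nodes) arrays (or
    NodeSyncSeries), e.g. 10 independent realizations of the 1-s prestimulus
    window.  Thresholds are the empirical (1 - alpha) quantile of the
    z-scored pooled samples per node (``method="empirical"``), or the
    Gaussian one-tailed quantile (``method="gaussian"``).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    arrays = [_as_value_array(s) for s in segments]
    if not arrays:
        raise ValueError("at least one baseline segment is required")
    pooled = np.vstack(arrays)
    n_samples = pooled.shape[0]
    if n_samples < 100:
        raise ValueError(f"pooled baseline has {n_samples} samples; at least 100 required")
    mean = np.nanmean(pooled, axis=0)
    sd = np.nanstd(pooled, axis=0)
    # Constant columns can carry O(eps) round-off variance; use a relative test.
    degenerate = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
    if degenerate.any():
        logger.warning("%d node(s) have zero baseline variance; PR forced to 0",
                       int(degenerate.sum()))
    safe_sd = np.where(degenerate, 1.0, sd)
    if method == "empirical":
        z = (pooled - mean) / safe_sd
        threshold = np.nanquantile(z, 1.0 - alpha, axis=0)
    elif method == "gaussian":
        from scipy.stats import norm

        threshold = np.full(mean.shape, norm.ppf(1.0 - alpha))
    else:
        raise ValueError(f"unknown method {method!r}")
    threshold = np.where(degenerate, np.inf, threshold)
    return BaselineStats(
        mean=mean, sd=safe_sd, threshold=threshold, alpha=alpha,
        n_samples=n_samples, degenerate=degenerate,
    )


@dataclass
class PRMatrix:
    """Binary perturbation responses, nodes x response-window steps.

    The time axis is stimulus-aligned: column 0 is the onset step.
    """

    values: np.ndarray  # (n_nodes, n_window) uint8
    dt: float = 1e-3

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.values.shape[1]) * self.dt


def binarize_response(post_sync, baseline: BaselineStats, window: float | None = None) -> PRMatrix:
    """PR_j(t) = 1 iff the z-scored post-stimulus value exceeds the baseline
    threshold; degenerate nodes are all-zero.

    ``post_sync`` is an (n_steps, n_nodes) series starting at stimulus onset;
    ``window`` (seconds) truncates it (default: the full series; the standard
    response window is 0.5 s).
    """
    dt = post_sync.dt if isinstance(post_sync, NodeSyncSeries) else 1e-3
    vals = _as_value_array(post_sync)
    n_steps = vals.shape[0]
    if window is not None:
        n_window = int(round(window / dt))
        if n_window > n_steps:
            raise ValueError(
                f"window of {n_window} steps exceeds available record ({n_steps} steps)"
            )
        vals = vals[:n_window]
    z = (vals - baseline.mean[None, :]) / baseline.sd[None, :]
    pr = z > baseline.threshold[None, :]
    pr[:, baseline.degenerate] = False
    pr[np.isnan(vals)] = False
    return PRMatrix(values=pr.T.astype(np.uint8), dt=dt)


def responsivity(pr: PRMatrix) -> tuple[np.ndarray, float]:
    """R_j = mean of PR_j over the window; returns (R_j, <R>)."""
    if pr.values.shape[1] == 0:
        raise ValueError("empty response window")
    r_j = pr.values.mean(axis=1)
    return r_j, float(r_j.mean())


@njit(cache=False)
def _lz76_count(s):  # pragma: no cover - exercised via lz76()
    n = s.shape[0]
    if n == 1:
        return 1
    i = 0
    c = 1
    l = 1
    k = 1
    k_max = 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            if k > k_max:
                k_max = k
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i = 0
                k = 1
                k_max = 1
            else:
                k = 1
    return c


def _to_bits(sequence) -> np.ndarray:
    if isinstance(sequence, str):
        arr = np.frombuffer(sequence.encode(), dtype=np.uint8) - ord("0")
    else:
        arr = np.ascontiguousarray(sequence, dtype=np.uint8)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("sequence must be a nonempty 1-D binary sequence")
    if np.any(arr > 1):
        bad = int(np.argmax(arr > 1))
        raise ValueError(f"non-binary symbol at position {bad}")
    return arr


def lz76(sequence) -> int:
    """Number of phrases in the Lempel-Ziv 1976 exhaustive-history parsing.

    Accepts a binary string ("0101...") or an array of 0/1.
    """
    return int(_lz76_count(_to_bits(sequence)))


def lzc_temporal(pr_row) -> float:
    """Temporal perturbational complexity LZc_j = c_j / (t / log2 t)."""
    bits = _to_bits(pr_row)
    t = bits.size
    if t < 2:
        raise ValueError("temporal LZc requires length >= 2")
    return float(_lz76_count(bits) * np.log2(t) / t)


def lzc_spatial(pr: PRMatrix) -> tuple[np.ndarray, float]:
    """Spatial complexity LZc(t) = c(t) / (N / log2 N) and its window mean.

    At each time step the N-bit spatial pattern (fixed connectome node
    order) is parsed; the node order is part of the measure's definition
    and is kept canonical across runs.
    """
    n_nodes, n_window = pr.values.shape
    if n_nodes < 2:
        raise ValueError("spatial LZc requires at least 2 nodes")
    patterns = np.ascontiguousarray(pr.values.T)  # (n_window, n_nodes), rows contiguous
    norm = np.log2(n_nodes) / n_nodes
    series = np.empty(n_window)
    for t in range(n_window):
        series[t] = _lz76_count(patterns[t]) * norm
    return series, float(series.mean())


def amplitude_response(
    post_amplitudes, baseline: BaselineStats, window: float | None = None
) -> PRMatrix:
    """Amplitude-based perturbation response: the |z_j(t)| analogue of the
    synchronization pipeline, with an identical contract and alignment."""
    return binarize_response(post_amplitudes, baseline, window)
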
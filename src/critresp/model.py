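"""Stochastic delay-coupled Stuart-Landau network with pulsatile stimulation.

The state of node j is a complex variable z_j obeying

    dz_j = [(lambda + i*omega_j - |z_j|^2) z_j
            + K * sum_k A_jk z_k(t - tau_jk) + u_j(t)] dt + beta dW_j

where tau_jk are conduction delays and u_j(t) is a rectangular pulse of
strength p applied to the target nodes for t1 < t < t1 + T.  Integration uses
the Stratonovich-Heun predictor-corrector scheme with one Wiener increment
shared between predictor and corrector; the noise is additive, so the Ito and
Stratonovich interpretations coincide.  Noise is complex-valued white noise
with independent real and imaginary components of standard deviation beta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from critresp.connectome import Connectome, delay_matrix

__all__ = ["ModelParams", "StimulusSpec", "Trajectory", "integrate", "stimulus_waveform"]


@dataclass
class ModelParams:
    """Parameters of the coupled Stuart-Landau network.

    omega is the per-node angular natural frequency (rad/s); coupling is the
    homogeneous per-edge strength K; lam is the Hopf bifurcation parameter
    (limit cycle for lam > 0, stable focus for lam < 0); noise_sd is the
    standard deviation beta of each white-noise component; conduction_speed
    (m/s) and dt (s) convert distances to integer delay steps; burn_in
    seconds are simulated and discarded before the record_len seconds that
    are returned.
    """

    omega: np.ndarray | None
    coupling: float
    lam: float = 1.0
    noise_sd: float = 0.05
    conduction_speed: float = 7.0
    dt: float = 1e-3
    burn_in: float = 10.0
    record_len: float = 25.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.coupling < 0:
            raise ValueError("coupling must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.record_len <= 0:
            raise ValueError("record_len must be positive")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")


@dataclass
class StimulusSpec:
    """Rectangular pulse u(t) = p for t1 < t < t1 + T on the target nodes.

    ``onset`` (t1) is measured on the recorded time axis (0 = first recorded
    sample).  ``targets`` is a node-index set; None stimulates all nodes.
    ``phase`` optionally rotates the drift increment in the complex plane;
    the default of 0 adds a purely real term as in pulsatile stimulation.
    """

    strength: float
    onset: float
    duration: float = 0.05
    targets: np.ndarray | None = None
    phase: float = 0.0

    def validate(self, record_len: float) -> None:
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")
        if self.onset < 0 or self.onset + self.duration > record_len:
            raise ValueError(
                f"stimulus window [{self.onset}, {self.onset + self.duration}] "
                f"outside record of length {record_len}"
            )


def stimulus_waveform(t: float, spec: StimulusSpec, node: int) -> float:
    """Drift increment u(t) for one node: p inside the open pulse window, else 0."""
    if spec.targets is not None and node not in np.asarray(spec.targets):
        return 0.0
    if spec.onset < t < spec.onset + spec.duration:
        return spec.strength
    return 0.0


@dataclass
class Trajectory:
    """Recorded complex node states; phases and amplitudes derive from them."""

    states: np.ndarray  # (n_steps, n_nodes) complex128
    dt: float

    @property
    def n_steps(self) -> int:
        return self.states.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.states.shape[1]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt

    @property
    def phases(self) -> np.ndarray:
        """theta_j(t) = arg z_j(t) in (-pi, pi]."""
        return np.angle(self.states)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.abs(self.states)

    def phase_factors(self) -> np.ndarray:
        """Unit phasors e^{i theta_j(t)} (z / |z|)."""
        return self.states / np.abs(self.states)

    def history_tail(self, n_history: int) -> np.ndarray:
        """Last ``n_history + 1`` states, usable as the delay history of a
        continuation run."""
        if self.n_steps < n_history + 1:
            raise ValueError("trajectory shorter than requested history")
        return self.states[-(n_history + 1) :]

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("states", data=self.states, compression="gzip")
            fh.attrs["dt"] = self.dt

    @classmethod
    def from_hdf5(cls, path) -> "Trajectory":
        import h5py

        with h5py.File(path, "r") as fh:
            return cls(states=fh["states"][...], dt=float(fh.attrs["dt"]))


@njit(cache=False, fastmath=True)
def _heun_kernel(Z, H, n_steps, lam, omega, coupling, esrc, edst, edel,
                 noise_r, noise_i, noise_scale, umask, sa, sb, dt):  # pragma: no cover
    n = Z.shape[1]
    n_edges = esrc.shape[0]
    acc = np.empty(n, np.complex128)
    acc2 = np.empty(n, np.complex128)
    f0 = np.empty(n, np.complex128)
    for i in range(H, H + n_steps):
        for j in range(n):
            acc[j] = 0.0
        for e in range(n_edges):
            acc[edst[e]] += Z[i - edel[e], esrc[e]]
        on0 = 1.0 if (sa < i < sb) else 0.0
        on1 = 1.0 if (sa < i + 1 < sb) else 0.0
        for j in range(n):
            z = Z[i, j]
            f = (lam + 1j * omega[j] - (z.real * z.real + z.imag * z.imag)) * z \
                + coupling * acc[j] + on0 * umask[j]
            f0[j] = f
            Z[i + 1, j] = z + f * dt + noise_scale * (noise_r[i - H, j] + 1j * noise_i[i - H, j])
        for j in range(n):
            acc2[j] = 0.0
        for e in range(n_edges):
            acc2[edst[e]] += Z[i + 1 - edel[e], esrc[e]]
        for j in range(n):
            z0 = Z[i, j]
            z1 = Z[i + 1, j]
            f1 = (lam + 1j * omega[j] - (z1.real * z1.real + z1.imag * z1.imag)) * z1 \
                + coupling * acc2[j] + on1 * umask[j]
            Z[i + 1, j] = z0 + 0.5 * (f0[j] + f1) * dt \
                + noise_scale * (noise_r[i - H, j] + 1j * noise_i[i - H, j])


# Grow-only scratch buffers for Wiener increments; refilled per call so large
# allocations are paid once per process.
_noise_buffers: dict[str, np.ndarray] = {}


def _fill_noise(rng: np.random.Generator, n_steps: int, n_nodes: int):
    size = n_steps * n_nodes
    for key in ("r", "i"):
        buf = _noise_buffers.get(key)
        if buf is None or buf.size < size:
            _noise_buffers[key] = np.empty(size)
    re = _noise_buffers["r"][:size].reshape(n_steps, n_nodes)
    im = _noise_buffers["i"][:size].reshape(n_steps, n_nodes)
    rng.standard_normal(out=re.ravel())
    rng.standard_normal(out=im.ravel())
    return re, im


def _edge_arrays(conn: Connectome, tau: np.ndarray):
    src, dst = np.nonzero(conn.adjacency)  # both directions of each edge
    order = np.argsort(dst, kind="stable")  # destination-major for cache locality
    src, dst = src[order], dst[order]
    delays = tau[dst, src]
    return src.astype(np.int64), dst.astype(np.int64), delays.astype(np.int64)


def integrate(
    conn: Connectome,
    params: ModelParams,
    stimulus: StimulusSpec | None = None,
    init_history: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the network and return the recorded trajectory.

    The delay history is initialized either from ``init_history`` (the last
    ``H + 1`` rows of a previous trajectory, enabling continuation runs) or
    from small random states |z| = 0.1 with uniform phases held constant over
    the delay window; in the latter case ``burn_in`` must cover the maximum
    delay so the artificial history is discarded.

    Runs with the same seed are bit-reproducible; a stimulated and an
    unstimulated run with the same seed are identical before the onset.
    """
    params.validate()
    if params.omega is None:
        raise ValueError("params.omega must be set")
    omega = np.asarray(params.omega, dtype=float)
    n = conn.n_nodes
    if omega.shape != (n,):
        raise ValueError(f"omega shape {omega.shape} does not match {n} nodes")

    dt = params.dt
    tau = delay_matrix(conn, params.conduction_speed, dt)
    tau_edges = tau[conn.adjacency > 0]
    H = max(int(tau_edges.max()) if tau_edges.size else 0, 1)
    n_burn = int(round(params.burn_in / dt))
    n_rec = int(round(params.record_len / dt))
    n_steps = n_burn + n_rec

    rng = np.random.default_rng(params.rng_seed)
    Z = np.empty((H + n_steps + 1, n), dtype=np.complex128)
    if init_history is not None:
        init_history = np.asarray(init_history, dtype=np.complex128)
        if init_history.shape[0] < H + 1:
            raise ValueError(
                f"init_history must provide at least {H + 1} rows (max delay {H} steps), "
                f"got {init_history.shape[0]}"
            )
        Z[: H + 1] = init_history[-(H + 1) :]
    else:
        if n_burn < H:
            raise ValueError(
                f"burn_in ({params.burn_in}s) must cover the maximum delay ({H} steps)"
            )
        z0 = 0.1 * np.exp(1j * rng.uniform(0.0, 2.0 * np.pi, n))
        Z[: H + 1] = z0[None, :]

    umask = np.zeros(n, dtype=np.complex128)
    sa, sb = -1, -1
    if stimulus is not None:
        stimulus.validate(params.record_len)
        amp = stimulus.strength * np.exp(1j * stimulus.phase)
        if stimulus.targets is None:
            umask[:] = amp
        else:
            umask[np.asarray(stimulus.targets, dtype=np.int64)] = amp
        sa = H + n_burn + int(round(stimulus.onset / dt))
        sb = sa + int(round(stimulus.duration / dt))

    noise_r, noise_i = _fill_noise(rng, n_steps, n)
    noise_scale = params.noise_sd * np.sqrt(dt)
    esrc, edst, edel = _edge_arrays(conn, tau)
    if np.any(edel > H):
        raise ValueError("delay exceeds history buffer length")

    _heun_kernel(
        Z, H, n_steps, float(params.lam), omega, float(params.coupling),
        esrc, edst, edel, noise_r, noise_i, noise_scale, umask, sa, sb, dt,
    )

    states = Z[H + n_burn : H + n_burn + n_rec].copy()
    if not np.isfinite(states).all():
        bad = np.argwhere(~np.isfinite(states))[0]
        raise RuntimeError(
            f"non-finite state at recorded step {bad[0]}, node {bad[1]} "
            f"(K={params.coupling}); the integration blew up"
        )
    return Trajectory(states=states, dt=dt)
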
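"""Structural connectomes: synthetic generation, file I/O, delays, target sets.

The synthetic generator emulates an 82-region human structural connectome
(68 cortical regions of a Desikan-Killiany-style parcellation plus 14
subcortical structures, 41 per hemisphere).  Region centroids are drawn
around approximate anatomical positions and edges are wired with an
exponentially distance-decaying probability rescaled to a target density,
reproducing the short-range bias of diffusion-imaging connectomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

#: Approximate centroids (mm) of left-hemisphere regions in a brain-shaped
#: coordinate frame: x lateral (negative = left), y posterior-anterior,
#: z inferior-superior.  Values are coarse anatomical positions; per-draw
#: jitter and a global rescale are applied on top.
_CORTICAL_CENTROIDS = {
    "bankssts": (-52.0, -45.0, 10.0),
    "caudalanteriorcingulate": (-5.0, 20.0, 30.0),
    "caudalmiddlefrontal": (-35.0, 12.0, 50.0),
    "cuneus": (-8.0, -80.0, 28.0),
    "entorhinal": (-25.0, -10.0, -30.0),
    "frontalpole": (-9.0, 62.0, -10.0),
    "fusiform": (-35.0, -45.0, -20.0),
    "inferiorparietal": (-42.0, -65.0, 35.0),
    "inferiortemporal": (-50.0, -30.0, -25.0),
    "insula": (-35.0, 5.0, 5.0),
    "isthmuscingulate": (-8.0, -45.0, 25.0),
    "lateraloccipital": (-30.0, -88.0, 5.0),
    "lateralorbitofrontal": (-25.0, 35.0, -15.0),
    "lingual": (-12.0, -70.0, -5.0),
    "medialorbitofrontal": (-8.0, 40.0, -18.0),
    "middletemporal": (-55.0, -30.0, -10.0),
    "paracentral": (-8.0, -25.0, 60.0),
    "parahippocampal": (-25.0, -35.0, -15.0),
    "parsopercularis": (-48.0, 15.0, 15.0),
    "parsorbitalis": (-45.0, 40.0, -8.0),
    "parstriangularis": (-47.0, 30.0, 5.0),
    "pericalcarine": (-10.0, -85.0, 10.0),
    "postcentral": (-40.0, -25.0, 50.0),
    "posteriorcingulate": (-6.0, -35.0, 35.0),
    "precentral": (-38.0, -10.0, 50.0),
    "precuneus": (-10.0, -58.0, 40.0),
    "rostralanteriorcingulate": (-6.0, 35.0, 10.0),
    "rostralmiddlefrontal": (-32.0, 45.0, 25.0),
    "superiorfrontal": (-12.0, 30.0, 55.0),
    "superiorparietal": (-25.0, -55.0, 55.0),
    "superiortemporal": (-52.0, -15.0, 0.0),
    "supramarginal": (-50.0, -45.0, 30.0),
    "temporalpole": (-32.0, 15.0, -35.0),
    "transversetemporal": (-45.0, -22.0, 10.0),
}

_SUBCORTICAL_CENTROIDS = {
    "thalamus": (-12.0, -20.0, 8.0),
    "caudate": (-13.0, 10.0, 10.0),
    "putamen": (-25.0, 0.0, 0.0),
    "pallidum": (-20.0, -5.0, 0.0),
    "hippocampus": (-26.0, -25.0, -12.0),
    "amygdala": (-24.0, -5.0, -18.0),
    "accumbens": (-10.0, 10.0, -8.0),
}

#: Node label used as the seed of the occipital target set.
OCCIPITAL_SEED_LABEL = "lh.cuneus"
DEFAULT_N_NODES = 82
DEFAULT_EDGE_DENSITY = 0.27  # typical group-averaged DTI adjacency density
DEFAULT_SPATIAL_SCALE_MM = 170.0  # max centroid distance; delay <= ~24 ms at 7 m/s


@dataclass
class Connectome:
    """A binary, symmetric structural brain network.

    Attributes
    ----------
    adjacency : (N, N) int array with entries in {0, 1}, zero diagonal.
    coords : (N, 3) region centroids in mm, or None when only distances are known.
    distances : (N, N) symmetric inter-region distances in mm.
    labels : region names, one per node.
    occipital_set : optional indices of the occipital target region.
    """

    adjacency: np.ndarray
    distances: np.ndarray
    labels: list[str]
    coords: np.ndarray | None = None
    occipital_set: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def edge_density(self) -> float:
        n = self.n_nodes
        return float(self.adjacency.sum() / (n * (n - 1)))

    def validate(self) -> None:
        a, d = self.adjacency, self.distances
        n = a.shape[0]
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"adjacency is not square: shape {a.shape}")
        bad = np.argwhere((a != 0) & (a != 1))
        if bad.size:
            i, j = bad[0]
            raise ValueError(f"adjacency entry ({i},{j})={a[i, j]} is not binary")
        if not np.array_equal(a, a.T):
            i, j = np.argwhere(a != a.T)[0]
            raise ValueError(f"adjacency asymmetric at ({i},{j}): {a[i, j]} != {a[j, i]}")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency has nonzero diagonal entries")
        if d.shape != (n, n):
            raise ValueError(f"distance matrix shape {d.shape} does not match {n} nodes")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix has nonzero diagonal entries")
        if np.any(d[~np.eye(n, dtype=bool)] < 0):
            raise ValueError("distance matrix has negative entries")
        if self.coords is not None:
            expected = squareform(pdist(self.coords))
            if not np.allclose(d, expected, atol=1e-6):
                raise ValueError("distances do not match Euclidean distances of coords")
        n_comp, _ = connected_components(a, directed=False)
        if n_comp != 1:
            raise ValueError(f"graph is disconnected ({n_comp} components)")
        if len(self.labels) != n:
            raise ValueError("label count does not match node count")


def _template_82(rng: np.random.Generator, jitter_mm: float) -> tuple[np.ndarray, list[str]]:
    labels: list[str] = []
    coords: list[tuple[float, float, float]] = []
    for hemi, sign in (("lh", 1.0), ("rh", -1.0)):
        for name, (x, y, z) in {**_CORTICAL_CENTROIDS, **_SUBCORTICAL_CENTROIDS}.items():
            labels.append(f"{hemi}.{name}")
            coords.append((sign * x, y, z))
    pts = np.asarray(coords, dtype=float)
    pts += rng.normal(0.0, jitter_mm, pts.shape)
    return pts, labels


def _generic_cloud(n: int, rng: np.random.Generator) -> tuple[np.ndarray, list[str]]:
    # Ellipsoidal point cloud roughly shaped like a brain (ML, AP, SI semi-axes).
    axes = np.array([65.0, 85.0, 55.0])
    pts = np.empty((n, 3))
    count = 0
    while count < n:
        cand = rng.uniform(-1.0, 1.0, size=(4 * (n - count), 3))
        keep = cand[(cand**2).sum(axis=1) <= 1.0]
        take = keep[: n - count]
        pts[count : count + take.shape[0]] = take * axes
        count += take.shape[0]
    labels = [f"region_{i:03d}" for i in range(n)]
    # Designate the most posterior node as the occipital seed.
    seed = int(np.argmin(pts[:, 1]))
    labels[seed] = OCCIPITAL_SEED_LABEL
    return pts, labels


def _rescale_to_max_distance(coords: np.ndarray, target_mm: float) -> np.ndarray:
    d = pdist(coords)
    dmax = d.max()
    if dmax <= 0:
        raise ValueError("degenerate coordinates: all nodes coincide")
    center = coords.mean(axis=0)
    return (coords - center) * (target_mm / dmax) + center


def _edge_probabilities(distances: np.ndarray, density: float, decay_mm: float) -> np.ndarray:
    """Per-pair wiring probabilities min(1, c * exp(-d / decay)) with c chosen
    by bisection so the expected density matches the target."""
    iu = np.triu_indices_from(distances, k=1)
    w = np.exp(-distances[iu] / decay_mm)
    if density >= 1.0:
        return np.ones_like(w)

    def mean_p(log_c: float) -> float:
        return float(np.minimum(1.0, np.exp(log_c) * w).mean())

    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < density:
            lo = mid
        else:
            hi = mid
    return np.minimum(1.0, np.exp(0.5 * (lo + hi)) * w)


def generate_synthetic_connectome(
    n_nodes: int = DEFAULT_N_NODES,
    edge_density: float = DEFAULT_EDGE_DENSITY,
    spatial_scale_mm: float = DEFAULT_SPATIAL_SCALE_MM,
    rng_seed: int = 0,
    *,
    decay_mm: float = 45.0,
    jitter_mm: float = 4.0,
    occipital_radius_mm: float = 50.0,
    max_retries: int = 50,
) -> Connectome:
    """Generate a synthetic structural brain network.

    Wiring probability decays exponentially with Euclidean centroid distance
    and is rescaled so the expected edge density matches ``edge_density``.
    For ``n_nodes == 82`` the anatomical 82-region template is used (labels
    include the occipital seed ``lh.cuneus``); other sizes get a generic
    ellipsoidal layout with the most posterior node designated as the seed.

    Parameters
    ----------
    spatial_scale_mm
        Maximum pairwise centroid distance after rescaling.  The default of
        170 mm keeps conduction delays at 7 m/s below ~25 ms, a quarter of
        the 10-Hz oscillation period.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if not 0.0 < edge_density <= 1.0:
        raise ValueError("edge_density must be in (0, 1]")
    n_pairs = n_nodes * (n_nodes - 1) // 2
    if edge_density * n_pairs < n_nodes - 1:
        raise ValueError(
            f"edge_density {edge_density} cannot yield a connected graph on {n_nodes} nodes"
        )

    rng = np.random.default_rng(rng_seed)
    if n_nodes == DEFAULT_N_NODES:
        coords, labels = _template_82(rng, jitter_mm)
    else:
        coords, labels = _generic_cloud(n_nodes, rng)
    coords = _rescale_to_max_distance(coords, spatial_scale_mm)
    distances = squareform(pdist(coords))
    probs = _edge_probabilities(distances, edge_density, decay_mm)

    iu = np.triu_indices(n_nodes, k=1)
    adjacency = None
    for attempt in range(max_retries):
        draw = rng.random(n_pairs) < probs
        a = np.zeros((n_nodes, n_nodes), dtype=np.int8)
        a[iu] = draw
        a += a.T
        n_comp, _ = connected_components(a, directed=False)
        if n_comp == 1:
            adjacency = a
            break
        logger.debug("connectome draw %d disconnected (%d components); resampling", attempt, n_comp)
    if adjacency is None:
        raise RuntimeError(
            f"failed to draw a connected graph in {max_retries} attempts "
            f"(n={n_nodes}, density={edge_density})"
        )

    seed_idx = labels.index(OCCIPITAL_SEED_LABEL)
    occipital = np.flatnonzero(distances[seed_idx] <= occipital_radius_mm)
    conn = Connectome(
        adjacency=adjacency,
        distances=distances,
        labels=labels,
        coords=coords,
        occipital_set=occipital,
    )
    conn.validate()
    return conn


def _read_matrix(path) -> np.ndarray:
    with open(path) as fh:
        text = fh.read()
    delimiter = "," if "," in text else None
    return np.atleast_2d(np.loadtxt(path, delimiter=delimiter))


def load_connectome(
    adjacency_path,
    coords_path=None,
    distances_path=None,
) -> Connectome:
    """Read a connectome from plain-text files.

    ``adjacency_path`` holds a whitespace- or comma-delimited square binary
    matrix.  Coordinates are TSV rows ``label<TAB>x<TAB>y<TAB>z`` (mm).  An
    explicit distance matrix overrides Euclidean distances from coordinates
    (e.g. to supply fiber lengths instead of straight-line distances).
    """
    a = _read_matrix(adjacency_path)
    if a.shape[0] != a.shape[1]:
        raise ValueError(f"adjacency matrix is not square: shape {a.shape}")
    bad = np.argwhere((a != 0) & (a != 1))
    if bad.size:
        i, j = bad[0]
        raise ValueError(f"adjacency entry ({i},{j})={a[i, j]} is not binary")
    if not np.array_equal(a, a.T):
        i, j = np.argwhere(a != a.T)[0]
        raise ValueError(f"adjacency asymmetric at ({i},{j}): {a[i, j]} != {a[j, i]}")
    a = a.astype(np.int8)
    n = a.shape[0]

    coords = None
    labels = [f"region_{i:03d}" for i in range(n)]
    if coords_path is not None:
        rows = []
        labels = []
        with open(coords_path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) != 4:
                    raise ValueError(f"coords row must be label<TAB>x<TAB>y<TAB>z, got {line!r}")
                labels.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        coords = np.asarray(rows)
        if coords.shape[0] != n:
            raise ValueError(f"coords rows ({coords.shape[0]}) do not match adjacency size ({n})")

    if distances_path is not None:
        distances = _read_matrix(distances_path)
        if coords is not None:
            # Explicit distances override Euclidean ones; drop coords so the
            # Euclidean invariant is not enforced against fiber lengths.
            coords = None
    elif coords is not None:
        distances = squareform(pdist(coords))
    else:
        raise ValueError("either coords_path or distances_path is required")

    occ = None
    if OCCIPITAL_SEED_LABEL in labels:
        seed_idx = labels.index(OCCIPITAL_SEED_LABEL)
        occ = np.flatnonzero(distances[seed_idx] <= 50.0)
    conn = Connectome(
        adjacency=a, distances=distances, labels=labels, coords=coords, occipital_set=occ
    )
    conn.validate()
    return conn


def save_connectome(conn: Connectome, adjacency_path, coords_path=None) -> None:
    """Write adjacency (whitespace matrix) and optional coordinates (TSV)."""
    np.savetxt(adjacency_path, conn.adjacency, fmt="%d")
    if coords_path is not None:
        if conn.coords is None:
            raise ValueError("connectome has no coordinates to write")
        with open(coords_path, "w") as fh:
            for label, (x, y, z) in zip(conn.labels, conn.coords):
                fh.write(f"{label}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")


def delay_matrix(conn: Connectome, conduction_speed: float = 7.0, dt: float = 1e-3) -> np.ndarray:
    """Integer conduction-delay steps tau_jk = round(D_jk / s / dt).

    ``conduction_speed`` is in m/s, distances in mm, ``dt`` in seconds; the
    delay D/s is therefore in milliseconds.  Rounding is to the nearest
    integer step with exact ties going toward zero (fixed-step integrator).
    """
    if conduction_speed <= 0:
        raise ValueError("conduction_speed must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    tau_ms = conn.distances / conduction_speed
    x = tau_ms / (dt * 1e3)
    steps = np.floor(x + 0.5)
    ties = np.mod(x, 1.0) == 0.5
    steps[ties] -= 1
    steps = steps.astype(np.int64)
    np.fill_diagonal(steps, 0)
    return steps


def sample_natural_frequencies(
    n: int, mean_hz: float = 10.0, sd_hz: float = 0.5, rng_seed: int = 0
) -> np.ndarray:
    """Per-node angular frequencies omega_j = 2*pi*f_j, f_j ~ N(mean_hz, sd_hz)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd_hz < 0:
        raise ValueError("sd_hz must be >= 0")
    rng = np.random.default_rng(rng_seed)
    return 2.0 * np.pi * rng.normal(mean_hz, sd_hz, size=n)


def select_local_targets(conn: Connectome, center_label: str, radius_mm: float) -> np.ndarray:
    """Indices of all nodes within ``radius_mm`` of the named center node."""
    if center_label not in conn.labels:
        raise KeyError(
            f"unknown label {center_label!r}; available labels: {', '.join(conn.labels)}"
        )
    idx = conn.labels.index(center_label)
    if conn.coords is not None:
        dist = np.linalg.norm(conn.coords - conn.coords[idx], axis=1)
    else:
        dist = conn.distances[idx]
    return np.flatnonzero(dist <= radius_mm)
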
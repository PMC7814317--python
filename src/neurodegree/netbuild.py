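"""Voxel-level functional connectivity graphs, degrees and FCS.

The network nodes are grey-matter voxels; edges come from thresholding the
Pearson correlation matrix of the voxel time series.  Two printed rules
shape the graph: only positive correlations count (a_ij = 1 iff
r_ij >= T, with T in {0.4, 0.5, 0.6} by default), and connectivity
terminating within ``d_min`` = 20 mm of the source voxel center is zeroed
to suppress shared signal between neighbours.  Subnetwork degree sequences
are *global* degrees (connections to anywhere in the brain) restricted to
the member voxels of the subnetwork.

FCS (functional connectivity strength, weighted degree centrality) is the
mean Fisher-z-transformed correlation of a voxel to all others above a
floor r0 — note the deliberate asymmetry with binarization: degrees use
``r >= T``, FCS uses strict ``r > r0``, both as printed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .synthetic import SyntheticScene, NETWORKS, WHOLE_BRAIN

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.4, 0.5, 0.6)
DEFAULT_R0 = 0.2
DEFAULT_D_MIN = 20.0
DEFAULT_GM_CUTOFF = 0.2


@dataclass
class ConnectivityGraph:
    """Correlation matrix over eligible voxels plus the excluded-pair mask.

    ``eligible_index`` maps graph node -> original voxel index.  Excluded
    pairs (closer than the distance floor) carry no edge at any threshold
    and contribute nothing to FCS.
    """

    r: np.ndarray
    eligible_index: np.ndarray
    excluded: np.ndarray | None = None
    atlas: np.ndarray | None = None
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = self.r.shape[0]
        if self.r.shape != (n, n):
            raise ValueError("correlation matrix must be square")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if self.excluded is None:
            self.excluded = np.zeros((n, n), dtype=bool)
        self.eligible_index = np.asarray(self.eligible_index)
        if self.eligible_index.shape != (n,):
            raise ValueError("eligible_index must have one entry per node")

    @property
    def n_nodes(self) -> int:
        return self.r.shape[0]


@dataclass
class DegreeSequence:
    """Integer degrees for a (network, threshold) pair."""

    degrees: np.ndarray
    network: str = WHOLE_BRAIN
    threshold: float = float("nan")
    node_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.degrees = np.asarray(self.degrees, dtype=np.int64)


@dataclass
class FCSMap:
    """Per-node functional connectivity strength (weighted degree)."""

    fcs: np.ndarray
    r0: float
    node_index: np.ndarray | None = None


def make_gm_mask(prob_map: np.ndarray, cutoff: float = DEFAULT_GM_CUTOFF) -> np.ndarray:
    """Grey-matter mask: voxels whose probability is >= cutoff (inclusive).

    Returns a boolean array over voxels; raises if the mask comes out empty.
    """
    prob = np.asarray(prob_map, dtype=float)
    if np.any((prob < 0) | (prob > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    mask = prob >= cutoff
    if not mask.any():
        raise ValueError(f"empty grey-matter mask at cutoff {cutoff}")
    return mask


def correlation_matrix(scene: SyntheticScene, mask: np.ndarray | None = None) -> ConnectivityGraph:
    """Full Pearson correlation matrix over eligible (masked, non-constant)
    voxels.  Zero-variance voxels are removed with a logged warning — their
    correlation is undefined."""
    if scene.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints")
    idx = np.arange(scene.n_voxels)
    if mask is not None:
        idx = idx[np.asarray(mask, dtype=bool)]
    series = scene.series[idx]
    sd = series.std(axis=1)
    # constant voxels leave a float-noise std ~1e-16; test relative to scale
    tol = 1e-12 * np.maximum(1.0, np.abs(series).max(axis=1))
    if np.any(sd <= tol):
        n_const = int(np.sum(sd <= tol))
        logger.warning("excluding %d zero-variance voxel(s) from the graph", n_const)
        keep = sd > tol
        idx, series = idx[keep], series[keep]
    if idx.size < 2:
        raise ValueError("fewer than 2 eligible voxels with nonzero variance")
    r = np.corrcoef(series)
    np.fill_diagonal(r, 0.0)  # diagonal ignored: no self-edges
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return ConnectivityGraph(r=r, eligible_index=idx,
                             atlas=scene.atlas[idx], coords=scene.coords[idx])


def apply_distance_exclusion(graph: ConnectivityGraph,
                             coords: np.ndarray | None = None,
                             d_min: float = DEFAULT_D_MIN) -> ConnectivityGraph:
    """Mark voxel pairs closer than ``d_min`` mm (strict) as excluded.

    Excluded pairs carry no edge at any threshold and contribute zero to
    FCS.  Distance is Euclidean between voxel centers in mm.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    coords = graph.coords if coords is None else np.asarray(coords, dtype=float)
    if coords is None or coords.shape[0] != graph.n_nodes:
        raise ValueError("coords must align with the graph's eligible nodes")
    dist = squareform(pdist(coords))
    excluded = dist < d_min
    np.fill_diagonal(excluded, True)
    return ConnectivityGraph(r=graph.r, eligible_index=graph.eligible_index,
                             excluded=excluded, atlas=graph.atlas, coords=coords)


def _adjacency(graph: ConnectivityGraph, T: float) -> np.ndarray:
    a = (graph.r >= T) & ~graph.excluded
    np.fill_diagonal(a, False)
    return a


def compute_degrees(graph: ConnectivityGraph, T: float) -> DegreeSequence:
    """Binarized nodal degree: degree(i) = #{j != i : r_ij >= T}, skipping
    distance-excluded pairs.  T must be positive — only positive
    correlations define edges."""
    if T <= 0:
        raise ValueError("threshold T must be positive (only positive "
                         "correlations are considered)")
    deg = _adjacency(graph, T).sum(axis=1).astype(np.int64)
    return DegreeSequence(degrees=deg, network=WHOLE_BRAIN, threshold=T,
                          node_index=graph.eligible_index.copy())


def subnetwork_degrees(deg: DegreeSequence, atlas: np.ndarray, k: int,
                       label: str | None = None) -> DegreeSequence:
    """Whole-brain degree values restricted to nodes with atlas label k.

    The values themselves are unchanged: a subnetwork's degree sequence is
    the *global* degree of its member voxels, not the within-subnetwork
    edge count.
    """
    if not 1 <= int(k) <= 7:
        raise ValueError("subnetwork label k must lie in 1..7")
    atlas = np.asarray(atlas)
    if atlas.shape != deg.degrees.shape:
        raise ValueError("atlas must align with the degree sequence")
    sel = atlas == k
    if not sel.any():
        raise ValueError(f"no nodes carry atlas label {k}")
    name = label if label is not None else NETWORKS[int(k) - 1]
    return DegreeSequence(degrees=deg.degrees[sel], network=name,
                          threshold=deg.threshold,
                          node_index=None if deg.node_index is None
                          else deg.node_index[sel])


def compute_fcs(graph: ConnectivityGraph, r0: float = DEFAULT_R0) -> FCSMap:
    """Functional connectivity strength: FCS(i) = (1/N) * sum_j z_ij over
    j != i with r_ij > r0 (strict) and not distance-excluded, where z is
    Fisher's transform and N the eligible-voxel count (the denominator is
    fixed at N regardless of how many terms survive the floor)."""
    if not 0 < r0 < 1:
        raise ValueError("r0 must lie in (0, 1)")
    keep = (graph.r > r0) & ~graph.excluded
    np.fill_diagonal(keep, False)
    z = np.where(keep, np.arctanh(np.clip(graph.r, -1 + 1e-15, 1 - 1e-15)), 0.0)
    fcs = z.sum(axis=1) / graph.n_nodes
    return FCSMap(fcs=fcs, r0=r0, node_index=graph.eligible_index.copy())


def scene_degree_sequences(scene: SyntheticScene, T: float,
                           d_min: float = DEFAULT_D_MIN,
                           mask: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Convenience: whole-brain + per-subnetwork degree arrays for a scene
    at one threshold, with the distance exclusion applied."""
    graph = apply_distance_exclusion(correlation_matrix(scene, mask), d_min=d_min)
    deg = compute_degrees(graph, T)
    out = {WHOLE_BRAIN: deg.degrees}
    for k, name in enumerate(NETWORKS, start=1):
        if np.any(graph.atlas == k):
            out[name] = subnetwork_degrees(deg, graph.atlas, k, label=name).degrees
    return out
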
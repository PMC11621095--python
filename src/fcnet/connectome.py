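"""Functional network construction: correlation, Fisher z, sparsity thresholding.

A subject's connectome is the 90 x 90 matrix of Pearson correlations between
regional time series, Fisher r-to-z transformed. Binary networks are formed
by keeping, at sparsity ``s``, the k = round(s * N(N-1)/2) strongest
off-diagonal weights as edges, so every subject's network has the same edge
count and group comparisons are not confounded by overall correlation
strength. The sweep covers s = 0.032 to 0.492 in steps of 0.01 (47 levels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .preprocess import RoiTimeSeries

N_DEFAULT = 90


@dataclass
class WeightedConnectome:
    """Symmetric Fisher-z connectivity matrix with zero diagonal."""

    z_matrix: np.ndarray
    region_labels: list[str]

    def __post_init__(self) -> None:
        z = np.asarray(self.z_matrix, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("z_matrix must be square")
        if z.shape[0] != len(self.region_labels):
            raise ValueError("label count must match matrix size")
        if not np.allclose(z, z.T, atol=1e-12):
            raise ValueError("z_matrix must be symmetric within 1e-12")
        if np.any(np.diag(z) != 0):
            raise ValueError("z_matrix diagonal must be exactly zero")
        if not np.all(np.isfinite(z)):
            raise ValueError("off-diagonal entries must be finite")
        self.z_matrix = z

    @property
    def n_regions(self) -> int:
        return self.z_matrix.shape[0]


@dataclass
class BinaryNetwork:
    """Undirected binary adjacency at a fixed sparsity (no self-loops)."""

    adjacency: np.ndarray
    sparsity: float
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        self.adjacency = a.astype(np.uint8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def edge_count(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(np.int64)


@dataclass
class SparsityGrid:
    """Arithmetic sparsity sweep; values are generated from integer indices
    so repeated addition of the float step cannot drift."""

    s_min: float = 0.032
    s_max: float = 0.492
    step: float = 0.01
    values: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not 0 < self.s_min <= self.s_max < 1 or self.step <= 0:
            raise ValueError("invalid sparsity grid")
        scale = 10**6
        lo = round(self.s_min * scale)
        st = round(self.step * scale)
        hi = round(self.s_max * scale)
        self.values = np.array([v / scale for v in range(lo, hi + 1, st)])

    def __len__(self) -> int:
        return len(self.values)

    @property
    def width(self) -> float:
        return float(self.values[-1] - self.values[0])


def correlation_matrix(ts: RoiTimeSeries) -> np.ndarray:
    """Pearson correlation between all pairs of regional series."""
    if ts.n_volumes < 3:
        raise ValueError("need at least 3 volumes for a correlation matrix")
    sd = ts.values.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = ", ".join(ts.region_labels[i] for i in zero[:5])
        raise ValueError(f"zero-variance region(s): {names}")
    r = np.corrcoef(ts.values.T)
    np.clip(r, -1.0, 1.0, out=r)
    return r


def fisher_z(r_matrix: np.ndarray, region_labels: list[str] | None = None) -> WeightedConnectome:
    """Fisher r-to-z transform (arctanh) of a correlation matrix.

    Off-diagonal values at |r| >= 1 are clipped to 1 - 1e-7 with a warning;
    the diagonal is set to zero.
    """
    r = np.asarray(r_matrix, dtype=float).copy()
    n = r.shape[0]
    np.fill_diagonal(r, 0.0)
    clip = 1.0 - 1e-7
    if np.any(np.abs(r) >= 1.0):
        warnings.warn(
            "correlations at |r| >= 1 clipped before Fisher transform",
            stacklevel=2,
        )
        np.clip(r, -clip, clip, out=r)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0  # enforce exact symmetry against fp asymmetry
    np.fill_diagonal(z, 0.0)
    labels = region_labels or [f"R{i + 1:03d}" for i in range(n)]
    return WeightedConnectome(z, labels)


def connectome_from_timeseries(ts: RoiTimeSeries) -> WeightedConnectome:
    return fisher_z(correlation_matrix(ts), ts.region_labels)


def edge_count_at_sparsity(s: float, n_nodes: int) -> int:
    """k = round(s * N(N-1)/2), rounding half away from zero."""
    return int(np.floor(s * n_nodes * (n_nodes - 1) / 2 + 0.5))


def _ranked_pairs(w: WeightedConnectome, rank: str) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle pairs ordered best-first; ties broken by (i, j)."""
    iu, ju = np.triu_indices(w.n_regions, k=1)
    weights = w.z_matrix[iu, ju]
    key = np.abs(weights) if rank == "abs" else weights
    # lexsort: last key primary; stable ordering gives (i, j) tie-break
    order = np.lexsort((ju, iu, -key))
    return iu[order], ju[order]


def binarize_at_sparsity(
    w: WeightedConnectome, s: float, rank: str = "signed"
) -> BinaryNetwork:
    """Keep the k strongest weights as edges at sparsity ``s``.

    ``rank='signed'`` keeps the most-positive correlations (the default:
    an edge exists where regions correlate most strongly); ``rank='abs'``
    ranks by magnitude.
    """
    if not 0 < s < 1:
        raise ValueError("sparsity must be in (0, 1)")
    if rank not in ("signed", "abs"):
        raise ValueError("rank must be 'signed' or 'abs'")
    k = edge_count_at_sparsity(s, w.n_regions)
    if k == 0:
        raise ValueError(f"sparsity {s} yields zero edges for N={w.n_regions}")
    ii, jj = _ranked_pairs(w, rank)
    adj = np.zeros((w.n_regions, w.n_regions), dtype=np.uint8)
    adj[ii[:k], jj[:k]] = 1
    adj |= adj.T
    return BinaryNetwork(adj, s, w.region_labels)


def sweep(
    w: WeightedConnectome, grid: SparsityGrid | None = None, rank: str = "signed"
) -> list[BinaryNetwork]:
    """One binary network per grid sparsity; edge sets are nested because
    the ranking is computed once."""
    grid = grid or SparsityGrid()
    ii, jj = _ranked_pairs(w, rank)
    nets = []
    for s in grid.values:
        k = edge_count_at_sparsity(s, w.n_regions)
        if k == 0:
            raise ValueError(f"sparsity {s} yields zero edges")
        adj = np.zeros((w.n_regions, w.n_regions), dtype=np.uint8)
        adj[ii[:k], jj[:k]] = 1
        adj |= adj.T
        nets.append(BinaryNetwork(adj, float(s), w.region_labels))
    return nets


# ---------------------------------------------------------------------------
# text exports (TSV matrices, edge lists, BrainNet Viewer .node/.edge)
# ---------------------------------------------------------------------------

def write_connectome_tsv(w: WeightedConnectome, path: str | Path) -> None:
    np.savetxt(path, w.z_matrix, fmt="%.6f", delimiter="\t")


def read_connectome_tsv(path: str | Path, region_labels: list[str] | None = None) -> WeightedConnectome:
    z = np.loadtxt(path)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    labels = region_labels or [f"R{i + 1:03d}" for i in range(z.shape[0])]
    return WeightedConnectome(z, labels)


def write_edge_list(net: BinaryNetwork, path: str | Path) -> None:
    ii, jj = np.nonzero(np.triu(net.adjacency, k=1))
    with open(path, "w") as fh:
        fh.write("i\tj\tweight\n")
        for i, j in zip(ii, jj):
            fh.write(f"{i}\t{j}\t1\n")


def write_brainnet(
    net: BinaryNetwork,
    prefix: str | Path,
    coordinates: np.ndarray | None = None,
) -> tuple[Path, Path]:
    """Write BrainNet-Viewer-compatible ``.edge`` (N x N ASCII matrix) and
    ``.node`` (x y z color size label) files; placeholder coordinates are
    used when none are supplied."""
    prefix = Path(prefix)
    edge_path = prefix.with_suffix(".edge")
    node_path = prefix.with_suffix(".node")
    np.savetxt(edge_path, net.adjacency, fmt="%d", delimiter="\t")
    n = net.n_nodes
    if coordinates is None:
        coordinates = np.zeros((n, 3))
    labels = net.region_labels or [f"R{i + 1:03d}" for i in range(n)]
    deg = net.degrees
    with open(node_path, "w") as fh:
        for i in range(n):
            x, y, z = coordinates[i]
            fh.write(
                f"{x:.1f}\t{y:.1f}\t{z:.1f}\t1\t{deg[i]}\t{labels[i]}\n"
            )
    return node_path, edge_path
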
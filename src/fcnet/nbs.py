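"""Network-based statistics (NBS) on functional connections.

Edge-wise group inference with family-wise error control by permutation:

1. for every off-diagonal edge, fit the same covariate-adjusted GLM used
   for the metric AUCs to the subjects' Fisher-z values and take the group
   coefficient's t;
2. threshold the t map at a primary edge-level threshold (default: the t
   corresponding to two-tailed p < 0.01) in the requested tail
   (patient > control or patient < control, run separately);
3. find connected components of the supra-threshold edges; the test
   statistic is the component size in edges;
4. permute group labels (covariates stay attached to their subjects),
   rebuild the max component size each time, and assign each observed
   component the corrected p

       p = (1 + #{null max size >= observed size}) / (1 + n_permutations),

   which is never zero and is monotone in the observed size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _cc

from .connectome import WeightedConnectome, BinaryNetwork, write_brainnet
from .stats import DesignMatrix

TAILS = ("patient_gt", "patient_lt")


@dataclass
class EdgeStatMap:
    t_matrix: np.ndarray
    primary_threshold: float  # positive t magnitude
    tail: str
    df: int
    supra_adjacency: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.t_matrix, dtype=float)
        if not np.allclose(t, t.T, atol=1e-10):
            raise ValueError("edge t matrix must be symmetric")
        if self.tail not in TAILS:
            raise ValueError(f"tail must be one of {TAILS}")
        np.fill_diagonal(t, 0.0)
        self.t_matrix = t
        if self.tail == "patient_gt":
            supra = t > self.primary_threshold
        else:
            supra = t < -self.primary_threshold
        np.fill_diagonal(supra, False)
        self.supra_adjacency = supra.astype(np.uint8)


@dataclass
class NbsComponent:
    edges: list[tuple[int, int]]
    nodes: list[int]
    size_in_edges: int
    corrected_p: float = np.nan


@dataclass
class NbsResult:
    components: list[NbsComponent]
    null_max_sizes: np.ndarray
    n_permutations: int
    seed: int
    tail: str
    primary_threshold: float
    edge_map: EdgeStatMap

    @property
    def significant(self) -> list[NbsComponent]:
        return [c for c in self.components if c.corrected_p < 0.05]


def _stack(connectomes: list[WeightedConnectome]) -> tuple[np.ndarray, int]:
    n = connectomes[0].n_regions
    iu, ju = np.triu_indices(n, k=1)
    Y = np.stack([w.z_matrix[iu, ju] for w in connectomes])
    return Y, n


def _edge_t(Y: np.ndarray, X: np.ndarray, coef_index: int) -> np.ndarray:
    """Vectorised OLS t of one coefficient across many edge outcomes."""
    n, p = X.shape
    df = n - p
    xtx_inv = np.linalg.inv(X.T @ X)
    proj = xtx_inv @ X.T  # (p, n)
    beta = proj @ Y  # (p, n_edges)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    var = rss / df * xtx_inv[coef_index, coef_index]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[coef_index] / np.sqrt(var)
    t[~np.isfinite(t)] = 0.0
    return t


def threshold_from_p(p_threshold: float, df: int) -> float:
    """Primary |t| threshold equivalent to a two-tailed edge-level p."""
    return float(sps.t.isf(p_threshold / 2.0, df))


def edge_t_map(
    connectomes: list[WeightedConnectome],
    design: DesignMatrix,
    tail: str = "patient_lt",
    primary_threshold: float | None = None,
    p_threshold: float = 0.01,
) -> EdgeStatMap:
    """Edge-wise group-coefficient t map with supra-threshold mask."""
    if len(connectomes) != design.n_subjects:
        raise ValueError(
            f"{len(connectomes)} connectomes for {design.n_subjects} design rows"
        )
    Y, n = _stack(connectomes)
    t = _edge_t(Y, design.matrix, design.group_index)
    tm = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    tm[iu, ju] = t
    tm = tm + tm.T
    df = design.df_resid
    thr = primary_threshold if primary_threshold is not None else threshold_from_p(p_threshold, df)
    return EdgeStatMap(tm, thr, tail, df)


def connected_component_sizes(supra_adjacency: np.ndarray) -> list[NbsComponent]:
    """Connected components of the supra-threshold graph, largest first;
    isolated nodes are ignored and size is counted in edges."""
    a = np.asarray(supra_adjacency)
    if a.sum() == 0:
        return []
    n_comp, labels = _cc(csr_matrix(a), directed=False)
    comps = []
    for c in range(n_comp):
        nodes = np.flatnonzero(labels == c)
        if nodes.size < 2:
            continue
        sub = a[np.ix_(nodes, nodes)]
        n_edges = int(sub.sum()) // 2
        if n_edges == 0:
            continue
        ii, jj = np.nonzero(np.triu(a, k=1))
        mask = np.isin(ii, nodes)
        comps.append(
            NbsComponent(
                edges=[(int(i), int(j)) for i, j in zip(ii[mask], jj[mask])],
                nodes=[int(v) for v in nodes],
                size_in_edges=n_edges,
            )
        )
    comps.sort(key=lambda c: -c.size_in_edges)
    return comps


def _max_component_size(supra: np.ndarray) -> int:
    comps = connected_component_sizes(supra)
    return comps[0].size_in_edges if comps else 0


def permutation_test(
    connectomes: list[WeightedConnectome],
    design: DesignMatrix,
    tail: str = "patient_lt",
    primary_threshold: float | None = None,
    p_threshold: float = 0.01,
    n_permutations: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
) -> NbsResult:
    """Max-component-size permutation inference on the supra-threshold graph."""
    if n_permutations < 100:
        warnings.warn(
            f"{n_permutations} permutations resolve corrected p no finer than "
            f"{1 / (n_permutations + 1):.3f}; results at alpha={alpha} are unreliable",
            stacklevel=2,
        )
    emap = edge_t_map(connectomes, design, tail, primary_threshold, p_threshold)
    observed = connected_component_sizes(emap.supra_adjacency)

    Y, n = _stack(connectomes)
    iu, ju = np.triu_indices(n, k=1)
    X = design.matrix.copy()
    gi = design.group_index
    thr = emap.primary_threshold
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_permutations, dtype=np.int64)
    supra = np.zeros((n, n), dtype=np.uint8)
    for b in range(n_permutations):
        perm = rng.permutation(design.n_subjects)
        Xp = X.copy()
        Xp[:, gi] = X[perm, gi]
        t = _edge_t(Y, Xp, gi)
        mask = t > thr if tail == "patient_gt" else t < -thr
        supra[:] = 0
        supra[iu[mask], ju[mask]] = 1
        supra |= supra.T
        null_max[b] = _max_component_size(supra)

    for comp in observed:
        comp.corrected_p = float(
            (1 + np.sum(null_max >= comp.size_in_edges)) / (1 + n_permutations)
        )
    return NbsResult(
        components=observed,
        null_max_sizes=null_max,
        n_permutations=n_permutations,
        seed=seed,
        tail=tail,
        primary_threshold=thr,
        edge_map=emap,
    )


def components_table(result: NbsResult, region_labels: list[str] | None = None) -> pd.DataFrame:
    """Edge-level table of the NBS components (one row per edge)."""
    rows = []
    for cid, comp in enumerate(result.components):
        for i, j in comp.edges:
            rows.append(
                {
                    "region1": region_labels[i] if region_labels else i,
                    "region2": region_labels[j] if region_labels else j,
                    "t": result.edge_map.t_matrix[i, j],
                    "component_id": cid,
                    "component_size_edges": comp.size_in_edges,
                    "corrected_p": comp.corrected_p,
                    "tail": result.tail,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "region1", "region2", "t", "component_id",
            "component_size_edges", "corrected_p", "tail",
        ],
    )


def write_significant_network(
    result: NbsResult,
    prefix: str | Path,
    region_labels: list[str],
    alpha: float = 0.05,
) -> tuple[Path, Path] | None:
    """BrainNet .node/.edge files of the significant supra-threshold network."""
    sig = result.significant
    if not sig:
        return None
    n = result.edge_map.t_matrix.shape[0]
    adj = np.zeros((n, n), dtype=np.uint8)
    for comp in sig:
        for i, j in comp.edges:
            adj[i, j] = adj[j, i] = 1
    net = BinaryNetwork(adj, sparsity=max(adj.sum() / (n * (n - 1)), 1e-9),
                        region_labels=region_labels)
    return write_brainnet(net, prefix)
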
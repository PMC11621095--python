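"""Global and nodal topology of binary brain networks.

Global metrics: clustering coefficient Cp, characteristic path length Lp,
global/local efficiency Eglob/Eloc, and the small-world ratios
gamma = Cp/Cp_rand, lambda = Lp/Lp_rand, sigma = gamma/lambda against
degree-preserving random null networks (Maslov-Sneppen double-edge swaps).
Nodal metrics: degree, nodal efficiency, betweenness, nodal local
efficiency. Metric curves over the sparsity sweep are summarised by their
area under the curve (AUC), the quantity entering group inference.

Conventions (stated because toolboxes differ):

* Cp, Eloc average over all N nodes; nodes with degree < 2 contribute 0.
* Lp is the mean hop distance over *connected* ordered pairs; fragmented
  networks (possible at the sparse end of the sweep) yield a warning with
  the component count instead of an infinite Lp.
* Eglob treats unreachable pairs as zero efficiency (1/inf = 0).
* Betweenness is unnormalised shortest-path betweenness with endpoints
  excluded; downstream group contrasts are unaffected by normalisation.

The inner loops (all-pairs BFS, per-neighbourhood efficiency, double-edge
swap null generation) are numba-compiled; null ensembles of 100-1000
rewired graphs per network are routine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _cc

from .connectome import BinaryNetwork, SparsityGrid

GLOBAL_METRICS = ("Cp", "Lp", "Eglob", "Eloc", "gamma", "lambda", "sigma")
NODAL_METRICS = (
    "degree",
    "nodal_efficiency",
    "betweenness",
    "nodal_local_efficiency",
)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _bfs_all(adj):
    """All-pairs unweighted shortest-path lengths; -1 marks unreachable."""
    n = adj.shape[0]
    dist = np.full((n, n), -1, dtype=np.int32)
    queue = np.empty(n, dtype=np.int32)
    for s in range(n):
        dist[s, s] = 0
        queue[0] = s
        head, tail = 0, 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[s, u]
            for v in range(n):
                if adj[u, v] != 0 and dist[s, v] < 0:
                    dist[s, v] = du + 1
                    queue[tail] = v
                    tail += 1
    return dist


@njit(cache=True)
def _cp_nodal(adj):
    """Per-node clustering coefficient 2 t_i / (k_i (k_i - 1))."""
    n = adj.shape[0]
    out = np.zeros(n)
    nb = np.empty(n, dtype=np.int32)
    for i in range(n):
        k = 0
        for j in range(n):
            if adj[i, j] != 0:
                nb[k] = j
                k += 1
        if k < 2:
            continue
        t = 0
        for p in range(k):
            for q in range(p + 1, k):
                if adj[nb[p], nb[q]] != 0:
                    t += 1
        out[i] = 2.0 * t / (k * (k - 1))
    return out


@njit(cache=True)
def _lp_and_eglob(adj):
    """(Lp over connected pairs, n unreachable ordered pairs, Eglob)."""
    n = adj.shape[0]
    dist = _bfs_all(adj)
    total = 0.0
    inv = 0.0
    cnt = 0
    miss = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = dist[i, j]
            if d > 0:
                total += d
                inv += 1.0 / d
                cnt += 1
            else:
                miss += 1
    lp = total / cnt if cnt > 0 else np.nan
    eglob = inv / (n * (n - 1)) if n > 1 else 0.0
    return lp, miss, eglob


@njit(cache=True)
def _eloc_nodal(adj):
    """Per-node local efficiency: Eglob of the neighbour-induced subgraph."""
    n = adj.shape[0]
    out = np.zeros(n)
    nb = np.empty(n, dtype=np.int32)
    for i in range(n):
        k = 0
        for j in range(n):
            if adj[i, j] != 0:
                nb[k] = j
                k += 1
        if k < 2:
            continue
        sub = np.zeros((k, k), dtype=np.uint8)
        for a in range(k):
            for b in range(k):
                sub[a, b] = adj[nb[a], nb[b]]
        d = _bfs_all(sub)
        tot = 0.0
        for a in range(k):
            for b in range(k):
                if a != b and d[a, b] > 0:
                    tot += 1.0 / d[a, b]
        out[i] = tot / (k * (k - 1))
    return out


@njit(cache=True)
def _betweenness(adj):
    """Brandes accumulation of unnormalised shortest-path betweenness."""
    n = adj.shape[0]
    bc = np.zeros(n)
    order = np.empty(n, dtype=np.int32)  # BFS visit order (acts as stack)
    dist = np.empty(n, dtype=np.int32)
    sigma = np.empty(n)
    delta = np.empty(n)
    # predecessor lists in flat storage
    pred = np.empty((n, n), dtype=np.int32)
    n_pred = np.empty(n, dtype=np.int32)
    for s in range(n):
        dist[:] = -1
        sigma[:] = 0.0
        n_pred[:] = 0
        dist[s] = 0
        sigma[s] = 1.0
        order[0] = s
        head, tail = 0, 1
        while head < tail:
            v = order[head]
            head += 1
            dv = dist[v]
            for w in range(n):
                if adj[v, w] == 0:
                    continue
                if dist[w] < 0:
                    dist[w] = dv + 1
                    order[tail] = w
                    tail += 1
                if dist[w] == dv + 1:
                    sigma[w] += sigma[v]
                    pred[w, n_pred[w]] = v
                    n_pred[w] += 1
        delta[:] = 0.0
        for idx in range(tail - 1, -1, -1):
            w = order[idx]
            coef = (1.0 + delta[w]) / sigma[w]
            for pi in range(n_pred[w]):
                v = pred[w, pi]
                delta[v] += sigma[v] * coef
            if w != s:
                bc[w] += delta[w]
    return bc / 2.0  # each undirected pair counted from both endpoints


@njit(cache=True)
def _edge_list(adj):
    n = adj.shape[0]
    m = 0
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j] != 0:
                m += 1
    edges = np.empty((m, 2), dtype=np.int32)
    e = 0
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j] != 0:
                edges[e, 0] = i
                edges[e, 1] = j
                e += 1
    return edges


@njit(cache=True)
def _rewire_inplace(adj, edges, nswap, max_tries):
    """Degree-preserving double-edge swaps; returns swaps performed.

    Each accepted swap replaces edges (u,v),(x,y) with (u,x),(v,y),
    rejecting proposals that would create self-loops or duplicate edges.
    Uses the numba global RNG; seed with np.random.seed beforehand.
    """
    m = edges.shape[0]
    done = 0
    tries = 0
    while done < nswap and tries < max_tries:
        tries += 1
        p = np.random.randint(m)
        q = np.random.randint(m)
        if p == q:
            continue
        u, v = edges[p, 0], edges[p, 1]
        x, y = edges[q, 0], edges[q, 1]
        if np.random.randint(2) == 1:
            x, y = y, x
        if u == x or u == y or v == x or v == y:
            continue
        if adj[u, x] != 0 or adj[v, y] != 0:
            continue
        adj[u, v] = 0
        adj[v, u] = 0
        adj[x, y] = 0
        adj[y, x] = 0
        adj[u, x] = 1
        adj[x, u] = 1
        adj[v, y] = 1
        adj[y, v] = 1
        edges[p, 0] = u
        edges[p, 1] = x
        edges[q, 0] = v
        edges[q, 1] = y
        done += 1
    return done


@njit(cache=True)
def _null_cp_lp(adj, n_nulls, swap_factor, seed):
    """Cp and Lp of ``n_nulls`` degree-matched rewired surrogates."""
    np.random.seed(seed)
    edges0 = _edge_list(adj)
    m = edges0.shape[0]
    nswap = swap_factor * m
    max_tries = 20 * nswap + 100
    cps = np.empty(n_nulls)
    lps = np.empty(n_nulls)
    for r in range(n_nulls):
        a = adj.copy()
        e = edges0.copy()
        _rewire_inplace(a, e, nswap, max_tries)
        cps[r] = _cp_nodal(a).mean()
        lp, _, _ = _lp_and_eglob(a)
        lps[r] = lp
    return cps, lps


# ---------------------------------------------------------------------------
# public metric API
# ---------------------------------------------------------------------------

@dataclass
class GlobalMetrics:
    Cp: float
    Lp: float
    Eglob: float
    Eloc: float
    gamma: float = np.nan
    lam: float = np.nan
    sigma: float = np.nan

    def as_dict(self) -> dict[str, float]:
        return {
            "Cp": self.Cp,
            "Lp": self.Lp,
            "Eglob": self.Eglob,
            "Eloc": self.Eloc,
            "gamma": self.gamma,
            "lambda": self.lam,
            "sigma": self.sigma,
        }


@dataclass
class NullEnsemble:
    n_nulls: int
    swap_factor: int
    seed: int
    cp_rand_mean: float
    lp_rand_mean: float
    cp_rand: np.ndarray | None = None
    lp_rand: np.ndarray | None = None


def _adj(g: BinaryNetwork | np.ndarray) -> np.ndarray:
    if isinstance(g, BinaryNetwork):
        return np.ascontiguousarray(g.adjacency, dtype=np.uint8)
    return np.ascontiguousarray(np.asarray(g), dtype=np.uint8)


def clustering_coefficient(g: BinaryNetwork) -> tuple[np.ndarray, float]:
    """(per-node clustering, network mean Cp averaged over all nodes)."""
    ci = _cp_nodal(_adj(g))
    return ci, float(ci.mean())


def shortest_path_lengths(g: BinaryNetwork) -> np.ndarray:
    """Pairwise hop distances; unreachable pairs are infinite."""
    d = _bfs_all(_adj(g)).astype(float)
    d[d < 0] = np.inf
    return d


def n_components(g: BinaryNetwork) -> int:
    return int(_cc(csr_matrix(_adj(g)), directed=False, return_labels=False))


def characteristic_path_length(g: BinaryNetwork) -> float:
    """Mean hop distance over connected ordered pairs; warns when the
    network is fragmented."""
    a = _adj(g)
    if a.sum() == 0:
        raise ValueError("characteristic path length undefined for an empty graph")
    lp, miss, _ = _lp_and_eglob(a)
    if miss > 0:
        warnings.warn(
            f"network is fragmented ({n_components(g)} components); Lp "
            "averaged over connected pairs only",
            stacklevel=2,
        )
    return float(lp)


def nodal_efficiency(g: BinaryNetwork) -> np.ndarray:
    """e_i = mean over j != i of 1/d_ij (1/inf = 0)."""
    d = shortest_path_lengths(g)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[np.isinf(d)] = 0.0
    return inv.sum(axis=1) / (d.shape[0] - 1)


def global_efficiency(g: BinaryNetwork) -> float:
    """Mean inverse shortest-path length over all ordered pairs."""
    _, _, eglob = _lp_and_eglob(_adj(g))
    return float(eglob)


def local_efficiency(g: BinaryNetwork) -> tuple[np.ndarray, float]:
    """(per-node local efficiency, network mean Eloc)."""
    ei = _eloc_nodal(_adj(g))
    return ei, float(ei.mean())


def betweenness(g: BinaryNetwork) -> np.ndarray:
    """Unnormalised shortest-path betweenness (endpoints excluded)."""
    return _betweenness(_adj(g))


def degree_preserving_nulls(
    g: BinaryNetwork,
    n_nulls: int = 1000,
    swap_factor: int = 10,
    seed: int = 0,
    keep_samples: bool = False,
) -> NullEnsemble:
    """Cp/Lp reference values from degree-matched rewired surrogates."""
    a = _adj(g)
    m = int(a.sum()) // 2
    if m < 2:
        raise ValueError("need at least 2 edges to rewire")
    n = a.shape[0]
    if m == n * (n - 1) // 2:
        warnings.warn(
            "complete graph admits no degree-preserving swap; null ensemble "
            "equals the observed network",
            stacklevel=2,
        )
        _, cp = clustering_coefficient(g)
        lp = characteristic_path_length(g)
        cps = np.full(n_nulls, cp)
        lps = np.full(n_nulls, lp)
    else:
        cps, lps = _null_cp_lp(a, n_nulls, swap_factor, seed % (2**31 - 1))
    return NullEnsemble(
        n_nulls=n_nulls,
        swap_factor=swap_factor,
        seed=seed,
        cp_rand_mean=float(cps.mean()),
        lp_rand_mean=float(np.nanmean(lps)),
        cp_rand=cps if keep_samples else None,
        lp_rand=lps if keep_samples else None,
    )


def randomize_preserving_degrees(
    g: BinaryNetwork, swap_factor: int = 10, seed: int = 0
) -> BinaryNetwork:
    """One degree-matched rewired surrogate of ``g``."""
    a = _adj(g).copy()
    edges = _edge_list(a)
    np.random.seed(seed % (2**31 - 1))
    _rewire_inplace(a, edges, swap_factor * edges.shape[0], 20 * swap_factor * edges.shape[0] + 100)
    return BinaryNetwork(a, g.sparsity, g.region_labels)


def small_world(g: BinaryNetwork, nulls: NullEnsemble) -> tuple[float, float, float]:
    """gamma = Cp/Cp_rand, lambda = Lp/Lp_rand, sigma = gamma/lambda."""
    _, cp = clustering_coefficient(g)
    lp = characteristic_path_length(g)
    if nulls.cp_rand_mean == 0:
        raise ValueError("null ensemble has zero mean clustering")
    gamma = cp / nulls.cp_rand_mean
    lam = lp / nulls.lp_rand_mean
    return float(gamma), float(lam), float(gamma / lam)


def global_metrics(
    g: BinaryNetwork,
    n_nulls: int = 100,
    swap_factor: int = 10,
    seed: int = 0,
) -> GlobalMetrics:
    """All seven global metrics of one network (nulls for gamma/lambda/sigma)."""
    a = _adj(g)
    if a.sum() == 0:
        raise ValueError("metrics undefined for an empty graph")
    cp = float(_cp_nodal(a).mean())
    lp, miss, eglob = _lp_and_eglob(a)
    if miss > 0:
        warnings.warn(
            f"network is fragmented ({n_components(g)} components); Lp "
            "averaged over connected pairs only",
            stacklevel=2,
        )
    eloc = float(_eloc_nodal(a).mean())
    nulls = degree_preserving_nulls(g, n_nulls=n_nulls, swap_factor=swap_factor, seed=seed)
    if nulls.cp_rand_mean == 0:
        raise ValueError("null ensemble has zero mean clustering")
    gamma = cp / nulls.cp_rand_mean
    lam = float(lp) / nulls.lp_rand_mean
    return GlobalMetrics(cp, float(lp), float(eglob), eloc, float(gamma),
                         float(lam), float(gamma / lam))


def nodal_metrics(g: BinaryNetwork) -> pd.DataFrame:
    """Degree, nodal efficiency, betweenness and nodal local efficiency."""
    eloc_i, _ = local_efficiency(g)
    return pd.DataFrame(
        {
            "node": g.region_labels or list(range(g.n_nodes)),
            "degree": g.degrees,
            "nodal_efficiency": nodal_efficiency(g),
            "betweenness": betweenness(g),
            "nodal_local_efficiency": eloc_i,
        }
    )


# ---------------------------------------------------------------------------
# AUC over the sparsity sweep
# ---------------------------------------------------------------------------

def auc(values: np.ndarray, grid: SparsityGrid | np.ndarray) -> float:
    """Trapezoidal integral of a metric curve over the sparsity grid."""
    xs = grid.values if isinstance(grid, SparsityGrid) else np.asarray(grid)
    ys = np.asarray(values, dtype=float)
    if ys.shape != xs.shape:
        raise ValueError(f"{ys.shape[0]} values for {xs.shape[0]} grid points")
    if not np.all(np.isfinite(ys)):
        raise ValueError("metric curve contains non-finite values")
    return float(np.trapezoid(ys, xs))


def subject_metric_table(
    subject_id: str,
    networks: list[BinaryNetwork],
    grid: SparsityGrid,
    n_nulls: int = 100,
    swap_factor: int = 10,
    seed: int = 0,
    include_nodal: bool = True,
    include_small_world: bool = True,
) -> pd.DataFrame:
    """Long-format metric table over the sweep: one row per
    (sparsity, metric, node), node == 'global' for network-level metrics."""
    if len(networks) != len(grid):
        raise ValueError("one network per grid sparsity required")
    sparsities: list[float] = []
    names: list[str] = []
    nodes: list[str] = []
    values: list[float] = []

    def emit(s: float, name: str, node: str, value: float) -> None:
        sparsities.append(s)
        names.append(name)
        nodes.append(node)
        values.append(value)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # fragmentation warnings at sparse end
        for k, (s, g) in enumerate(zip(grid.values, networks)):
            s = float(s)
            if include_small_world:
                gm = global_metrics(g, n_nulls=n_nulls, swap_factor=swap_factor,
                                    seed=seed + 1000 * k)
            else:
                _, cp = clustering_coefficient(g)
                gm = GlobalMetrics(
                    cp,
                    characteristic_path_length(g),
                    global_efficiency(g),
                    local_efficiency(g)[1],
                )
            for name, val in gm.as_dict().items():
                if not include_small_world and name in ("gamma", "lambda", "sigma"):
                    continue
                emit(s, name, "global", val)
            if include_nodal:
                labels = [str(x) for x in (g.region_labels or range(g.n_nodes))]
                eloc_i, _ = local_efficiency(g)
                for metric, vec in (
                    ("degree", g.degrees),
                    ("nodal_efficiency", nodal_efficiency(g)),
                    ("betweenness", betweenness(g)),
                    ("nodal_local_efficiency", eloc_i),
                ):
                    for node, val in zip(labels, vec):
                        emit(s, metric, node, float(val))
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "sparsity": sparsities,
            "metric_name": names,
            "node": nodes,
            "value": values,
        }
    )


def auc_table(metric_table: pd.DataFrame, grid: SparsityGrid) -> pd.DataFrame:
    """Per-subject AUC of every metric curve in a long metric table."""
    xs = grid.values
    rows = []
    for (sid, metric, node), sub in metric_table.groupby(
        ["subject_id", "metric_name", "node"], sort=False
    ):
        sub = sub.sort_values("sparsity")
        if len(sub) != len(xs) or not np.allclose(sub["sparsity"].values, xs):
            raise ValueError(
                f"metric {metric}/{node} of {sid} does not cover the grid"
            )
        rows.append(
            {"subject_id": sid, "metric_name": metric, "node": node,
             "auc": auc(sub["value"].values, xs)}
        )
    return pd.DataFrame(rows)
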
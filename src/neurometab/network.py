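"""Voxel x metabolite association network: cutoff rule, communities,
centrality, and the cluster summary table.

The association matrix defaults to Pearson correlation with analytic
two-sided p-values; a sparse-PLS mode (soft-thresholded singular-vector
reconstruction rescaled to [-1, 1]) is provided for fidelity to
xMWAS-style integration. The edge cutoff follows the weakest-correlation
rule: the largest threshold at which every voxel retains at least one
metabolite link. Communities come from multilevel (Louvain) modularity
maximization on |r|-weighted edges via igraph; eigenvector centrality is the
principal eigenvector of the weighted adjacency, normalized to max 1 per
connected component.
"""

from __future__ import annotations

import random as _random
import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    EmptyNetworkError,
    InputError,
)


@dataclass
class AssociationMatrix:
    r: np.ndarray                 # (n_voxels, n_metabolites)
    p: np.ndarray
    n: int
    voxel_ids: list[str]
    metabolite_ids: list[str]
    constant_flags: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))


@dataclass
class BipartiteNetwork:
    edges: pd.DataFrame           # voxel, metabolite, r, p, sign
    cutoff: float
    alpha: float

    @property
    def voxels(self) -> list[str]:
        return sorted(self.edges["voxel"].unique())

    @property
    def metabolites(self) -> list[str]:
        return sorted(self.edges["metabolite"].unique())

    def graph(self) -> ig.Graph:
        nodes = self.voxels + self.metabolites
        index = {v: i for i, v in enumerate(nodes)}
        g = ig.Graph(
            n=len(nodes),
            edges=[
                (index[v], index[m])
                for v, m in zip(self.edges["voxel"], self.edges["metabolite"])
            ],
        )
        g.vs["name"] = nodes
        g.vs["type"] = ["voxel"] * len(self.voxels) + ["metabolite"] * len(
            self.metabolites
        )
        g.es["weight"] = np.abs(self.edges["r"].to_numpy()).tolist()
        g.es["r"] = self.edges["r"].to_numpy().tolist()
        g.es["sign"] = self.edges["sign"].to_numpy().tolist()
        return g


@dataclass
class CommunitySet:
    membership: pd.Series         # node name -> community id
    modularity: float
    edges: pd.DataFrame
    node_types: pd.Series

    def nodes_in(self, community: int) -> list[str]:
        return list(self.membership.index[self.membership == community])

    @property
    def communities(self) -> list[int]:
        return sorted(self.membership.unique())


def _soft_threshold(v: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold so that at most `keep` entries stay non-zero."""
    if keep >= v.size:
        return v.copy()
    lam = np.sort(np.abs(v))[-(keep + 1)]
    return np.sign(v) * np.maximum(np.abs(v) - lam, 0.0)


def compute_association_matrix(
    X: np.ndarray,
    M: np.ndarray,
    mode: str = "pearson",
    voxel_ids: list[str] | None = None,
    metabolite_ids: list[str] | None = None,
    n_components: int = 3,
    keep_frac: float = 0.3,
) -> AssociationMatrix:
    """Pairwise voxel-metabolite association with two-sided p-values.

    ``pearson``: plain correlation, p from t = r sqrt(n-2)/sqrt(1-r^2).
    ``spls``: association reconstructed from soft-thresholded singular-vector
    pairs of the cross-covariance of the standardized blocks, rescaled to
    [-1, 1]; p-values are computed from the Pearson correlations (the sparse
    reconstruction is a score, not a sampling distribution).
    """
    X = np.asarray(X, dtype=float)
    M = np.asarray(M, dtype=float)
    if X.shape[0] != M.shape[0]:
        raise InputError("X and M must share subjects (rows)")
    n = X.shape[0]
    if n < 4:
        raise InputError("need at least 4 subjects")
    if mode not in ("pearson", "spls"):
        raise ConfigurationError(f"unknown association mode {mode!r}")

    def _standardize_block(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        sd = A.std(axis=0, ddof=1)
        const = np.flatnonzero(sd == 0)
        sd_safe = np.where(sd == 0, 1.0, sd)
        Z = (A - A.mean(axis=0)) / sd_safe
        return Z, const

    Zx, const_x = _standardize_block(X)
    Zm, const_m = _standardize_block(M)
    r = (Zx.T @ Zm) / (n - 1)
    r = np.clip(r, -1.0, 1.0)
    r[const_x, :] = 0.0
    r[:, const_m] = 0.0
    if const_x.size or const_m.size:
        warnings.warn(
            f"{const_x.size} voxel and {const_m.size} metabolite columns are "
            "constant; their correlations were set to 0",
            stacklevel=2,
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p[const_x, :] = 1.0
    p[:, const_m] = 1.0

    if mode == "spls":
        C = (Zx.T @ Zm) / (n - 1)
        A = np.zeros_like(C)
        keep_x = max(1, int(round(keep_frac * C.shape[0])))
        keep_m = max(1, int(round(keep_frac * C.shape[1])))
        R = C.copy()
        for _ in range(min(n_components, min(C.shape) - 1) or 1):
            u, s, vt = np.linalg.svd(R, full_matrices=False)
            uu = _soft_threshold(u[:, 0], keep_x)
            vv = _soft_threshold(vt[0], keep_m)
            if np.linalg.norm(uu) == 0 or np.linalg.norm(vv) == 0:
                break
            uu /= np.linalg.norm(uu)
            vv /= np.linalg.norm(vv)
            sigma = float(uu @ R @ vv)
            A += sigma * np.outer(uu, vv)
            R = R - sigma * np.outer(uu, vv)
        peak = np.abs(A).max()
        if peak > 0:
            A = A / peak * np.abs(r).max()
        r = np.clip(A, -1.0, 1.0)

    voxel_ids = voxel_ids or [f"V{i}" for i in range(X.shape[1])]
    metabolite_ids = metabolite_ids or [f"F{j}" for j in range(M.shape[1])]
    return AssociationMatrix(
        r=r, p=p, n=n, voxel_ids=list(voxel_ids), metabolite_ids=list(metabolite_ids),
        constant_flags=const_x,
    )


def select_cutoff(assoc: AssociationMatrix, alpha: float = 0.05) -> float:
    """Weakest correlation keeping every voxel linked to >= 1 metabolite.

    cutoff = min over voxels of (max over metabolites of |r| restricted to
    p < alpha). At this threshold every voxel keeps at least one edge; any
    strictly larger threshold orphans the defining voxel. Voxels with no
    pair passing alpha are reported and excluded from the minimum.
    """
    absr = np.abs(assoc.r)
    ok = assoc.p < alpha
    row_max = np.where(ok, absr, -np.inf).max(axis=1)
    dead = ~np.isfinite(row_max)
    if dead.all():
        raise DegenerateInputError("no voxel has any pair passing alpha")
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} voxels have no metabolite passing alpha; "
            "cutoff computed over the remaining voxels",
            stacklevel=2,
        )
    return float(row_max[~dead].min())


def build_network(
    assoc: AssociationMatrix, cutoff: float, alpha: float = 0.05
) -> BipartiteNetwork:
    """Bipartite edges: exactly the pairs with |r| >= cutoff and p < alpha."""
    if not (0.0 < cutoff <= 1.0):
        raise ConfigurationError("cutoff must lie in (0, 1]")
    keep = (np.abs(assoc.r) >= cutoff) & (assoc.p < alpha)
    vi, mi = np.nonzero(keep)
    if vi.size == 0:
        raise EmptyNetworkError("no voxel-metabolite pair passes the edge criteria")
    r = assoc.r[vi, mi]
    edges = pd.DataFrame(
        {
            "voxel": [assoc.voxel_ids[i] for i in vi],
            "metabolite": [assoc.metabolite_ids[j] for j in mi],
            "r": r,
            "p": assoc.p[vi, mi],
            "sign": np.sign(r).astype(int),
        }
    )
    return BipartiteNetwork(edges=edges, cutoff=cutoff, alpha=alpha)


def detect_communities(net: BipartiteNetwork, seed: int = 0) -> CommunitySet:
    """Multilevel (Louvain) modularity communities on |r|-weighted edges."""
    g = net.graph()
    state = _random.getstate()
    try:
        _random.seed(seed)
        ig.set_random_number_generator(_random)
        clustering = g.community_multilevel(weights="weight")
    finally:
        ig.set_random_number_generator(_random)
        _random.setstate(state)
    membership = pd.Series(
        clustering.membership, index=pd.Index(g.vs["name"], name="node"), name="community"
    )
    q = g.modularity(clustering.membership, weights="weight")
    node_types = pd.Series(g.vs["type"], index=membership.index, name="type")
    return CommunitySet(
        membership=membership,
        modularity=float(q),
        edges=net.edges,
        node_types=node_types,
    )


def modularity_score(
    edges: pd.DataFrame, membership: dict[str, int]
) -> float:
    """Weighted Newman modularity of an arbitrary partition (used by the
    exhaustive oracle tests as an independent scoring path)."""
    w = np.abs(edges["r"].to_numpy())
    total = w.sum()
    deg: dict[str, float] = {}
    for (u, v, wi) in zip(edges["voxel"], edges["metabolite"], w):
        deg[u] = deg.get(u, 0.0) + wi
        deg[v] = deg.get(v, 0.0) + wi
    q = 0.0
    for (u, v, wi) in zip(edges["voxel"], edges["metabolite"], w):
        if membership[u] == membership[v]:
            q += wi / total
    for u, du in deg.items():
        for v, dv in deg.items():
            if membership[u] == membership[v]:
                q -= du * dv / (2 * total) ** 2
    return q


def compute_centrality(net: BipartiteNetwork) -> pd.Series:
    """Eigenvector centrality of the |r|-weighted adjacency.

    Computed per connected component from the principal eigenvector
    (Perron vector) and normalized so the maximum within each component is 1.
    """
    g = net.graph()
    names = g.vs["name"]
    scores = np.zeros(g.vcount())
    for comp in g.connected_components():
        idx = np.array(comp)
        if idx.size == 1:
            scores[idx] = 1.0
            continue
        sub = g.subgraph(comp)
        A = np.zeros((idx.size, idx.size))
        for e in sub.es:
            A[e.source, e.target] = e["weight"]
            A[e.target, e.source] = e["weight"]
        vals, vecs = np.linalg.eigh(A)
        v = np.abs(vecs[:, np.argmax(vals)])
        scores[idx] = v / v.max()
    return pd.Series(scores, index=pd.Index(names, name="node"), name="centrality")


def summarize_clusters(
    communities: CommunitySet, mode: str = "edge_linked"
) -> pd.DataFrame:
    """Per-community voxel and metabolite counts plus a totals row.

    ``edge_linked`` counts a metabolite in every community containing at
    least one of its voxel partners (so the metabolite total can exceed the
    number of distinct metabolites); ``partition`` counts hard membership.
    """
    if mode not in ("edge_linked", "partition"):
        raise ConfigurationError(f"unknown counting mode {mode!r}")
    memb, types = communities.membership, communities.node_types
    rows = []
    voxel_comm = memb[types == "voxel"]
    for c in communities.communities:
        n_vox = int((voxel_comm == c).sum())
        if mode == "partition":
            n_met = int(((memb == c) & (types == "metabolite")).sum())
        else:
            vox_in_c = set(memb.index[(memb == c) & (types == "voxel")])
            sub = communities.edges[communities.edges["voxel"].isin(vox_in_c)]
            n_met = int(sub["metabolite"].nunique())
        rows.append((c, n_vox, n_met))
    out = pd.DataFrame(rows, columns=["community", "n_voxels", "n_metabolites"])
    total = pd.DataFrame(
        [("total", out["n_voxels"].sum(), out["n_metabolites"].sum())],
        columns=out.columns,
    )
    return pd.concat([out, total], ignore_index=True)


def export_graphml(
    net: BipartiteNetwork,
    communities: CommunitySet | None = None,
    centrality: pd.Series | None = None,
    path: str | None = None,
) -> ig.Graph:
    g = net.graph()
    if communities is not None:
        g.vs["community"] = [int(communities.membership[v]) for v in g.vs["name"]]
    if centrality is not None:
        g.vs["centrality"] = [float(centrality[v]) for v in g.vs["name"]]
    if path is not None:
        g.write_graphml(path)
    return g
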
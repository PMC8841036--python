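"""Co-occurrence networks: abundance/occurrence filtering, Spearman
correlation with FDR control, signed thresholded graphs, topology metrics,
modularity-based module detection, and Zi-Pi module-role classification.

An edge is kept when |rho| >= rho_min (default 0.8) and the BH-adjusted
P <= q_max (default 0.001); its sign is the sign of rho. Node roles follow
the within-module degree z-score (Zi) vs participation coefficient (Pi)
convention: module hubs (Zi > 2.5), connectors (Pi > 0.62), network hubs
(both), else peripheral; any non-peripheral node is a keystone candidate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountTable, SampleMetadata, ValidationError, relative_abundance


@dataclass
class NodeTopology:
    asv_id: str
    degree: int
    module: int
    zi: float
    pi: float
    role: str  # peripheral | connector | module hub | network hub

    @property
    def keystone(self) -> bool:
        return self.role != "peripheral"


@dataclass
class NetworkMetrics:
    n_nodes: int
    n_edges: int
    n_positive: int
    n_negative: int
    average_degree: float
    connectance: float
    largest_component_fraction: float
    modularity: float
    n_modules: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def filter_for_network(table: CountTable, abundance_threshold: float = 5e-3,
                       occurrence_threshold: float = 0.5,
                       sample_ids=None) -> CountTable:
    """Keep ASVs above the abundance threshold (dataset-subset relative
    abundance, strict >) present in strictly more than the occurrence
    fraction of subset samples."""
    if sample_ids is not None:
        sample_ids = list(sample_ids)
        if not sample_ids:
            raise ValidationError("empty sample subset for network filtering")
        table = table.subset_samples(sample_ids)
    frac = relative_abundance(table, basis="dataset_total").to_numpy()
    occ = (table.counts > 0).mean(axis=0)
    pass_ab = frac > abundance_threshold
    pass_occ = occ > occurrence_threshold
    keep = pass_ab & pass_occ
    if not keep.any():
        raise ValidationError(
            f"no ASVs survive network filtering "
            f"({int(pass_ab.sum())} pass abundance > {abundance_threshold}, "
            f"{int(pass_occ.sum())} pass occurrence > {occurrence_threshold})")
    return table.subset_asvs([a for a, k in zip(table.asv_ids, keep) if k])


def spearman_matrix(table: CountTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rho and two-sided p (t-approximation, n-2 df).

    Ties get average ranks. ASVs constant across samples have undefined
    correlations: their off-diagonal p entries are NaN (they can never pass
    the edge gates).
    """
    if table.n_samples < 4:
        raise ValidationError("spearman_matrix requires >= 4 samples")
    if table.n_asvs < 2:
        raise ValidationError("spearman_matrix requires >= 2 ASVs")
    X = table.counts.astype(float)
    with warnings.catch_warnings():
        # constant ASVs are handled explicitly below
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho, p = stats.spearmanr(X, axis=0)
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        p = np.array([[0.0, float(p)], [float(p), 0.0]])
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    const = X.std(axis=0) == 0
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    p[const, :] = np.nan
    p[:, const] = np.nan
    np.fill_diagonal(rho, 1.0)
    ids = table.asv_ids
    return (pd.DataFrame(rho, index=ids, columns=ids),
            pd.DataFrame(p, index=ids, columns=ids))


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def build_network(rho: pd.DataFrame, q: pd.DataFrame, rho_min: float = 0.8,
                  q_max: float = 0.001,
                  node_abundance: pd.Series | None = None) -> nx.Graph:
    """Signed thresholded graph: edge iff |rho| >= rho_min and q <= q_max.

    Isolated nodes are excluded; node attribute ``abundance`` carries the
    dataset relative abundance when provided.
    """
    if rho.shape != q.shape or list(rho.index) != list(q.index):
        raise ValidationError("rho and q matrices are not conformable")
    ids = list(rho.index)
    r = rho.to_numpy()
    qv = q.to_numpy()
    g = nx.Graph()
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if np.isnan(r[i, j]) or np.isnan(qv[i, j]):
                continue
            if abs(r[i, j]) >= rho_min and qv[i, j] <= q_max:
                g.add_edge(ids[i], ids[j], rho=float(r[i, j]), q=float(qv[i, j]),
                           sign=1 if r[i, j] > 0 else -1)
    if node_abundance is not None:
        for node in g.nodes:
            g.nodes[node]["abundance"] = float(node_abundance.get(node, np.nan))
    return g


def adjusted_p_matrix(p: pd.DataFrame) -> pd.DataFrame:
    """BH adjustment over the strictly-upper-triangle tests, mirrored back."""
    ids = list(p.index)
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    flat = p.to_numpy()[iu]
    qflat = fdr_bh(flat)
    q = np.zeros((n, n))
    q[iu] = qflat
    q = q + q.T
    return pd.DataFrame(q, index=ids, columns=ids)


def detect_modules(net: nx.Graph, seed: int = 0) -> tuple[dict[str, int], float]:
    """Greedy modularity maximization on the unweighted, unsigned graph.

    The CNM greedy algorithm is deterministic; ``seed`` is accepted for
    interface stability. Returns (node -> module id, modularity Q).
    """
    if net.number_of_nodes() == 0:
        raise ValidationError("empty network")
    communities = nx.algorithms.community.greedy_modularity_communities(net)
    communities = sorted((sorted(c) for c in communities),
                         key=lambda c: (-len(c), c[0]))
    modules = {node: m for m, comm in enumerate(communities) for node in comm}
    q = nx.algorithms.community.modularity(net, communities)
    return modules, float(q)


def network_metrics(net: nx.Graph, modules: dict[str, int] | None = None,
                    modularity: float | None = None,
                    seed: int = 0) -> NetworkMetrics:
    if net.number_of_nodes() == 0:
        raise ValidationError("empty network")
    if modules is None or modularity is None:
        modules, modularity = detect_modules(net, seed)
    n = net.number_of_nodes()
    e = net.number_of_edges()
    signs = [d.get("sign", 1) for _, _, d in net.edges(data=True)]
    n_pos = sum(1 for s in signs if s > 0)
    comp = max(nx.connected_components(net), key=len)
    return NetworkMetrics(
        n_nodes=n, n_edges=e, n_positive=n_pos, n_negative=e - n_pos,
        average_degree=2.0 * e / n,
        connectance=2.0 * e / (n * (n - 1)) if n > 1 else 0.0,
        largest_component_fraction=len(comp) / n,
        modularity=float(modularity),
        n_modules=len(set(modules.values())))


def zi_pi(net: nx.Graph, modules: dict[str, int], zi_threshold: float = 2.5,
          pi_threshold: float = 0.62) -> list[NodeTopology]:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    Zi standardizes a node's within-module degree against its module's
    mean and sd; it is set to 0 when the sd is 0 or the module has fewer
    than 3 nodes. Pi = 1 - sum_t (k_it / k_i)^2 over modules t.
    """
    missing = [v for v in net.nodes if v not in modules]
    if missing:
        raise ValidationError(f"nodes missing module assignment: {missing[:5]}")
    within = {}
    for node in net.nodes:
        m = modules[node]
        within[node] = sum(1 for nb in net.neighbors(node) if modules[nb] == m)
    module_nodes: dict[int, list] = {}
    for node in net.nodes:
        module_nodes.setdefault(modules[node], []).append(node)
    mod_stats = {}
    for m, nodes in module_nodes.items():
        vals = np.array([within[v] for v in nodes], dtype=float)
        mod_stats[m] = (vals.mean(), vals.std(ddof=0), len(nodes))

    out = []
    for node in net.nodes:
        k = net.degree(node)
        m = modules[node]
        mean_w, sd_w, size = mod_stats[m]
        zi = 0.0 if (sd_w == 0 or size < 3) else (within[node] - mean_w) / sd_w
        per_module: dict[int, int] = {}
        for nb in net.neighbors(node):
            per_module[modules[nb]] = per_module.get(modules[nb], 0) + 1
        pi = 1.0 - sum((kt / k) ** 2 for kt in per_module.values()) if k > 0 else 0.0
        hub = zi > zi_threshold
        conn = pi > pi_threshold
        role = ("network hub" if hub and conn else "module hub" if hub
                else "connector" if conn else "peripheral")
        out.append(NodeTopology(node, int(k), int(m), float(zi), float(pi), role))
    return out


def topology_frame(records: list[NodeTopology]) -> pd.DataFrame:
    return pd.DataFrame(
        {"degree": [r.degree for r in records],
         "module": [r.module for r in records],
         "Zi": [r.zi for r in records],
         "Pi": [r.pi for r in records],
         "role": [r.role for r in records],
         "keystone": [r.keystone for r in records]},
        index=pd.Index([r.asv_id for r in records], name="asv_id"))


def compare_networks(nets: dict[str, nx.Graph]) -> dict[str, int]:
    """Shared-node counts for every pair and the full intersection."""
    if len(nets) < 2:
        raise ValidationError("compare_networks requires >= 2 networks")
    names = list(nets)
    sets = {k: set(v.nodes) for k, v in nets.items()}
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            out[f"{a}&{b}"] = len(sets[a] & sets[b])
    out["&".join(names)] = len(set.intersection(*sets.values()))
    return out


def build_cooccurrence_network(table: CountTable, metadata: SampleMetadata | None = None,
                               layer: str | None = None,
                               abundance_threshold: float = 5e-3,
                               occurrence_threshold: float = 0.5,
                               rho_min: float = 0.8, q_max: float = 0.001,
                               use_raw_p: bool = False) -> nx.Graph:
    """Full network stage: subset -> filter -> Spearman -> FDR -> threshold."""
    sample_ids = None
    if layer is not None:
        if metadata is None:
            raise ValidationError("layer subsetting requires metadata")
        sample_ids = [s for s in table.sample_ids
                      if s in set(metadata.samples_in_layer(layer))]
    filtered = filter_for_network(table, abundance_threshold,
                                  occurrence_threshold, sample_ids)
    rho, p = spearman_matrix(filtered)
    q = p if use_raw_p else adjusted_p_matrix(p)
    abund = relative_abundance(filtered, basis="dataset_total")
    return build_network(rho, q, rho_min, q_max, node_abundance=abund)
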
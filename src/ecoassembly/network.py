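"""Thresholded Spearman co-occurrence networks and their topology.

OTUs passing a prevalence filter (present in at least two-thirds of samples
by default) are correlated all-against-all with Spearman rank correlation;
pairs that are both strong (|r| > 0.8) and significant (p < 0.01) become
signed edges. Topology follows the usual co-occurrence summaries: average
degree, average clustering coefficient, average path distance on the largest
connected component, graph density, and modularity from repeated stochastic
community detection (mean +/- sd over restarts).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .io import DegenerateInputError, OtuTable

logger = logging.getLogger("ecoassembly")

__all__ = [
    "CooccurrenceNetwork",
    "prevalence_filter",
    "build_network",
    "topology",
    "annotate_nodes",
]


@dataclass
class CooccurrenceNetwork:
    """Signed weighted OTU co-occurrence graph with thresholds recorded."""

    graph: nx.Graph
    r_min: float
    p_max: float
    correction: str = "none"
    topology_summary: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_sign_fractions(self) -> dict[str, float]:
        e = self.n_edges
        if e == 0:
            return {"positive": float("nan"), "negative": float("nan")}
        pos = sum(1 for *_, d in self.graph.edges(data=True) if d["sign"] == "positive")
        return {"positive": pos / e, "negative": (e - pos) / e}

    def to_dict(self) -> dict:
        return {
            "r_min": self.r_min,
            "p_max": self.p_max,
            "correction": self.correction,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "edge_sign_fractions": self.edge_sign_fractions(),
            "topology": self.topology_summary,
        }


def prevalence_filter(table: OtuTable, min_fraction: float = 2 / 3) -> OtuTable:
    """Keep OTUs present (nonzero) in at least ceil(min_fraction * n) samples."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must lie in (0, 1]")
    need = math.ceil(min_fraction * table.n_samples)
    present = (table.counts > 0).sum(axis=0)
    keep = list(present.index[present >= need])
    if not keep:
        raise DegenerateInputError(
            f"no OTU present in >= {need} of {table.n_samples} samples"
        )
    return table.subset(otu_ids=keep)


def build_network(
    table: OtuTable,
    r_min: float = 0.8,
    p_max: float = 0.01,
    correction: str = "none",
    use_relative_abundance: bool = False,
) -> CooccurrenceNetwork:
    """All-pairs Spearman correlation thresholded into a signed graph.

    Edges require |r| > ``r_min`` AND p < ``p_max`` (strict inequalities);
    ``correction='bh'`` applies Benjamini-Hochberg to the pairwise p-values
    first. Zero-variance OTUs are excluded before correlation; OTUs left
    without any edge do not appear as nodes. Ranks are depth-invariant, so
    counts and proportions differ only when sequencing depths differ.
    """
    if table.n_samples < 4:
        raise ValueError("Spearman p-values need at least 4 samples")
    data = table.counts.astype(float)
    if use_relative_abundance:
        data = data.div(data.sum(axis=1), axis=0)
    variances = data.var(axis=0)
    dropped = list(variances.index[variances == 0])
    if dropped:
        warnings.warn(
            f"excluding {len(dropped)} zero-variance OTU(s) before correlation",
            stacklevel=2,
        )
        data = data.drop(columns=dropped)
    otus = list(data.columns)
    if len(otus) < 2:
        raise DegenerateInputError("fewer than 2 OTUs with variance; no network")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, pval = stats.spearmanr(data.to_numpy())
    if np.ndim(rho) == 0:  # scipy collapses the 2-variable case to scalars
        rho = np.array([[1.0, rho], [rho, 1.0]])
        pval = np.array([[0.0, pval], [pval, 0.0]])
    iu = np.triu_indices(len(otus), k=1)
    p_flat = pval[iu]
    if correction == "bh":
        from statsmodels.stats.multitest import multipletests

        p_flat = multipletests(p_flat, method="fdr_bh")[1]
    elif correction != "none":
        raise ValueError(f"unknown correction: {correction!r}")
    g = nx.Graph()
    for (i, j), p in zip(zip(*iu), p_flat):
        r = rho[i, j]
        if abs(r) > r_min and p < p_max:
            g.add_edge(
                otus[i],
                otus[j],
                r=float(r),
                p=float(p),
                sign="positive" if r > 0 else "negative",
                weight=float(abs(r)),
            )
    return CooccurrenceNetwork(graph=g, r_min=r_min, p_max=p_max, correction=correction)


def topology(
    net: CooccurrenceNetwork,
    n_modularity_restarts: int = 20,
    seed: int | None = None,
) -> dict:
    """Topology summary: AD, ACC, APD, GD, modularity mean +/- sd.

    * AD = 2E/V; GD = 2E/(V(V-1)).
    * ACC = mean local clustering coefficient (degree < 2 contributes 0).
    * APD = mean shortest-path length on the largest connected component
      (unweighted); the component's coverage of the node set is reported.
    * Modularity: Louvain community detection on the unweighted graph,
      repeated with distinct seeds; the best partition's module labels are
      stored on the nodes.
    """
    g = net.graph
    v, e = g.number_of_nodes(), g.number_of_edges()
    if e == 0:
        raise ValueError("topology of an empty network is undefined")
    ad = 2 * e / v
    acc = nx.average_clustering(g)
    gd = 2 * e / (v * (v - 1)) if v > 1 else float("nan")
    components = sorted(nx.connected_components(g), key=len, reverse=True)
    giant = g.subgraph(components[0])
    apd = (
        nx.average_shortest_path_length(giant)
        if giant.number_of_nodes() > 1
        else float("nan")
    )
    ss = np.random.SeedSequence(seed)
    restart_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_modularity_restarts)]
    mods, partitions = [], []
    for s in restart_seeds:
        communities = nx.community.louvain_communities(g, weight=None, seed=s)
        mods.append(nx.community.modularity(g, communities, weight=None))
        partitions.append(communities)
    mods_arr = np.asarray(mods)
    best = partitions[int(np.argmax(mods_arr))]
    best_sorted = sorted((sorted(c) for c in best), key=lambda c: (-len(c), c))
    for module_id, members in enumerate(best_sorted):
        for node in members:
            g.nodes[node]["module"] = module_id
    for node, deg in g.degree():
        g.nodes[node]["degree"] = deg
    summary = {
        "n_nodes": v,
        "n_edges": e,
        "average_degree": ad,
        "average_clustering_coefficient": acc,
        "average_path_distance": float(apd),
        "largest_component_fraction": giant.number_of_nodes() / v,
        "graph_density": gd,
        "modularity_mean": float(mods_arr.mean()),
        "modularity_sd": float(mods_arr.std(ddof=1)) if len(mods_arr) > 1 else 0.0,
        "n_modules": len(best_sorted),
        "module_sizes": [len(c) for c in best_sorted],
        "edge_sign_fractions": net.edge_sign_fractions(),
        "n_modularity_restarts": n_modularity_restarts,
        "seed": seed,
    }
    net.topology_summary = summary
    return summary


def annotate_nodes(
    net: CooccurrenceNetwork,
    classification=None,
    niche=None,
    taxonomy: dict[str, str] | None = None,
) -> dict:
    """Attach abundance class / niche category / phylum attributes to nodes.

    Ids that cannot be resolved get the label ``"unknown"``. Returns the
    per-attribute node fractions (each fraction set sums to 1).
    """
    g = net.graph

    def _lookup_class(otu):
        if classification is None or otu not in classification.labels.index:
            return "unknown"
        return str(classification.labels[otu])

    def _lookup_niche(otu):
        if niche is None or otu not in niche.per_otu.index:
            return "unknown"
        return str(niche.per_otu.loc[otu, "category"])

    def _lookup_phylum(otu):
        if not taxonomy or otu not in taxonomy:
            return "unknown"
        lineage = taxonomy[otu]
        parts = [p.strip() for p in lineage.replace("|", ";").split(";") if p.strip()]
        for part in parts:
            if part.lower().startswith("p__"):
                return part[3:] or "unknown"
        return parts[1] if len(parts) > 1 else parts[0]

    fractions: dict[str, dict[str, float]] = {}
    for attr, fn in (
        ("abundance_class", _lookup_class),
        ("niche_category", _lookup_niche),
        ("phylum", _lookup_phylum),
    ):
        counts: dict[str, int] = {}
        for node in g.nodes:
            val = fn(node)
            g.nodes[node][attr] = val
            counts[val] = counts.get(val, 0) + 1
        total = sum(counts.values())
        fractions[attr] = {k: c / total for k, c in sorted(counts.items())}
    return fractions
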
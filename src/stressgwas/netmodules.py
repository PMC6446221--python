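"""Protein-interaction module discovery with a randomized null.

Maximal cliques of the (score-filtered) interaction network are tested for
enrichment of a foreground gene list (hypergeometric, against the network's
node set as background), BH-corrected across cliques; the union of
significant cliques, split into connected components, forms the modules.
Module statistics (modularity and association with a curated reference
list) are compared against equally sized random gene lists with a paired
Wilcoxon signed-rank test, mirroring the design of ModuleDiscoverer-style
validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "InteractionNetwork",
    "Module",
    "ModuleStats",
    "STAT_FIELDS",
    "read_network",
    "find_modules",
    "module_stats",
    "null_comparison",
    "shared_modules",
]


class NetworkParseError(ValueError):
    pass


@dataclass
class InteractionNetwork:
    graph: nx.Graph
    score_min: float = 0.0

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)


@dataclass
class Module:
    nodes: frozenset
    cliques: list[frozenset]
    p_adjusted: float                      # min BH-adjusted clique p
    labels: dict[str, str] = field(default_factory=dict)


STAT_FIELDS = (
    "nodes_in_modules", "nodes_in_cliques", "internal_edges",
    "foreground_proportion", "edges_to_reference_nodes",
    "overlap_rate", "foreground_overlap_rate",
)


@dataclass
class ModuleStats:
    nodes_in_modules: int = 0
    nodes_in_cliques: int = 0
    internal_edges: int = 0
    foreground_proportion: float = 0.0
    edges_to_reference_nodes: int = 0
    overlap_rate: float = 0.0
    foreground_overlap_rate: float = 0.0

    def as_series(self) -> pd.Series:
        return pd.Series({k: getattr(self, k) for k in STAT_FIELDS})


def read_network(path, score_min: float = 0.0) -> InteractionNetwork:
    """Read a STRING-style 3-column edge list (node_a, node_b, score).

    Edges below ``score_min`` are dropped; duplicate undirected edges are
    merged keeping the maximum score; self-loops are discarded.
    """
    try:
        frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:
        raise NetworkParseError(f"cannot parse {path}: {exc}") from exc
    if frame.shape[1] != 3:
        raise NetworkParseError(f"{path}: expected 3 columns, got {frame.shape[1]}")
    # headerless files: first row is data if its third field is numeric
    try:
        float(frame.columns[2])
        frame.loc[-1] = list(frame.columns)
        frame = frame.sort_index().reset_index(drop=True)
    except ValueError:
        pass
    frame.columns = ["node_a", "node_b", "score"]
    scores = pd.to_numeric(frame["score"], errors="coerce")
    bad = frame.index[scores.isna()]
    if len(bad):
        raise NetworkParseError(f"{path}: line {bad[0] + 2}: non-numeric score")
    g = nx.Graph()
    for a, b, s in zip(frame["node_a"], frame["node_b"], scores):
        if a == b:
            continue
        if s < score_min:
            continue
        if g.has_edge(a, b):
            g[a][b]["score"] = max(g[a][b]["score"], float(s))
        else:
            g.add_edge(a, b, score=float(s))
    return InteractionNetwork(graph=g, score_min=score_min)


def find_modules(
    network: InteractionNetwork | nx.Graph,
    foreground: list[str],
    clique_min_size: int = 3,
    alpha: float = 0.05,
    max_exact_nodes: int = 5000,
    n_clique_samples: int = 20000,
    seed: int = 0,
    reference: list[str] | None = None,
) -> list[Module]:
    """Foreground-enriched modules: union of enrichment-significant cliques.

    Maximal cliques of size >= ``clique_min_size`` are enumerated exactly
    (randomized sampling above ``max_exact_nodes`` nodes, seed-controlled);
    each clique's foreground content is tested with a hypergeometric against
    the network node set; BH across cliques at ``alpha``; the induced union
    of significant cliques splits into connected components = modules.
    """
    g = network.graph if isinstance(network, InteractionNetwork) else network
    nodeset = set(g.nodes)
    fg = [v for v in dict.fromkeys(foreground)]
    dropped = [v for v in fg if v not in nodeset]
    if dropped:
        warnings.warn(f"{len(dropped)} foreground genes not in network; dropped",
                      stacklevel=2)
    fg = set(v for v in fg if v in nodeset)
    if not fg:
        raise ValueError("empty foreground after intersecting with network")
    if len(nodeset) <= max_exact_nodes:
        cliques = [frozenset(c) for c in nx.find_cliques(g) if len(c) >= clique_min_size]
    else:  # sampled fallback for very large graphs
        rng = np.random.default_rng(seed)
        nodes = list(nodeset)
        seen = set()
        for _ in range(n_clique_samples):
            v = nodes[rng.integers(len(nodes))]
            c = frozenset(nx.find_cliques(g, nodes=[v]).__next__())
            if len(c) >= clique_min_size:
                seen.add(c)
        cliques = sorted(seen, key=sorted)
    if not cliques:
        return []
    N, Kfg = len(nodeset), len(fg)
    pvals = np.array(
        [stats.hypergeom.sf(len(c & fg) - 1, N, Kfg, len(c)) for c in cliques]
    )
    rej, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    sig = [(c, p_adj[i]) for i, c in enumerate(cliques) if rej[i]]
    if not sig:
        return []
    union = nx.Graph()
    for c, _ in sig:
        union.add_nodes_from(c)
        for a in c:
            for b in c:
                if a < b:
                    union.add_edge(a, b)
    ref = set(reference or [])
    modules = []
    for comp in nx.connected_components(union):
        comp = frozenset(comp)
        mod_cliques = [c for c, _ in sig if c <= comp]
        p_min = min(p for c, p in sig if c <= comp)
        labels = {}
        for v in comp:
            in_fg, in_ref = v in fg, v in ref
            labels[v] = "both" if in_fg and in_ref else (
                "foreground-only" if in_fg else
                ("reference-only" if in_ref else "neither"))
        modules.append(Module(nodes=comp, cliques=mod_cliques,
                              p_adjusted=float(p_min), labels=labels))
    return sorted(modules, key=lambda m: (-len(m.nodes), sorted(m.nodes)))


def module_stats(
    modules: list[Module],
    network: InteractionNetwork | nx.Graph,
    foreground: list[str],
    reference: list[str] | None = None,
) -> ModuleStats:
    """Modularity and reference-association statistics over a module set."""
    g = network.graph if isinstance(network, InteractionNetwork) else network
    if not modules:
        return ModuleStats()
    mod_nodes = set().union(*(m.nodes for m in modules))
    clique_nodes = set().union(*(set().union(*m.cliques) for m in modules))
    fg = set(foreground) & set(g.nodes)
    ref = set(reference or [])
    internal = sum(
        1 for m in modules for a, b in g.subgraph(m.nodes).edges()
    )
    edges_to_ref = sum(
        1 for v in mod_nodes for u in g.neighbors(v) if u in ref and u not in mod_nodes
    ) + sum(1 for a, b in g.subgraph(mod_nodes).edges() if a in ref or b in ref)
    fg_in_mod = mod_nodes & fg
    return ModuleStats(
        nodes_in_modules=len(mod_nodes),
        nodes_in_cliques=len(clique_nodes),
        internal_edges=internal,
        foreground_proportion=len(fg_in_mod) / len(mod_nodes),
        edges_to_reference_nodes=edges_to_ref,
        overlap_rate=len(mod_nodes & ref) / len(mod_nodes),
        foreground_overlap_rate=(len(fg_in_mod & ref) / len(fg_in_mod)) if fg_in_mod else 0.0,
    )


def null_comparison(
    network: InteractionNetwork | nx.Graph,
    foreground: list[str],
    n_random: int = 5,
    seed: int = 0,
    reference: list[str] | None = None,
    clique_min_size: int = 3,
    alpha: float = 0.05,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Compare the real foreground's module statistics with random lists.

    ``n_random`` random node lists of the same length are drawn; for every
    module statistic the paired differences (real minus each null run) are
    tested with a one-sided Wilcoxon signed-rank test (all-zero differences
    report p = 1).  Returns a frame indexed by statistic with columns
    real, null_mean, p.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    g = network.graph if isinstance(network, InteractionNetwork) else network
    rng = np.random.default_rng(seed)
    fg = [v for v in dict.fromkeys(foreground) if v in g.nodes]
    if not fg:
        raise ValueError("empty foreground")

    def stats_for(genes: list[str]) -> pd.Series:
        try:
            mods = find_modules(g, genes, clique_min_size=clique_min_size,
                                alpha=alpha, reference=reference)
        except ValueError:
            mods = []
        return module_stats(mods, g, genes, reference).as_series()

    real = stats_for(fg)
    nodes = sorted(g.nodes)
    null_rows = []
    for _ in range(n_random):
        draw = rng.choice(nodes, size=len(fg), replace=False)
        null_rows.append(stats_for([str(v) for v in draw]))
    nulls = pd.DataFrame(null_rows)

    out = []
    for k in STAT_FIELDS:
        diffs = real[k] - nulls[k].to_numpy(dtype=float)
        if np.all(diffs == 0):
            p = 1.0
        else:
            try:
                _, p = stats.wilcoxon(diffs, alternative=alternative,
                                      zero_method="wilcox")
            except ValueError:
                p = 1.0
        out.append({"statistic": k, "real": float(real[k]),
                    "null_mean": float(nulls[k].mean()), "p": float(p)})
    return pd.DataFrame(out).set_index("statistic")


def shared_modules(
    module_sets: dict[str, list[Module]], jaccard_min: float = 0.5
) -> pd.DataFrame:
    """Cross-phenotype module overlap: Jaccard of node sets above threshold."""
    if len(module_sets) < 2:
        raise ValueError("need module sets for at least 2 phenotypes")
    rows = []
    phenos = sorted(module_sets)
    for i, pa in enumerate(phenos):
        for pb in phenos[i + 1:]:
            for ia, ma in enumerate(module_sets[pa]):
                for ib, mb in enumerate(module_sets[pb]):
                    inter = len(ma.nodes & mb.nodes)
                    union = len(ma.nodes | mb.nodes)
                    j = inter / union if union else 0.0
                    if j >= jaccard_min:
                        rows.append(
                            {"phenotype_a": pa, "module_a": ia,
                             "phenotype_b": pb, "module_b": ib, "jaccard": j}
                        )
    return pd.DataFrame(
        rows, columns=["phenotype_a", "module_a", "phenotype_b", "module_b", "jaccard"]
    )
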
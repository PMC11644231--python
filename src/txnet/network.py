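"""DEG-restricted interaction networks from channel-scored edge lists.

Interaction evidence comes in the STRING "detailed" dialect: one row per
protein pair with a score in [0, 1] (or the 0-1000 integer encoding) for
each evidence channel — neighborhood, fusion, co-occurrence,
co-expression, experimental, database, text-mining — plus a combined
score.  Channels are combined probabilistically after removing a shared
prior p0 (the baseline chance that any pair interacts, 0.041):

    s'_c  = max(0, (s_c - p0) / (1 - p0))        per channel
    S'    = 1 - prod_c (1 - s'_c)                 over allowed channels
    S     = S' + p0 * (1 - S')                    prior re-added

Restricting the product to a subset of channels is how evidence sources
(e.g. text-mining) are excluded: the published combined score cannot be
decomposed, so it is recomputed from the per-channel scores.

The analysis graph is the induced subgraph on differentially expressed
genes with edges at or above a confidence threshold (default 0.900, the
"highest confidence" band).  Downstream operations: connected-component
diameters, selection of the highest-diameter component, removal of a gene
group (e.g. ribosomal proteins), degree/betweenness centrality, and hub
selection at betweenness > 0.5 and degree > 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: Evidence channels, canonical internal spelling.
CHANNELS = (
    "neighborhood",
    "fusion",
    "cooccurrence",
    "coexpression",
    "experimental",
    "database",
    "textmining",
)

#: Channels excluded by default (indirect / literature-derived evidence).
EXCLUDED_CHANNELS = frozenset({"textmining", "neighborhood", "fusion", "cooccurrence"})

#: Direct-evidence channels kept by default.
ALLOWED_CHANNELS = frozenset(CHANNELS) - EXCLUDED_CHANNELS

#: Baseline probability that a random protein pair interacts.
DEFAULT_PRIOR = 0.041

# the STRING file header spells it "cooccurence"
_FILE_TO_CHANNEL = {
    "neighborhood": "neighborhood",
    "fusion": "fusion",
    "cooccurence": "cooccurrence",
    "cooccurrence": "cooccurrence",
    "coexpression": "coexpression",
    "experimental": "experimental",
    "database": "database",
    "textmining": "textmining",
}
_CHANNEL_TO_FILE = {
    "neighborhood": "neighborhood",
    "fusion": "fusion",
    "cooccurrence": "cooccurence",
    "coexpression": "coexpression",
    "experimental": "experimental",
    "database": "database",
    "textmining": "textmining",
}


@dataclass(frozen=True)
class ChannelEdge:
    """Undirected protein pair with per-channel evidence scores in [0, 1].

    The pair is stored in canonical (lexicographic) order.
    """

    gene_a: str
    gene_b: str
    channel_scores: Mapping[str, float] = field(default_factory=dict)
    combined_score: float = 0.0

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-loop edge: {self.gene_a}")
        if self.gene_b < self.gene_a:
            a, b = self.gene_b, self.gene_a
            object.__setattr__(self, "gene_a", a)
            object.__setattr__(self, "gene_b", b)
        for c, s in self.channel_scores.items():
            if c not in CHANNELS:
                raise ValueError(f"unknown channel: {c!r}")
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"channel score out of [0,1]: {c}={s}")
        if not 0.0 <= self.combined_score <= 1.0:
            raise ValueError(f"combined score out of [0,1]: {self.combined_score}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def read_string_edges(path) -> list[ChannelEdge]:
    """Read a channel-scored edge list in the STRING detailed dialect.

    Expects columns ``protein1 protein2 neighborhood fusion cooccurence
    coexpression experimental database textmining combined_score``
    (tab- or whitespace-separated).  Integer scores 0-1000 are mapped to
    [0, 1]; files already on the float scale are accepted as-is.
    Symmetric duplicate rows collapse to one canonical edge; self-loop
    rows are dropped (count logged).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.strip(): c for c in df.columns}
    required = ["protein1", "protein2"]
    score_cols = [c for c in cols if c in _FILE_TO_CHANNEL] + (
        ["combined_score"] if "combined_score" in cols else []
    )
    missing = [c for c in required if c not in cols]
    if missing or not any(c in _FILE_TO_CHANNEL for c in cols):
        raise ValueError(f"missing required columns in {path}: {missing or 'channel scores'}")
    for c in score_cols:
        if not pd.api.types.is_numeric_dtype(df[cols[c]]):
            raise ValueError(f"non-numeric score column {c!r} in {path}")
    # integer dialect detection: all score columns integral -> 0-1000 scale
    integer_dialect = all(
        pd.api.types.is_integer_dtype(df[cols[c]]) for c in score_cols
    )
    scale = 1000.0 if integer_dialect else 1.0

    edges: dict[tuple[str, str], ChannelEdge] = {}
    n_self = 0
    for row in df.itertuples(index=False):
        rec = dict(zip(df.columns, row))
        a, b = str(rec[cols["protein1"]]), str(rec[cols["protein2"]])
        if a == b:
            n_self += 1
            continue
        scores = {
            _FILE_TO_CHANNEL[c]: float(rec[cols[c]]) / scale
            for c in cols
            if c in _FILE_TO_CHANNEL
        }
        combined = float(rec[cols["combined_score"]]) / scale if "combined_score" in cols else 0.0
        edge = ChannelEdge(a, b, scores, combined)
        edges.setdefault(edge.pair, edge)
    if n_self:
        logger.info("read_string_edges: dropped %d self-loop row(s)", n_self)
    return list(edges.values())


def write_string_edges(edges: Iterable[ChannelEdge], path) -> None:
    """Write edges in the STRING detailed dialect (integer 0-1000 scores)."""
    file_channels = [_CHANNEL_TO_FILE[c] for c in CHANNELS]
    rows = []
    for e in edges:
        row = {"protein1": e.gene_a, "protein2": e.gene_b}
        for c in CHANNELS:
            row[_CHANNEL_TO_FILE[c]] = int(round(e.channel_scores.get(c, 0.0) * 1000))
        row["combined_score"] = int(round(e.combined_score * 1000))
        rows.append(row)
    cols = ["protein1", "protein2", *file_channels, "combined_score"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def recombine_score(
    channel_scores: Mapping[str, float],
    allowed_channels: Iterable[str] = ALLOWED_CHANNELS,
    prior: float = DEFAULT_PRIOR,
) -> float:
    """Combined confidence from a subset of evidence channels.

    Removes the prior from each allowed channel, combines the excesses as
    independent evidence, and re-adds the prior.  With no allowed evidence
    above the prior the result is exactly ``prior``; a single channel at
    score *s* >= prior recombines back to *s* (idempotence).
    """
    if not 0.0 <= prior < 1.0:
        raise ValueError(f"prior must be in [0, 1): {prior}")
    no_prior = 1.0
    for c in allowed_channels:
        if c not in CHANNELS:
            raise ValueError(f"unknown channel: {c!r}")
        s = channel_scores.get(c, 0.0)
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"channel score out of [0,1]: {c}={s}")
        s_excess = max(0.0, (s - prior) / (1.0 - prior))
        no_prior *= 1.0 - s_excess
    combined_noprior = 1.0 - no_prior
    return combined_noprior + prior * (1.0 - combined_noprior)


def build_network(
    edges: Iterable[ChannelEdge],
    deg_genes: Iterable[str],
    threshold: float = 0.900,
    allowed_channels: Iterable[str] = ALLOWED_CHANNELS,
    prior: float = DEFAULT_PRIOR,
) -> nx.Graph:
    """Induced interaction graph on DEGs at a confidence threshold.

    Keeps edges whose both endpoints are DEGs and whose recombined
    allowed-channel score is >= ``threshold``.  Every DEG becomes a node,
    so isolated DEGs are retained with degree 0.  The recombined score is
    stored as edge attribute ``score``.
    """
    deg_set = set(deg_genes)
    if not deg_set:
        raise ValueError("empty DEG list")
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1]: {threshold}")
    allowed = frozenset(allowed_channels)
    g = nx.Graph()
    g.add_nodes_from(sorted(deg_set))
    for e in edges:
        if e.gene_a in deg_set and e.gene_b in deg_set:
            s = recombine_score(e.channel_scores, allowed, prior)
            if s >= threshold:
                g.add_edge(e.gene_a, e.gene_b, score=s)
    return g


def component_diameters(net: nx.Graph) -> list[tuple[frozenset, int]]:
    """Connected components with their unweighted diameters.

    The diameter of a component is the maximum shortest-path hop count
    between any two of its nodes; a singleton has diameter 0.
    """
    out = []
    for comp in nx.connected_components(net):
        sub = net.subgraph(comp)
        diam = 0 if len(comp) == 1 else nx.diameter(sub)
        out.append((frozenset(comp), diam))
    return out


def select_max_diameter_component(net: nx.Graph) -> nx.Graph:
    """The component with the largest diameter, as a standalone graph.

    Ties broken by larger node count, then lexicographically smallest
    sorted node set — fully deterministic.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comps = component_diameters(net)
    comps.sort(key=lambda cd: (-cd[1], -len(cd[0]), tuple(sorted(cd[0]))))
    chosen = comps[0][0]
    return net.subgraph(chosen).copy()


def remove_group_nodes(net: nx.Graph, group_genes: Iterable[str]) -> nx.Graph:
    """Induced subgraph after dropping nodes in a gene group.

    The graph may disconnect; no component re-selection happens here.
    """
    group = set(group_genes)
    keep = [n for n in net.nodes if n not in group]
    n_removed = net.number_of_nodes() - len(keep)
    if n_removed:
        logger.info("remove_group_nodes: removed %d node(s)", n_removed)
    return net.subgraph(keep).copy()


def centrality(net: nx.Graph) -> pd.DataFrame:
    """Degree and normalized betweenness centrality per node.

    Betweenness uses unweighted shortest paths with endpoints excluded,
    normalized by ``(n-1)(n-2)/2`` where *n* is the node count of the
    analyzed graph; nodes in components of size <= 2 score 0.

    Returns a DataFrame with columns ``gene, degree, betweenness``, sorted
    by gene.
    """
    nodes = sorted(net.nodes)
    bt = nx.betweenness_centrality(net, normalized=True)
    return pd.DataFrame(
        {
            "gene": nodes,
            "degree": [net.degree(n) for n in nodes],
            "betweenness": [bt[n] for n in nodes],
        }
    )


def select_hubs(records: pd.DataFrame, bt_min: float = 0.5, deg_min: int = 2) -> list[str]:
    """Hub genes: betweenness strictly above ``bt_min`` AND degree strictly
    above ``deg_min``, sorted by betweenness then degree descending, then
    symbol."""
    hubs = records[(records["betweenness"] > bt_min) & (records["degree"] > deg_min)]
    hubs = hubs.sort_values(
        ["betweenness", "degree", "gene"], ascending=[False, False, True], kind="stable"
    )
    return list(hubs["gene"])


def network_summary(net: nx.Graph) -> dict:
    """Node/edge counts, average degree 2E/N and mean local clustering."""
    n = net.number_of_nodes()
    e = net.number_of_edges()
    if n == 0:
        return {"n_nodes": 0, "n_edges": 0, "avg_degree": 0.0, "avg_clustering": 0.0}
    return {
        "n_nodes": n,
        "n_edges": e,
        "avg_degree": 2.0 * e / n,
        "avg_clustering": nx.average_clustering(net),
    }


def write_edge_list(net: nx.Graph, path) -> None:
    """Two-column TSV edge list, canonically ordered (deterministic)."""
    rows = sorted(tuple(sorted(e)) for e in net.edges)
    pd.DataFrame(rows, columns=["gene_a", "gene_b"]).to_csv(path, sep="\t", index=False)


def write_graphml(net: nx.Graph, path) -> None:
    """GraphML export (text XML)."""
    nx.write_graphml(net, path)
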
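"""Network export (SIF, GraphML, edge TSV) and node statistics.

Exports target Cytoscape-style consumers: SIF carries one line per edge
with the interaction label (phos / dephos / undetermined); GraphML keeps
node attributes (is_regulator, membership) and edge attributes (sign,
score, lapse, membership); the edge TSV mirrors the GraphML attributes.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

FORMATS = ("sif", "graphml", "tsv")


def site_label(site) -> str:
    """Stable string id for a site key tuple: protein_pPOSRES_mMULT."""
    if isinstance(site, tuple) and len(site) == 4:
        prot, pos, res, mult = site
        return f"{prot}_p{pos}{res}_m{mult}"
    return str(site)


def _string_graph(net: nx.DiGraph) -> nx.DiGraph:
    g = nx.DiGraph()
    for node, attrs in net.nodes(data=True):
        g.add_node(
            site_label(node),
            is_regulator=bool(attrs.get("is_regulator", False)),
            membership=str(attrs.get("membership", "")),
        )
    for u, v, attrs in net.edges(data=True):
        g.add_edge(
            site_label(u),
            site_label(v),
            sign=str(attrs.get("sign", "")),
            lapse=int(attrs.get("lapse", 0)),
            score=float(attrs.get("score", 0.0)),
            membership=str(attrs.get("membership", "")),
        )
    return g


def export_network(net: nx.DiGraph, path, fmt: str) -> None:
    """Write ``net`` as SIF, GraphML, or edge TSV.

    SIF lists edges only (isolated nodes are dropped by the format);
    GraphML and TSV keep all attributes.
    """
    fmt = fmt.lower()
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")
    g = _string_graph(net)
    if fmt == "sif":
        with open(path, "w") as fh:
            for u, v, attrs in sorted(g.edges(data=True)):
                fh.write(f"{u}\t{attrs['sign'] or 'undetermined'}\t{v}\n")
    elif fmt == "graphml":
        nx.write_graphml(g, path)
    else:
        edges_frame(net).to_csv(path, sep="\t", index=False)


def edges_frame(net: nx.DiGraph) -> pd.DataFrame:
    rows = [
        {
            "regulator": site_label(u),
            "target": site_label(v),
            "sign": attrs.get("sign", ""),
            "lapse": attrs.get("lapse", ""),
            "score": attrs.get("score", ""),
            "membership": attrs.get("membership", ""),
        }
        for u, v, attrs in sorted(net.edges(data=True), key=lambda e: (str(e[0]), str(e[1])))
    ]
    return pd.DataFrame(
        rows, columns=["regulator", "target", "sign", "lapse", "score", "membership"]
    )


def compute_betweenness(net: nx.DiGraph, directed: bool = False) -> dict:
    """Normalized betweenness centrality per node.

    Computed on the undirected projection by default (what a default
    Cytoscape analysis reports for mixed networks); pass
    ``directed=True`` for the directed variant.
    """
    g = net if directed else nx.Graph(net)
    return nx.betweenness_centrality(g, normalized=True)
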
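"""Signed, role-annotated co-regulation network assembly and export.

Nodes are phosphosites (rendered ``GENE_R###``), classed as the target
protein's major sites or PsOPs; edges connect a major site to a
high-confidence co-regulated PsOP and carry the sign, FET p, the
sign-appropriate co-regulation ratio and the evidence counts.  Exports
(GraphML, SIF with sidecar attribute TSVs, plain node/edge TSVs) are
byte-stable: nodes and edges are written in sorted order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import pandas as pd

from .annotation import RoleAssignment
from .compendium import SiteKey
from .coregulation import CoRegResult

FORMATS = ("graphml", "sif", "node_edge_tsv")


@dataclass
class CoRegNetwork:
    graph: nx.DiGraph  # edges directed m-site -> o-site

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    highconf: Sequence[CoRegResult],
    roles: Sequence[RoleAssignment] = (),
    target_sites: Sequence[SiteKey] = (),
) -> CoRegNetwork:
    """Assemble the signed network from high-confidence pairs and roles.

    Every pair must be unique; target sites are always present as nodes
    even when they carry no edges.  Role labels are aggregated per PsOP
    node as a sorted, semicolon-joined list.
    """
    g = nx.DiGraph()

    def add_site(site: SiteKey, node_class: str) -> None:
        g.add_node(
            str(site),
            gene=site.gene,
            residue=site.residue,
            position=site.position,
            node_class=node_class,
            roles="",
        )

    for s in target_sites:
        add_site(s, "target_site")
    seen: set[tuple[str, str]] = set()
    for r in highconf:
        if r.sign == "none":
            continue
        key = (str(r.m_site), str(r.o_site))
        if key in seen:
            raise ValueError(f"duplicate (m, o) pair in input: {key}")
        seen.add(key)
        if str(r.m_site) not in g:
            add_site(r.m_site, "target_site")
        if str(r.o_site) not in g:
            add_site(r.o_site, "psop")
        ratio = r.ratio_pos if r.sign == "positive" else r.ratio_neg
        g.add_edge(
            str(r.m_site),
            str(r.o_site),
            sign=r.sign,
            fet_p=float(r.fet_p),
            ratio=float(ratio) if math.isfinite(ratio) else math.inf,
            n_conditions=int(r.n_conditions),
            n_pmids=int(r.n_pmids),
        )
    node_roles: dict[str, set[str]] = {}
    for a in roles:
        for endpoint in (str(a.o_site),):
            node_roles.setdefault(endpoint, set()).add(a.role)
    for node, rs in node_roles.items():
        if node not in g:
            raise ValueError(f"role assignment references unknown node {node}")
        g.nodes[node]["roles"] = ";".join(sorted(rs))
    return CoRegNetwork(g)


def filter_by_role(net: CoRegNetwork, role: str, sign: Optional[str] = None) -> CoRegNetwork:
    """Subgraph keeping target sites plus PsOPs holding ``role`` (and sign)."""
    g = net.graph
    keep_nodes = {n for n, d in g.nodes(data=True) if d["node_class"] == "target_site"}
    psops = {
        n
        for n, d in g.nodes(data=True)
        if d["node_class"] == "psop" and role in d["roles"].split(";")
    }
    sub = nx.DiGraph()
    for n in sorted(keep_nodes | psops):
        sub.add_node(n, **g.nodes[n])
    for u, v, d in g.edges(data=True):
        if v in psops and (sign is None or d["sign"] == sign):
            sub.add_edge(u, v, **d)
    return CoRegNetwork(sub)


def _sorted_copy(g: nx.DiGraph) -> nx.DiGraph:
    out = nx.DiGraph()
    for n in sorted(g.nodes):
        out.add_node(n, **g.nodes[n])
    for u, v in sorted(g.edges):
        out.add_edge(u, v, **g.edges[u, v])
    return out


def node_frame(net: CoRegNetwork) -> pd.DataFrame:
    rows = [
        {"node": n, **{k: d[k] for k in ("gene", "residue", "position", "node_class", "roles")}}
        for n, d in sorted(net.graph.nodes(data=True))
    ]
    return pd.DataFrame(
        rows, columns=["node", "gene", "residue", "position", "node_class", "roles"]
    )


def edge_frame(net: CoRegNetwork) -> pd.DataFrame:
    rows = [
        {
            "m_site": u,
            "o_site": v,
            "sign": d["sign"],
            "fet_p": d["fet_p"],
            "ratio": d["ratio"],
            "n_conditions": d["n_conditions"],
            "n_pmids": d["n_pmids"],
        }
        for u, v, d in sorted(net.graph.edges(data=True))
    ]
    return pd.DataFrame(
        rows,
        columns=["m_site", "o_site", "sign", "fet_p", "ratio", "n_conditions", "n_pmids"],
    )


def write_network(net: CoRegNetwork, fmt: str, path: str | Path) -> list[Path]:
    """Write the network in one of FORMATS; returns the files written.

    * ``graphml`` — single XML file with typed attribute keys;
    * ``sif``     — ``<m> coreg_pos|coreg_neg <o>`` lines plus sidecar
      ``*.nodes.tsv`` / ``*.edges.tsv`` attribute tables;
    * ``node_edge_tsv`` — the two attribute tables only.
    """
    path = Path(path)
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")
    written: list[Path] = []
    if fmt == "graphml":
        nx.write_graphml(_sorted_copy(net.graph), path)
        written.append(path)
    elif fmt == "sif":
        token = {"positive": "coreg_pos", "negative": "coreg_neg"}
        lines = [
            f"{u}\t{token[d['sign']]}\t{v}"
            for u, v, d in sorted(net.graph.edges(data=True))
        ]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        written.append(path)
        for suffix, frame in (("nodes", node_frame(net)), ("edges", edge_frame(net))):
            side = path.with_suffix(f".{suffix}.tsv")
            frame.to_csv(side, sep="\t", index=False)
            written.append(side)
    else:
        for suffix, frame in (("nodes", node_frame(net)), ("edges", edge_frame(net))):
            side = path.with_suffix(f".{suffix}.tsv")
            frame.to_csv(side, sep="\t", index=False)
            written.append(side)
    return written


def collapse_to_proteins(net: CoRegNetwork) -> CoRegNetwork:
    """Protein-level view: PsOP nodes collapsed to genes, edge signs kept.

    When several sites of one protein connect to the same target site
    with different signs, the edge keeps the sign of the smallest FET p.
    """
    g = nx.DiGraph()
    for n, d in net.graph.nodes(data=True):
        if d["node_class"] == "target_site":
            g.add_node(n, **d)
        else:
            g.add_node(d["gene"], gene=d["gene"], node_class="psop_protein",
                       roles=d["roles"])
    for u, v, d in sorted(net.graph.edges(data=True)):
        gene = net.graph.nodes[v]["gene"]
        if g.has_edge(u, gene) and g.edges[u, gene]["fet_p"] <= d["fet_p"]:
            continue
        g.add_edge(u, gene, **d)
    return CoRegNetwork(g)
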
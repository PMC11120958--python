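"""Bipartite causality graphs: TF nodes feed model nodes, model nodes feed targets.

Instead of drawing a plain TF -> target edge for every regulator, each
pairwise-disjoint predictive TF set becomes a *model node*: its member TFs
point to the model, and the model emits a single edge to its target gene.
A TF shared by models of several targets appears as one gene node, which is
what makes group effects across targets visible.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np

from tfsynergy.models import rmse
from tfsynergy.selection import DisjointSetsResult

__all__ = ["build_bipartite", "serialize_graph", "read_graph", "render_graph",
           "model_node_id"]


def model_node_id(target: str, set_index: int) -> str:
    return f"{target}#{set_index}"


def build_bipartite(results: list[DisjointSetsResult]) -> nx.DiGraph:
    """Assemble the two-kind graph from per-target disjoint-set results.

    One model node per (target, set); gene nodes carry a role in
    {tf, target, both}; model nodes carry their member TF list and summary
    training RMSE.  Duplicate (target, set_index) pairs are an error.
    """
    g = nx.DiGraph()
    tf_roles: set[str] = set()
    target_roles: set[str] = set()

    for res in results:
        res.validate_disjoint()
        target_roles.add(res.target_id)
        for i, (members, model) in enumerate(zip(res.sets, res.per_set_models), start=1):
            mid = model_node_id(res.target_id, i)
            if g.has_node(mid):
                raise ValueError(f"duplicate model node {mid!r}")
            errs = model.train_error_vector.to_numpy()
            g.add_node(mid, kind="model", target=res.target_id, set_index=i,
                       rmse=float(rmse(errs, np.zeros_like(errs))),
                       members="|".join(members))
            for tf in members:
                tf_roles.add(tf)
                if not g.has_node(tf):
                    g.add_node(tf, kind="gene")
                g.add_edge(tf, mid)
            if not g.has_node(res.target_id):
                g.add_node(res.target_id, kind="gene")
            g.add_edge(mid, res.target_id)

    for node in g.nodes:
        if g.nodes[node].get("kind") == "gene":
            is_tf = node in tf_roles
            is_target = node in target_roles
            g.nodes[node]["role"] = "both" if (is_tf and is_target) else (
                "tf" if is_tf else "target")
    return g


def _check(graph: nx.DiGraph) -> None:
    for u, v in graph.edges:
        ku, kv = graph.nodes[u]["kind"], graph.nodes[v]["kind"]
        if ku == kv:
            raise ValueError(f"edge {u}->{v} does not cross node kinds")


def serialize_graph(graph: nx.DiGraph, path: str | Path, format: str = "graphml") -> Path:
    """Write the graph as GraphML, JSON (node/edge lists), or DOT."""
    _check(graph)
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "json":
        payload = {
            "nodes": [{"id": n, **graph.nodes[n]} for n in graph.nodes],
            "edges": [{"source": u, "target": v} for u, v in graph.edges],
        }
        path.write_text(json.dumps(payload, indent=2))
    elif format == "dot":
        lines = ["digraph bipartite_causality {"]
        for n in graph.nodes:
            attrs = graph.nodes[n]
            shape = "ellipse" if attrs["kind"] == "model" else "box"
            label = n.replace('"', r"\"")
            lines.append(f'  "{label}" [shape={shape}, kind="{attrs["kind"]}"];')
        for u, v in graph.edges:
            lines.append(f'  "{u}" -> "{v}";')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_graph(path: str | Path, format: str = "graphml") -> nx.DiGraph:
    path = Path(path)
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "json":
        payload = json.loads(path.read_text())
        g = nx.DiGraph()
        for node in payload["nodes"]:
            node = dict(node)
            g.add_node(node.pop("id"), **node)
        for e in payload["edges"]:
            g.add_edge(e["source"], e["target"])
        return g
    raise ValueError(f"unknown format {format!r}")


def _layered_positions(graph: nx.DiGraph) -> dict[str, tuple[float, float]]:
    """Deterministic three-column layout: TFs | models | targets."""
    tfs, mids, targets = [], [], []
    for n in sorted(graph.nodes):
        attrs = graph.nodes[n]
        if attrs["kind"] == "model":
            mids.append(n)
        elif attrs.get("role") == "target":
            targets.append(n)
        else:  # tf or both: drawn in the TF column
            tfs.append(n)
    pos = {}
    for x, col in ((0.0, tfs), (1.0, mids), (2.0, targets)):
        for i, n in enumerate(col):
            y = 0.0 if len(col) == 1 else i / (len(col) - 1)
            pos[n] = (x, y)
    return pos


def render_graph(graph: nx.DiGraph, out_path: str | Path,
                 target_subset: list[str] | None = None, seed: int = 0) -> Path:
    """Draw the bipartite graph: TFs as dark-orange squares, models as
    light-orange circles, target genes as blue circles; layered layout.

    ``target_subset`` restricts the figure to the chosen targets, their
    model nodes, and those models' TFs.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if target_subset is not None:
        keep = set()
        for n in graph.nodes:
            attrs = graph.nodes[n]
            if attrs["kind"] == "model" and attrs.get("target") in target_subset:
                keep.add(n)
                keep.update(graph.predecessors(n))
                keep.update(graph.successors(n))
        if not keep:
            raise ValueError("target_subset does not intersect the graph")
        graph = graph.subgraph(keep).copy()
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot render an empty graph")

    pos = _layered_positions(graph)
    tfs = [n for n in graph.nodes if graph.nodes[n]["kind"] == "gene"
           and graph.nodes[n].get("role") in ("tf", "both")]
    mids = [n for n in graph.nodes if graph.nodes[n]["kind"] == "model"]
    targets = [n for n in graph.nodes if graph.nodes[n]["kind"] == "gene"
               and graph.nodes[n].get("role") == "target"]

    height = max(4.0, 0.28 * max(len(tfs), len(mids), len(targets), 1))
    fig, ax = plt.subplots(figsize=(9, height))
    nx.draw_networkx_edges(graph, pos, ax=ax, edge_color="grey", arrows=True,
                           arrowsize=8, width=0.8)
    nx.draw_networkx_nodes(graph, pos, nodelist=tfs, node_shape="s",
                           node_color="#cc6600", node_size=350, ax=ax)
    nx.draw_networkx_nodes(graph, pos, nodelist=mids, node_shape="o",
                           node_color="#ffbb66", node_size=420, ax=ax)
    nx.draw_networkx_nodes(graph, pos, nodelist=targets, node_shape="o",
                           node_color="#3366cc", node_size=420, ax=ax)
    labels = {n: (f"{graph.nodes[n]['rmse']:.2f}" if graph.nodes[n]["kind"] == "model"
                  else n) for n in graph.nodes}
    nx.draw_networkx_labels(graph, pos, labels=labels, font_size=6, ax=ax)
    ax.set_axis_off()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return out_path
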
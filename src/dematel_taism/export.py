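"""Topology export: layered digraphs in DOT and GraphML.

Nodes are the factor codes, ranked by their level in the chosen
extraction (UP or DOWN); edges come from the general skeleton and are
labelled with the selected valued matrix (TS influence values or WS loop
markers).  Edges inside a loop are drawn double-headed, matching the
convention that a chain closed on itself represents a loop.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx

from .errors import PipelineError
from .hierarchy import Mode
from .report import RunReport

__all__ = ["topology_graph", "export_topology"]


def topology_graph(report: RunReport, value_source: str = "TS") -> nx.DiGraph:
    """Build the skeleton digraph with level and value annotations."""
    if value_source not in ("TS", "WS"):
        raise PipelineError(f"unknown value source {value_source!r}; use 'TS' or 'WS'")
    values = report.valued.TS if value_source == "TS" else report.valued.WS
    loop_of = report.reachability.component_index
    in_loop = {c for loop in report.reachability.loops for c in loop}

    G = nx.DiGraph()
    for code in report.system.codes:
        info = report.system.info(code)
        G.add_node(
            code,
            name=info.name,
            dimension=info.dimension,
            level_up=report.up.level_of(code),
            level_down=report.down.level_of(code),
        )
    idx = {c: i for i, c in enumerate(report.system.codes)}
    n = report.system.n
    for i in range(n):
        for j in range(n):
            if report.skeleton.S_general[i, j]:
                a, b = report.system.codes[i], report.system.codes[j]
                G.add_edge(a, b, weight=float(values[i, j]),
                           loop=bool(a in in_loop and loop_of[a] == loop_of[b]))
    # WS marks the whole loop clique, not only the threaded cycle
    if value_source == "WS":
        for loop in report.reachability.loops:
            for a in loop:
                for b in loop:
                    if a != b:
                        G.add_edge(a, b, weight=1.0, loop=True)
    return G


def _dot(report: RunReport, G: nx.DiGraph, mode: Mode, precision: int) -> str:
    part = report.up if mode is Mode.UP else report.down
    lines = [
        "digraph taism {",
        "  rankdir=BT;",
        '  node [shape=box, style=rounded];',
        f'  label="{mode.value} (level 0 on top)";',
    ]
    for k, level in enumerate(part.levels):
        members = " ".join(f'"{c}";' for c in level)
        lines.append(f"  {{ rank=same; {members} }}  /* level {k} */")
    for code in G.nodes:
        name = G.nodes[code]["name"]
        lines.append(f'  "{code}" [tooltip="{name}"];')
    seen_pairs = set()
    for a, b, data in G.edges(data=True):
        if (b, a) in seen_pairs:
            continue
        label = f"{data['weight']:.{precision}f}".rstrip("0").rstrip(".")
        attrs = [f'label="{label}"']
        if data["loop"]:
            if G.has_edge(b, a):
                attrs.append("dir=both")
                seen_pairs.add((a, b))
            attrs.append("color=firebrick")
        lines.append(f'  "{a}" -> "{b}" [{", ".join(attrs)}];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_topology(
    report: RunReport,
    path: str | Path,
    fmt: str = "dot",
    value_source: str = "TS",
    mode: Mode | str = Mode.UP,
) -> Path:
    """Write the layered topology to ``path`` in DOT or GraphML."""
    mode = Mode(mode)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    G = topology_graph(report, value_source)
    if fmt == "dot":
        path.write_text(
            _dot(report, G, mode, report.config.precision_skeleton), encoding="utf-8"
        )
    elif fmt == "graphml":
        nx.write_graphml(G, path)
    else:
        raise PipelineError(f"unknown export format {fmt!r}; use 'dot' or 'graphml'")
    return path
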
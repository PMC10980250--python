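"""Construction of the two-layer audio-visual network (AV-net) and its
viseme-only ablation (V-net).

The audio layer has one node per phonological word-form ("A" suffix) with
edges between forms one phoneme edit apart.  The visual layer has one node
per distinct viseme string ("V" suffix) — i.e. one node per lexical
equivalence class — with edges between viseme strings that differ by a
single-position substitution.  Interlayer edges tie each word to the viseme
node of its transcription.  All edges are undirected and unweighted; node
attribute ``layer`` is "audio"|"visual", node attribute ``payload`` the bare
string, edge attribute ``edge_type`` is "phono"|"viseme"|"interlayer".
"""

from __future__ import annotations

from itertools import combinations
from pathlib import Path

import networkx as nx
import pandas as pd

from .lexicon import (Lexicon, VisemeMap, WordEntry, default_viseme_map,
                      edit_distance_is_one, lec_partition, to_visemes)

__all__ = [
    "audio_id", "visual_id",
    "build_phono_layer", "build_viseme_layer", "build_av_net", "build_v_net",
    "components", "lec_degree",
    "write_graphml", "read_graphml", "write_edge_lists", "graph_summary",
]

AUDIO_SUFFIX = "A"
VISUAL_SUFFIX = "V"


def audio_id(phono: str) -> str:
    return phono + AUDIO_SUFFIX


def visual_id(viseme: str) -> str:
    return viseme + VISUAL_SUFFIX


def build_phono_layer(lexicon: Lexicon) -> nx.Graph:
    """Audio layer: one node per word, edges at phoneme edit distance 1."""
    g = nx.Graph()
    words = lexicon.phono_strings()
    for w in words:
        g.add_node(audio_id(w), layer="audio", payload=w)
    # bucket by length so the pairwise scan only touches candidate pairs
    by_len: dict[int, list[str]] = {}
    for w in words:
        by_len.setdefault(len(w), []).append(w)
    for length, group in by_len.items():
        for a, b in _substitution_pairs(group):
            g.add_edge(audio_id(a), audio_id(b), edge_type="phono")
        for a in group:
            for b in by_len.get(length + 1, ()):
                if edit_distance_is_one(a, b):
                    g.add_edge(audio_id(a), audio_id(b), edge_type="phono")
    return g


def _substitution_pairs(strings: list[str]):
    """All pairs of equal-length strings differing in exactly one position."""
    buckets: dict[str, list[str]] = {}
    for s in strings:
        for i in range(len(s)):
            buckets.setdefault(f"{i}:{s[:i]}\x00{s[i+1:]}", []).append(s)
    seen: set[tuple[str, str]] = set()
    for group in buckets.values():
        for a, b in combinations(group, 2):
            pair = (a, b) if a < b else (b, a)
            if pair not in seen:
                seen.add(pair)
                yield pair


def build_viseme_layer(partition: dict[str, set[WordEntry]]) -> nx.Graph:
    """Visual layer: one node per LEC, edges between viseme strings of equal
    length that differ by a single-position substitution."""
    if not partition:
        raise ValueError("empty LEC partition")
    g = nx.Graph()
    for v in partition:
        g.add_node(visual_id(v), layer="visual", payload=v)
    by_len: dict[int, list[str]] = {}
    for v in partition:
        by_len.setdefault(len(v), []).append(v)
    for group in by_len.values():
        for a, b in _substitution_pairs(group):
            g.add_edge(visual_id(a), visual_id(b), edge_type="viseme")
    return g


def build_av_net(lexicon: Lexicon, vmap: VisemeMap | None = None) -> nx.Graph:
    """The full two-layer network: audio layer + visual layer + one
    interlayer edge per word, linking it to its viseme node."""
    vmap = vmap or default_viseme_map()
    partition = lec_partition(lexicon, vmap)
    g: nx.Graph = nx.compose(build_phono_layer(lexicon),
                             build_viseme_layer(partition))
    for e in lexicon:
        g.add_edge(audio_id(e.phono), visual_id(to_visemes(e.phono, vmap)),
                   edge_type="interlayer")
    return g


def build_v_net(av: nx.Graph) -> nx.Graph:
    """Ablate the audio layer: keep only visual nodes and viseme edges."""
    visual = [n for n, d in av.nodes(data=True) if d["layer"] == "visual"]
    v = av.subgraph(visual).copy()
    drop = [(u, w) for u, w, d in v.edges(data=True)
            if d["edge_type"] != "viseme"]
    v.remove_edges_from(drop)
    return v


def components(g: nx.Graph) -> list[set[str]]:
    """Connected components as node sets, largest first."""
    return sorted(nx.connected_components(g), key=len, reverse=True)


def lec_degree(node: str, g: nx.Graph) -> int:
    """Within-layer degree of a visual node: the number of other LECs one
    viseme substitution away.  Interlayer edges do not count."""
    if node not in g:
        raise KeyError(f"unknown node {node!r}")
    if g.nodes[node]["layer"] != "visual":
        raise ValueError(f"{node!r} is not a visual node")
    return sum(1 for _, _, d in g.edges(node, data=True)
               if d["edge_type"] == "viseme")


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))


def write_edge_lists(g: nx.Graph, edges_path: str | Path,
                     nodes_path: str | Path) -> None:
    pd.DataFrame(
        [(u, v, d["edge_type"]) for u, v, d in g.edges(data=True)],
        columns=["source", "target", "edge_type"],
    ).to_csv(edges_path, index=False)
    pd.DataFrame(
        [(n, d["layer"], d["payload"]) for n, d in g.nodes(data=True)],
        columns=["id", "layer", "payload"],
    ).to_csv(nodes_path, index=False)


def graph_summary(g: nx.Graph) -> dict[str, int]:
    layers = nx.get_node_attributes(g, "layer")
    types = nx.get_edge_attributes(g, "edge_type")
    return {
        "n_nodes": g.number_of_nodes(),
        "n_audio_nodes": sum(1 for l in layers.values() if l == "audio"),
        "n_visual_nodes": sum(1 for l in layers.values() if l == "visual"),
        "n_edges": g.number_of_edges(),
        "n_phono_edges": sum(1 for t in types.values() if t == "phono"),
        "n_viseme_edges": sum(1 for t in types.values() if t == "viseme"),
        "n_interlayer_edges": sum(1 for t in types.values() if t == "interlayer"),
        "n_components": nx.number_connected_components(g),
    }
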
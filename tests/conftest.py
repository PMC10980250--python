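"""Shared fixtures and independent oracles.

Oracles here are deliberately naive (dynamic-programming edit distance,
dense matrix powers, brute-force scans) so they stay independent of the
library's optimised code paths.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from avnet.lexicon import Lexicon, WordEntry


# ---------------------------------------------------------------- oracles

def dp_edit_distance(a: str, b: str) -> int:
    """Full Levenshtein distance by dynamic programming."""
    la, lb = len(a), len(b)
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                         prev[j - 1] + (a[i - 1] != b[j - 1]))
        prev = cur
    return prev[lb]


def dense_operator(g: nx.Graph, retention: float, decay: float,
                   nodelist: list) -> np.ndarray:
    """Per-step diffusion operator built entry-by-entry from its definition:
    column j sends (1-r)(1-d)/deg(j) to each neighbor and keeps r (or
    everything, if j is isolated)."""
    n = len(nodelist)
    idx = {v: i for i, v in enumerate(nodelist)}
    M = np.zeros((n, n))
    for v in nodelist:
        j = idx[v]
        deg = g.degree(v)
        if deg == 0:
            M[j, j] = 1.0
            continue
        M[j, j] = retention
        for u in g.neighbors(v):
            M[idx[u], j] = (1.0 - retention) * (1.0 - decay) / deg
    return M


def bfs_components(g: nx.Graph) -> list[set]:
    """Connected components by explicit breadth-first search."""
    seen: set = set()
    comps = []
    for start in g.nodes:
        if start in seen:
            continue
        comp = {start}
        queue = [start]
        while queue:
            node = queue.pop(0)
            for nbr in g.neighbors(node):
                if nbr not in comp:
                    comp.add(nbr)
                    queue.append(nbr)
        seen |= comp
        comps.append(comp)
    return sorted(comps, key=len, reverse=True)


# ---------------------------------------------------------------- fixtures

@pytest.fixture
def toy_lexicon() -> Lexicon:
    """Five CVC words spanning two LECs plus outliers.

    pEt, bEt -> LEC "bes"; bEl, mEn -> LEC "ben"; kup -> LEC "kob".
    """
    return Lexicon([
        WordEntry("pet", "pEt", 6.8, 42.0, "easy"),
        WordEntry("bet", "bEt", 6.5, 18.0, "hard"),
        WordEntry("bell", "bEl", 6.9, 30.0, "easy"),
        WordEntry("men", "mEn", 6.7, 55.0, "hard"),
        WordEntry("coop", "kup", 5.5, 3.0, "unlabeled"),
    ])


@pytest.fixture
def random_graphs():
    """A batch of small random graphs (isolates included) for oracles."""
    rng = np.random.default_rng(42)
    graphs = []
    for i in range(30):
        n = int(rng.integers(2, 51))
        p = float(rng.uniform(0.02, 0.3))
        graphs.append(nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31))))
    return graphs
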
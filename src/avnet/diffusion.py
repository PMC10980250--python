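"""Diffusion of activation on an undirected, unweighted graph.

At each synchronous time step a node keeps a fraction ``retention`` of its
activation; of the remainder, a fraction ``1 - decay`` is split equally among
its neighbors.  A node with no neighbors keeps everything, so with decay 0 and
suppress 0 total activation is conserved exactly.  After each step, any node
whose activation falls strictly below ``suppress`` is zeroed.  Edge types are
ignored: the process runs on the flat graph, so the same engine serves the
single-layer and the multilayer networks.

This is a plain linear diffusion — no inhibition, thresholds, or resting
levels — closer to diffusion in physics than to classic interactive-activation
models of the lexicon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["DiffusionParams", "ActivationTrace", "step", "run",
           "transition_operator"]


@dataclass(frozen=True)
class DiffusionParams:
    """Simulation constants.  Defaults are the standard settings used
    throughout: 20 units of seed activation, retention 0.5, no decay, no
    suppression, 5 time steps (activation is near asymptote by then)."""

    initial_activation: float = 20.0
    retention: float = 0.5
    decay: float = 0.0
    suppress: float = 0.0
    steps: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.retention <= 1.0:
            raise ValueError("retention must be in [0, 1]")
        if not 0.0 <= self.decay <= 1.0:
            raise ValueError("decay must be in [0, 1]")
        if self.suppress < 0:
            raise ValueError("suppress must be >= 0")
        if self.steps < 0 or self.steps != int(self.steps):
            raise ValueError("steps must be a nonnegative integer")
        if self.initial_activation < 0:
            raise ValueError("initial activation must be >= 0")


@dataclass
class ActivationTrace:
    """Per-step activation states, t = 0 .. T (state 0 is the seeding)."""

    states: list[dict[str, float]] = field(default_factory=list)

    @property
    def final(self) -> dict[str, float]:
        return self.states[-1]

    def __len__(self) -> int:
        return len(self.states)

    def activation(self, node: str, t: int) -> float:
        return self.states[t][node]

    def total(self, t: int) -> float:
        return sum(self.states[t].values())

    def to_frame(self) -> pd.DataFrame:
        rows = [(t, node, a)
                for t, state in enumerate(self.states)
                for node, a in state.items()]
        return pd.DataFrame(rows, columns=["t", "node", "activation"])


def step(state: dict[str, float], g: nx.Graph,
         params: DiffusionParams) -> dict[str, float]:
    """One synchronous update of the whole network.

    Every node's new value is computed from the time-t state: retained share
    plus the equal splits received from each neighbor.
    """
    r, d = params.retention, params.decay
    new = dict.fromkeys(g.nodes, 0.0)
    for node, a in state.items():
        if a == 0.0:
            continue
        degree = g.degree(node)
        if degree == 0:
            new[node] += a          # isolates have nowhere to disperse
            continue
        new[node] += r * a
        share = (1.0 - r) * (1.0 - d) * a / degree
        for nbr in g.neighbors(node):
            new[nbr] += share
    if params.suppress > 0.0:
        for node, a in new.items():
            if a < params.suppress:
                new[node] = 0.0
    return new


def run(g: nx.Graph, seeds: dict[str, float],
        params: DiffusionParams) -> ActivationTrace:
    """Iterate :func:`step` from a seed assignment for ``params.steps`` steps."""
    missing = [n for n in seeds if n not in g]
    if missing:
        raise KeyError(f"seed nodes not in graph: {missing}")
    state = dict.fromkeys(g.nodes, 0.0)
    state.update(seeds)
    trace = ActivationTrace([state])
    for _ in range(params.steps):
        state = step(state, g, params)
        trace.states.append(state)
    return trace


def transition_operator(g: nx.Graph, params: DiffusionParams,
                        nodelist: list[str]) -> sp.csr_matrix:
    """The per-step linear operator M as a sparse matrix over ``nodelist``:
    x(t+1) = M @ x(t), with M = r*I + (1-r)(1-d) * A @ D^-1 and isolated
    nodes mapped to themselves.  Used as a fast path for batched runs; the
    per-node :func:`step` is the reference semantics.
    """
    r, d = params.retention, params.decay
    n = len(nodelist)
    adj = nx.to_scipy_sparse_array(g, nodelist=nodelist, format="csr",
                                   dtype=float)
    degs = np.asarray(adj.sum(axis=0)).ravel()
    inv = np.divide(1.0, degs, out=np.zeros_like(degs), where=degs > 0)
    spread = (1.0 - r) * (1.0 - d) * (adj @ sp.diags(inv))
    keep = np.where(degs > 0, r, 1.0)
    return (sp.diags(keep) + spread).tocsr()
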
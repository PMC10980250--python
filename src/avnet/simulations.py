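"""Word-identification simulations on the AV-net and V-net.

Each stimulus word is presented in isolation (activation reset between
trials).  Five presentation conditions are simulated:

========  =======  ===============================  ==============
column    network  seeded nodes (20 units each)     readout node
========  =======  ===============================  ==============
sim1      AV-net   phono node + viseme node         phono node
sim2      AV-net   phono node                       phono node
sim3      AV-net   viseme node                      phono node
sim4_av   AV-net   viseme node                      viseme node
sim4_v    V-net    viseme node                      viseme node
========  =======  ===============================  ==============

sim1 models audio-visual presentation, sim2 audio-only, sim3 visual-only
(the readout stays on the phonological node because the task response is a
word, not a lip gesture), and the sim4 pair contrasts visual identification
with and without access to the phonological layer.  Because the process is
linear with decay 0, sim1 equals sim2 + sim3 per word exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .diffusion import DiffusionParams, run, transition_operator
from .graphs import audio_id, build_av_net, build_v_net, visual_id
from .lexicon import Lexicon, VisemeMap, WordEntry, default_viseme_map, to_visemes

__all__ = ["StimulusSet", "SimulationResult", "run_condition", "run_suite",
           "CONDITIONS"]

CONDITIONS = ("sim1", "sim2", "sim3", "sim4_av", "sim4_v")


@dataclass
class StimulusSet:
    """Easy/hard stimulus words for the identification task."""

    items: list[WordEntry]
    balanced: bool = True
    initial_consonant_matched: bool = False

    def __post_init__(self) -> None:
        bad = [w.orthography for w in self.items
               if w.difficulty not in ("easy", "hard")]
        if bad:
            raise ValueError(f"stimuli must be labeled easy or hard: {bad}")
        if self.balanced:
            n_easy = sum(1 for w in self.items if w.difficulty == "easy")
            n_hard = len(self.items) - n_easy
            if n_easy != n_hard:
                raise ValueError(
                    f"unbalanced stimulus set: {n_easy} easy vs {n_hard} hard")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)


@dataclass
class SimulationResult:
    """Per-word final activations for every condition, as a tidy table with
    columns word, phono, viseme, difficulty, sim1..sim4_v."""

    table: pd.DataFrame
    params: DiffusionParams = field(default_factory=DiffusionParams)

    def condition(self, name: str) -> pd.Series:
        return self.table[name]

    def by_difficulty(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        easy = self.table.loc[self.table.difficulty == "easy", name]
        hard = self.table.loc[self.table.difficulty == "hard", name]
        return easy.to_numpy(), hard.to_numpy()


def run_condition(g: nx.Graph, seed_nodes: list[str], readout: str,
                  params: DiffusionParams | None = None) -> float:
    """One independent trial: seed each listed node with the initial
    activation, diffuse for ``params.steps`` steps, read one node."""
    params = params or DiffusionParams()
    if readout not in g:
        raise KeyError(f"readout node {readout!r} not in graph")
    seeds = {n: params.initial_activation for n in seed_nodes}
    return run(g, seeds, params).final[readout]


def _batched_finals(g: nx.Graph, seed_cols: list[dict[str, float]],
                    readouts: list[str],
                    params: DiffusionParams) -> np.ndarray:
    """Final readout activation for many independent trials at once.

    Stacks the seed vectors as columns and applies the per-step linear
    operator T times.  Valid whenever suppress is 0 (the operator is then the
    exact per-node update); otherwise falls back to the per-trial engine.
    """
    if params.suppress > 0.0:
        return np.array([
            run(g, seeds, params).final[r]
            for seeds, r in zip(seed_cols, readouts)
        ])
    nodelist = list(g.nodes)
    index = {n: i for i, n in enumerate(nodelist)}
    M = transition_operator(g, params, nodelist)
    X = np.zeros((len(nodelist), len(seed_cols)))
    for j, seeds in enumerate(seed_cols):
        for node, a in seeds.items():
            X[index[node], j] = a
    for _ in range(params.steps):
        X = M @ X
    return np.array([X[index[r], j] for j, r in enumerate(readouts)])


def run_suite(lexicon: Lexicon, stimuli: StimulusSet,
              params: DiffusionParams | None = None,
              vmap: VisemeMap | None = None) -> SimulationResult:
    """Run all five conditions for every stimulus word.

    Builds the AV-net from the lexicon and the V-net by ablating it, then
    simulates each word in isolation under each seeding scheme.
    """
    params = params or DiffusionParams()
    vmap = vmap or default_viseme_map()
    missing = [w.orthography for w in stimuli if w.phono not in lexicon]
    if missing:
        raise KeyError(f"stimulus words absent from lexicon: {missing}")

    av = build_av_net(lexicon, vmap)
    vnet = build_v_net(av)
    a0 = params.initial_activation

    av_seed_cols: list[dict[str, float]] = []
    av_readouts: list[str] = []
    v_seed_cols: list[dict[str, float]] = []
    v_readouts: list[str] = []
    rows = []
    for w in stimuli:
        pA = audio_id(w.phono)
        viseme = to_visemes(w.phono, vmap)
        vV = visual_id(viseme)
        # conditions on the AV-net: sim1, sim2, sim3, sim4_av
        av_seed_cols += [{pA: a0, vV: a0}, {pA: a0}, {vV: a0}, {vV: a0}]
        av_readouts += [pA, pA, pA, vV]
        v_seed_cols.append({vV: a0})
        v_readouts.append(vV)
        rows.append((w.orthography, w.phono, viseme, w.difficulty))

    av_vals = _batched_finals(av, av_seed_cols, av_readouts, params)
    v_vals = _batched_finals(vnet, v_seed_cols, v_readouts, params)

    table = pd.DataFrame(rows, columns=["word", "phono", "viseme",
                                        "difficulty"])
    table["sim1"] = av_vals[0::4]
    table["sim2"] = av_vals[1::4]
    table["sim3"] = av_vals[2::4]
    table["sim4_av"] = av_vals[3::4]
    table["sim4_v"] = v_vals
    return SimulationResult(table=table, params=params)
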
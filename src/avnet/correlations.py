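"""Word-level correlations linking simulation, network structure, and
behavior.

Three quantities are joined per stimulus word: the visual-only simulated
activation (viseme node seeded, phonological node read out), the within-layer
degree of the word's lexical equivalence class, and human visual-only
identification accuracy (percent correct).  The expected sign pattern is
(+, -, -): activation tracks accuracy positively, while a more confusable
LEC (higher degree) depresses both.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .graphs import lec_degree, visual_id
from .simulations import SimulationResult
from .stats import TestResult, pearson_r

__all__ = ["build_dataset", "run_correlations"]


def build_dataset(sim: SimulationResult, av: nx.Graph,
                  behavior: pd.DataFrame) -> pd.DataFrame:
    """Join sim3 activation, LEC degree, and behavioral accuracy per word.

    Raises ``KeyError`` listing any stimulus word without a behavioral row.
    """
    sim_tab = sim.table[["word", "phono", "viseme", "difficulty", "sim3"]]
    beh = behavior[["stimulus_phono", "accuracy_pct"]].rename(
        columns={"stimulus_phono": "phono"})
    merged = sim_tab.merge(beh, on="phono", how="left", validate="1:1")
    missing = merged.loc[merged.accuracy_pct.isna(), "word"].tolist()
    if missing:
        raise KeyError(f"no behavioral data for words: {missing}")
    merged["lec_degree"] = [lec_degree(visual_id(v), av)
                            for v in merged.viseme]
    return merged.rename(columns={"sim3": "activation"})


def run_correlations(ds: pd.DataFrame) -> dict[str, TestResult]:
    """The three product-moment correlations over the joined dataset."""
    return {
        "activation_vs_accuracy": pearson_r(ds.activation, ds.accuracy_pct),
        "lec_degree_vs_accuracy": pearson_r(ds.lec_degree, ds.accuracy_pct),
        "lec_degree_vs_activation": pearson_r(ds.lec_degree, ds.activation),
    }
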
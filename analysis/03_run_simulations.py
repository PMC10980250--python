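"""Simulate word identification under the five presentation conditions.

Each of the 76 stimulus words is presented in isolation with 20 units of
activation diffusing for 5 steps (retention 0.5, no decay): audio-visual
(sim1), audio-only (sim2), visual-only (sim3), and viseme readout in the
intact network (sim4_av) versus the phonology-ablated V-net (sim4_v).
Writes the per-word table to results/simulations.csv.
"""

from pathlib import Path

from avnet.diffusion import DiffusionParams
from avnet.lexicon import load_lexicon
from avnet.simulations import StimulusSet, run_suite

import pandas as pd

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    lexicon = load_lexicon(ROOT / "data" / "lexicon.csv")
    stim_df = pd.read_csv(ROOT / "data" / "stimuli.csv", dtype=str)
    stimuli = StimulusSet([lexicon[p].with_difficulty(d)
                           for p, d in zip(stim_df.phono, stim_df.difficulty)])

    params = DiffusionParams()  # 20 units, r=0.5, d=0, s=0, T=5
    result = run_suite(lexicon, stimuli, params)
    result.table.to_csv(ROOT / "simulations.csv", index=False)

    means = result.table.groupby("difficulty")[
        ["sim1", "sim2", "sim3", "sim4_av", "sim4_v"]].mean().round(3)
    print(f"{len(result.table)} words x 5 conditions "
          f"(T={params.steps}, r={params.retention})")
    print(means.to_string())
    print("\nhigher activation at the readout node = more accurate "
          "identification")


if __name__ == "__main__":
    main()
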
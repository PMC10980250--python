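"""Easy-versus-hard group comparisons of the simulated activations.

One-tailed pooled t-tests (easy > hard expected a priori) in every
condition, plus the two-tailed paired test of the audio-visual boost
(sim1 vs sim2 on the same words).  Writes results/group_comparisons.csv.
"""

from pathlib import Path

import pandas as pd

from avnet.stats import t_independent, t_paired

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = pd.read_csv(ROOT / "simulations.csv")
    easy = table[table.difficulty == "easy"]
    hard = table[table.difficulty == "hard"]

    rows = []
    for cond in ("sim1", "sim2", "sim3", "sim4_av", "sim4_v"):
        res = t_independent(easy[cond], hard[cond], tails="one")
        rows.append({
            "analysis": f"easy_vs_hard_{cond}",
            "mean_easy": easy[cond].mean(), "sd_easy": easy[cond].std(),
            "mean_hard": hard[cond].mean(), "sd_hard": hard[cond].std(),
            "t": res.statistic, "df": res.df, "p": res.p_value,
            "tails": res.tails,
        })
        verdict = "easy > hard" if res.p_value < .05 else "no reliable difference"
        print(f"{cond}: easy {easy[cond].mean():.3f} vs hard "
              f"{hard[cond].mean():.3f} units; t({res.df:.0f}) = "
              f"{res.statistic:.2f}, one-tailed p = {res.p_value:.4f} "
              f"-> {verdict}")

    boost = t_paired(table.sim1, table.sim2, tails="two")
    rows.append({"analysis": "sim1_vs_sim2_paired",
                 "mean_easy": table.sim1.mean(), "sd_easy": table.sim1.std(),
                 "mean_hard": table.sim2.mean(), "sd_hard": table.sim2.std(),
                 "t": boost.statistic, "df": boost.df, "p": boost.p_value,
                 "tails": boost.tails})
    print(f"\naudio-visual boost: sim1 {table.sim1.mean():.3f} vs sim2 "
          f"{table.sim2.mean():.3f} units; paired t({boost.df:.0f}) = "
          f"{boost.statistic:.2f}, p = {boost.p_value:.3g}")

    pd.DataFrame(rows).to_csv(ROOT / "group_comparisons.csv", index=False)


if __name__ == "__main__":
    main()
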
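"""Classify and test the visual-only identification errors.

For every stimulus/modal-error pair: is the error in the same lexical
equivalence class, is it a phonological neighbor, and — when the LEC is
wrong — what single-viseme edit (and position) produced it?  Runs the four
chi-square tests over the resulting tables.  Writes error_lec_table.csv,
error_edit_table.csv, and error_tests.csv under results/.
"""

from pathlib import Path

import pandas as pd

from avnet.error_analysis import (load_behavior, records_from_behavior,
                                  run_error_tests, tabulate)
from avnet.lexicon import load_lexicon

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    lexicon = load_lexicon(ROOT / "data" / "lexicon.csv")
    behavior = load_behavior(ROOT / "data" / "behavior.csv")
    stim_df = pd.read_csv(ROOT / "data" / "stimuli.csv", dtype=str)
    stimuli = [lexicon[p].with_difficulty(d)
               for p, d in zip(stim_df.phono, stim_df.difficulty)]

    records = records_from_behavior(behavior, lexicon, stimuli=stimuli)
    table = tabulate(records)
    table.lec_table.to_csv(ROOT / "error_lec_table.csv", index=False)
    table.edit_table.to_csv(ROOT / "error_edit_table.csv", index=False)

    print(f"{table.n_records} modal errors: "
          f"{table.total(same_lec=False)} in a different LEC, "
          f"{table.total(same_lec=True)} in the same LEC; "
          f"{table.total(neighbor=True)} were phonological neighbors")

    rows = []
    for name, res in run_error_tests(table).items():
        rows.append({"analysis": name, "chi2": res.statistic, "df": res.df,
                     "p": res.p_value, "n": res.n})
        print(f"{name}: chi2({res.df:.0f}) = {res.statistic:.2f}, "
              f"p = {res.p_value:.3f}")
    pd.DataFrame(rows).to_csv(ROOT / "error_tests.csv", index=False)


if __name__ == "__main__":
    main()
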
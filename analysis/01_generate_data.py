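"""Generate the synthetic study materials.

Draws a 1,000-word CVC lexicon with Zipf-skewed phoneme use and log-normal
word frequencies, selects 38 lexically easy + 38 lexically hard stimulus
words with matched initial consonants, and simulates a visual-only
identification experiment over them.  Writes lexicon.csv, stimuli.csv, and
behavior.csv under results/data/.
"""

from pathlib import Path

import pandas as pd

from avnet.lexicon import neighborhood_density
from avnet.synthetic import (LexiconGenSpec, ResponseGenSpec,
                             generate_lexicon, label_easy_hard,
                             simulate_visual_identification)

SEED = 20240501
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    lexicon = generate_lexicon(LexiconGenSpec(n_words=1000, seed=SEED))
    stimuli = label_easy_hard(lexicon, k_per_group=38, seed=SEED + 1)
    behavior = simulate_visual_identification(
        lexicon, stimuli, ResponseGenSpec(seed=SEED + 2))

    lexicon.to_frame().to_csv(OUT / "lexicon.csv", index=False)
    pd.DataFrame(
        [(w.orthography, w.phono, w.difficulty) for w in stimuli],
        columns=["orthography", "phono", "difficulty"],
    ).to_csv(OUT / "stimuli.csv", index=False)
    behavior.to_csv(OUT / "behavior.csv", index=False)

    dens = neighborhood_density(lexicon)
    easy = [w for w in stimuli if w.difficulty == "easy"]
    hard = [w for w in stimuli if w.difficulty == "hard"]
    print(f"lexicon: {len(lexicon)} CVC words")
    print(f"stimuli: {len(easy)} easy + {len(hard)} hard, "
          "initial consonants matched")
    print(f"  easy: mean freq {sum(w.frequency for w in easy)/len(easy):.1f} "
          f"per million, mean density {sum(dens[w.phono] for w in easy)/len(easy):.1f}")
    print(f"  hard: mean freq {sum(w.frequency for w in hard)/len(hard):.1f} "
          f"per million, mean density {sum(dens[w.phono] for w in hard)/len(hard):.1f}")
    print(f"behavior: mean visual-only accuracy "
          f"{behavior.accuracy_pct.mean():.2f}% correct")


if __name__ == "__main__":
    main()
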
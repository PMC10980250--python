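# avnet

Multilayer audio-visual lexical networks for studying visual speech
perception (lip-reading) *in silico*.

When a word is spoken, a viewer sees lip and jaw gestures that collapse many
phonemes into a single *viseme*: `p`, `b`, and `m` are visually
indistinguishable, so *pet* and *bet* look identical on the lips. Words that
share a full viseme transcription form a *lexical equivalence class* (LEC),
and the confusability structure among LECs is a strong predictor of how
accurately people identify silently spoken words. `avnet` builds a
two-layer network — an audio layer of phonological word-forms linked at
phoneme edit distance 1, a visual layer of LEC nodes linked by
single-viseme substitution, and interlayer edges tying each word to its
viseme node (the **AV-net**) — plus the phonology-ablated **V-net**, and
simulates word identification as diffusion of activation:

> per time step, each node retains a fraction *r* of its activation and
> disperses the rest equally to its neighbors; with retention 0.5, no
> decay, and 5 steps, a stimulus node seeded with 20 units yields a final
> readout whose magnitude tracks identification accuracy.

The package is for cognitive scientists and speech engineers who want to
probe audio-visual integration effects (easy/hard lexical competition, the
audio-visual boost, error patterns in lip-reading) before running human
experiments. It is organised as a library (`src/avnet/`: lexicon handling,
graph construction, the diffusion engine, simulations, statistics, error
analysis, correlations, and synthetic-data generators), a CLI (`avnet
synth|build|simulate|analyze`), and a numbered analysis pipeline
(`analysis/01…06`).

## Worked example

```python
import networkx as nx
from avnet import DiffusionParams, run, to_visemes
from avnet.lexicon import Lexicon, WordEntry, lec_partition

# viseme transcription and LECs
print(to_visemes("pEt"))          # bes   (p->b, E->e, t->s)
lex = Lexicon([WordEntry("bell", "bEl"), WordEntry("men", "mEn")])
print(lec_partition(lex).keys())  # dict_keys(['ben'])  - one shared LEC

# the diffusion walk-through: a hub with two neighbors, seeded with 20 units
star = nx.star_graph(2)
trace = run(star, {0: 20.0}, DiffusionParams(steps=2))
print(trace.states[1])            # {0: 10.0, 1: 5.0, 2: 5.0}
print(trace.states[2][0])         # 10.0  - the leaves return half of their 5
```

Running the full synthetic study (`python analysis/01_generate_data.py`
through `06_error_patterns.py`) generates a 1,000-word CVC lexicon, selects
38 easy + 38 hard stimuli with matched initial consonants, and prints, for
example:

```
sim1: easy 1.610 vs hard 1.254 units; t(74) = 7.10, one-tailed p = 0.0000 -> easy > hard
audio-visual boost: sim1 1.432 vs sim2 1.206 units; paired t(75) = 18.15, p = 3.73e-29
activation_vs_accuracy: r = +0.82, p = 3.1e-19, n = 76
lec_degree_vs_accuracy: r = -0.87, p = 3.1e-24, n = 76
```

i.e. lexically easy words out-activate hard ones in every audio-involving
condition, seeding the viseme node on top of the word node adds a reliable
boost, and words in highly confusable LECs are identified worse both by the
network and by the simulated viewers. Tables land under `results/`.

See `docs/methods.md` for the model, parameter defaults, and the synthetic
generators' assumptions.

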
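"""Synthetic lexicons, easy/hard stimulus sets, and visual-only behavior.

The generators emulate the statistical structure the analysis pipeline
assumes, so every stage runs end-to-end without external data:

* a lexicon of distinct consonant-vowel-consonant (CVC) forms over the
  computer-readable phoneme alphabet, with log-normally distributed word
  frequencies (the standard heavy-tailed lexical assumption) and familiarity
  ratings in the "known word" range;
* an easy/hard stimulus set — easy words are frequent with few phonological
  neighbors, hard words rare with many — with the multiset of initial
  consonants matched between groups so the two groups present identical
  onsets to a lip-reader;
* a visual-only identification table: per-word accuracy falls with the size
  and the within-layer degree of the word's lexical equivalence class (the
  two confusability axes), and the modal incorrect response is drawn mostly
  from the stimulus's own LEC or from LECs one viseme substitution away,
  weighted by word frequency.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .graphs import build_viseme_layer, lec_degree, visual_id
from .lexicon import (CONSONANT_CLASSES, VOWEL_CLASSES, Lexicon, VisemeMap,
                      WordEntry, default_viseme_map, lec_partition,
                      neighborhood_density, to_visemes)
from .simulations import StimulusSet

__all__ = ["LexiconGenSpec", "ResponseGenSpec", "generate_lexicon",
           "label_easy_hard", "simulate_visual_identification",
           "DEFAULT_CONSONANT_WEIGHTS", "DEFAULT_VOWEL_WEIGHTS"]

ALL_CONSONANTS = "".join(CONSONANT_CLASSES.values())
ALL_VOWELS = "".join(VOWEL_CLASSES.values())

# Default phoneme weights: Zipf (1/rank) over an English-like frequency
# ranking of the transcription alphabet.  Skewed phoneme frequencies are what
# couple a word's phonological neighborhood density to the size and degree of
# its lexical equivalence class, as in real lexicons; with uniform phoneme
# use, density decouples from viseme-layer confusability.
_CONSONANTS_BY_RANK = "tnsrdlkDmzwhbpgfvGyCJST Z".replace(" ", "")
_VOWELS_BY_RANK = "@IiEea^uoUOYRcW"
DEFAULT_CONSONANT_WEIGHTS = {c: 1.0 / (i + 1)
                             for i, c in enumerate(_CONSONANTS_BY_RANK)}
DEFAULT_VOWEL_WEIGHTS = {v: 1.0 / (i + 1)
                         for i, v in enumerate(_VOWELS_BY_RANK)}


@dataclass(frozen=True)
class LexiconGenSpec:
    """Parameters for CVC lexicon generation.

    ``log_freq_mean``/``log_freq_sd`` are the natural-log parameters of the
    per-million frequency distribution (median ~e^mean occurrences per
    million).  Phoneme weights default to the Zipf-skewed English-like
    ranking in ``DEFAULT_CONSONANT_WEIGHTS`` / ``DEFAULT_VOWEL_WEIGHTS``.
    """

    n_words: int = 1000
    consonant_weights: dict[str, float] | None = None
    vowel_weights: dict[str, float] | None = None
    log_freq_mean: float = 1.0
    log_freq_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        for w in (self.consonant_weights, self.vowel_weights):
            if w is not None and any(v <= 0 for v in w.values()):
                raise ValueError("phoneme weights must be positive")
        if self.n_words < 1:
            raise ValueError("n_words must be positive")


@dataclass(frozen=True)
class ResponseGenSpec:
    """Parameters for the visual-only identification model.

    Accuracy follows a logistic model on the confusability of the stimulus's
    LEC: logit(p) = logit(p_correct_base) + lec_size_slope * z(LEC size)
    + lec_degree_slope * z(LEC degree), observed over ``n_presentations``
    simulated viewers.  ``within_lec_error_weight`` is the probability that
    the modal error stays inside the stimulus's own LEC;
    ``far_error_weight`` the probability of a gross misperception (a
    frequency-weighted draw from anywhere in the lexicon, typically more
    than one viseme away); the remaining mass goes to LECs one viseme
    substitution away.
    """

    p_correct_base: float = 0.15
    lec_size_slope: float = -0.4
    lec_degree_slope: float = -0.6
    within_lec_error_weight: float = 0.35
    far_error_weight: float = 0.15
    n_presentations: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_correct_base < 1.0:
            raise ValueError("p_correct_base must be in (0, 1)")
        for name in ("within_lec_error_weight", "far_error_weight"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.within_lec_error_weight + self.far_error_weight > 1.0:
            raise ValueError("error weights must sum to at most 1")


def _weights(weight_map: dict[str, float] | None, alphabet: str) -> np.ndarray:
    if weight_map is None:
        w = np.ones(len(alphabet))
    else:
        w = np.array([weight_map.get(s, 0.0) for s in alphabet])
        if w.sum() == 0:
            raise ValueError("weights assign no mass to the alphabet")
    return w / w.sum()


def generate_lexicon(spec: LexiconGenSpec) -> Lexicon:
    """Draw ``n_words`` distinct CVC forms with log-normal frequencies."""
    n_space = len(ALL_CONSONANTS) ** 2 * len(ALL_VOWELS)
    if spec.n_words > n_space:
        raise ValueError(
            f"requested {spec.n_words} words but only {n_space} distinct "
            "CVC strings exist")
    rng = np.random.default_rng(spec.seed)
    cw = _weights(spec.consonant_weights or DEFAULT_CONSONANT_WEIGHTS,
                  ALL_CONSONANTS)
    vw = _weights(spec.vowel_weights or DEFAULT_VOWEL_WEIGHTS, ALL_VOWELS)

    chosen: dict[str, None] = {}
    while len(chosen) < spec.n_words:
        need = spec.n_words - len(chosen)
        c1 = rng.choice(list(ALL_CONSONANTS), size=2 * need, p=cw)
        v = rng.choice(list(ALL_VOWELS), size=2 * need, p=vw)
        c2 = rng.choice(list(ALL_CONSONANTS), size=2 * need, p=cw)
        for a, b, c in zip(c1, v, c2):
            if len(chosen) == spec.n_words:
                break
            chosen.setdefault(a + b + c, None)

    phonos = list(chosen)
    freqs = rng.lognormal(mean=spec.log_freq_mean, sigma=spec.log_freq_sd,
                          size=len(phonos))
    fams = rng.uniform(5.0, 7.0, size=len(phonos))
    entries = [WordEntry(orthography=p, phono=p,
                         familiarity=round(float(f), 2),
                         frequency=round(float(q), 4))
               for p, f, q in zip(phonos, fams, freqs)]
    return Lexicon(entries)


def label_easy_hard(lexicon: Lexicon, k_per_group: int = 38,
                    seed: int = 0) -> StimulusSet:
    """Select k easy and k hard stimuli with matched initial consonants.

    Easy candidates sit in the high-frequency, low-neighborhood-density
    corner of the lexicon; hard candidates in the low-frequency,
    high-density corner.  Candidate pools start at the quartile cuts and the
    cut is relaxed in 0.05 steps (never past the median) until ``k_per_group``
    initial-consonant-matched pairs exist; raises with the achievable count
    if even the median split cannot supply them.
    """
    entries = lexicon.entries
    density = neighborhood_density(lexicon)
    freqs = np.array([e.frequency for e in entries])
    dens = np.array([density[e.phono] for e in entries])
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(entries))      # seed-dependent tie-breaking

    best_achievable = 0
    for q in np.arange(0.25, 0.501, 0.05):
        f_lo, f_hi = np.quantile(freqs, [q, 1 - q])
        d_lo, d_hi = np.quantile(dens, [q, 1 - q])
        easy_pool: dict[str, list[WordEntry]] = {}
        hard_pool: dict[str, list[WordEntry]] = {}
        for i in order:
            e = entries[i]
            onset = e.phono[0]
            if freqs[i] >= f_hi and dens[i] <= d_lo:
                easy_pool.setdefault(onset, []).append(e)
            elif freqs[i] <= f_lo and dens[i] >= d_hi:
                hard_pool.setdefault(onset, []).append(e)
        # sort each pool by extremity so the strongest contrast is kept
        for onset in easy_pool:
            easy_pool[onset].sort(key=lambda e: (-e.frequency,
                                                 density[e.phono]))
        for onset in hard_pool:
            hard_pool[onset].sort(key=lambda e: (e.frequency,
                                                 -density[e.phono]))
        achievable = sum(min(len(easy_pool.get(c, [])),
                             len(hard_pool.get(c, [])))
                         for c in set(easy_pool) | set(hard_pool))
        best_achievable = max(best_achievable, achievable)
        if achievable >= k_per_group:
            pairs: list[tuple[WordEntry, WordEntry]] = []
            onsets = sorted(set(easy_pool) & set(hard_pool),
                            key=lambda c: (-min(len(easy_pool[c]),
                                                len(hard_pool[c])), c))
            depth = 0
            while len(pairs) < k_per_group:   # round-robin across onsets
                progressed = False
                for c in onsets:
                    if len(pairs) == k_per_group:
                        break
                    if depth < min(len(easy_pool[c]), len(hard_pool[c])):
                        pairs.append((easy_pool[c][depth], hard_pool[c][depth]))
                        progressed = True
                depth += 1
                if not progressed:
                    break
            if len(pairs) == k_per_group:
                items = ([e.with_difficulty("easy") for e, _ in pairs]
                         + [h.with_difficulty("hard") for _, h in pairs])
                return StimulusSet(items=items, balanced=True,
                                   initial_consonant_matched=True)
    raise ValueError(
        f"cannot form {k_per_group} matched easy/hard pairs; at most "
        f"{best_achievable} are achievable with this lexicon")


def simulate_visual_identification(lexicon: Lexicon, stimuli: StimulusSet,
                                   spec: ResponseGenSpec | None = None,
                                   vmap: VisemeMap | None = None
                                   ) -> pd.DataFrame:
    """Generate a behavioral table for the visual-only condition.

    Returns columns stimulus_orthography, stimulus_phono,
    modal_error_orthography, modal_error_phono, accuracy_pct.
    """
    spec = spec or ResponseGenSpec()
    vmap = vmap or default_viseme_map()
    rng = np.random.default_rng(spec.seed)

    partition = lec_partition(lexicon, vmap)
    vlayer = build_viseme_layer(partition)
    sizes = np.array([len(partition[to_visemes(w.phono, vmap)])
                      for w in stimuli], dtype=float)
    degrees = np.array([lec_degree(visual_id(to_visemes(w.phono, vmap)),
                                   vlayer) for w in stimuli], dtype=float)

    def z(x: np.ndarray) -> np.ndarray:
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    eta = (logit(spec.p_correct_base)
           + spec.lec_size_slope * z(sizes)
           + spec.lec_degree_slope * z(degrees))
    p = expit(eta)
    hits = rng.binomial(spec.n_presentations, p)
    accuracy = 100.0 * hits / spec.n_presentations

    rows = []
    for w, acc in zip(stimuli, accuracy):
        resp = _modal_error(w, lexicon, partition, vlayer, spec, vmap, rng)
        rows.append((w.orthography, w.phono, resp.orthography, resp.phono,
                     float(acc)))
    return pd.DataFrame(rows, columns=["stimulus_orthography",
                                       "stimulus_phono",
                                       "modal_error_orthography",
                                       "modal_error_phono", "accuracy_pct"])


def _freq_choice(rng: np.random.Generator,
                 candidates: list[WordEntry]) -> WordEntry:
    w = np.array([c.frequency for c in candidates])
    p = w / w.sum() if w.sum() > 0 else None
    return candidates[rng.choice(len(candidates), p=p)]


def _modal_error(word: WordEntry, lexicon: Lexicon, partition, vlayer,
                 spec: ResponseGenSpec, vmap: VisemeMap,
                 rng: np.random.Generator) -> WordEntry:
    """Sample the modal incorrect response for one stimulus."""
    viseme = to_visemes(word.phono, vmap)
    # candidate lists sorted by form: LEC members are stored as sets, whose
    # iteration order is not reproducible across interpreter runs
    same = sorted((e for e in partition[viseme] if e.phono != word.phono),
                  key=lambda e: e.phono)
    near: list[WordEntry] = []
    for nbr in vlayer.neighbors(visual_id(viseme)):
        near.extend(partition[vlayer.nodes[nbr]["payload"]])
    near.sort(key=lambda e: e.phono)
    u = rng.random()
    if u < spec.within_lec_error_weight and same:
        return _freq_choice(rng, same)
    if u < spec.within_lec_error_weight + spec.far_error_weight:
        others = [e for e in lexicon if e.phono != word.phono]
        return _freq_choice(rng, others)
    if near:
        return _freq_choice(rng, near)
    if same:
        return _freq_choice(rng, same)
    others = [e for e in lexicon if e.phono != word.phono]
    return _freq_choice(rng, others)
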
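"""Lexicon handling: phoneme inventory, viseme transcription, neighbors, LECs.

Words are stored as computer-readable phonemic strings (one character per
phoneme, case-sensitive: ``E`` and ``e`` are different vowels).  Each phoneme
belongs to exactly one *phoneme equivalence class* — a viseme — grouping the
phonemes that look alike on the lips and jaw when spoken.  Transcribing a word
position-by-position into viseme class symbols yields its viseme string, and
words sharing a viseme string form a *lexical equivalence class* (LEC): they
are indistinguishable to an ideal lip-reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "CONSONANT_CLASSES",
    "VOWEL_CLASSES",
    "PhonemeInventory",
    "VisemeMap",
    "WordEntry",
    "Lexicon",
    "LexiconError",
    "default_inventory",
    "default_viseme_map",
    "load_lexicon",
    "to_visemes",
    "edit_distance_is_one",
    "phonological_neighbors",
    "neighborhood_density",
    "lec_partition",
]

# Viseme classes: phonemes grouped by visual similarity when spoken.  Keys are
# the single-character class symbols; values the member phonemes.  The vowel
# class "e" contains both the i and I codes (tense/lax front vowels); note that
# d patterns with the palato-alveolars (class C) rather than with t, s, z.
CONSONANT_CLASSES: dict[str, str] = {
    "b": "bmp",
    "f": "fv",
    "T": "TD",
    "w": "w",
    "r": "r",
    "C": "CJZSd",
    "s": "tsz",
    "k": "kghGy",
    "n": "nl",
}

VOWEL_CLASSES: dict[str, str] = {
    "e": "iIeYE@^",
    "o": "RoOUu",
    "a": "ac",
    "W": "W",
}


class LexiconError(ValueError):
    """Raised for invalid lexicon files, rows, or transcription symbols."""


@dataclass(frozen=True)
class PhonemeInventory:
    """The computer-readable transcription alphabet, split into C and V."""

    consonants: frozenset[str]
    vowels: frozenset[str]

    def __post_init__(self) -> None:
        overlap = self.consonants & self.vowels
        if overlap:
            raise LexiconError(f"consonant/vowel overlap: {sorted(overlap)}")
        for sym in self.consonants | self.vowels:
            if len(sym) != 1:
                raise LexiconError(f"phoneme symbol {sym!r} is not one character")

    @property
    def symbols(self) -> frozenset[str]:
        return self.consonants | self.vowels

    def __contains__(self, sym: str) -> bool:
        return sym in self.consonants or sym in self.vowels


@dataclass(frozen=True)
class VisemeMap:
    """Total mapping phoneme symbol -> viseme class symbol.

    Idempotent on class representatives: the class symbol of a consonant class
    is itself a member phoneme (b->b, f->f, ...), likewise for vowels.
    """

    mapping: Mapping[str, str]

    def __getitem__(self, sym: str) -> str:
        return self.mapping[sym]

    def __contains__(self, sym: str) -> bool:
        return sym in self.mapping

    @property
    def classes(self) -> frozenset[str]:
        return frozenset(self.mapping.values())


def default_inventory() -> PhonemeInventory:
    """Inventory induced by the default viseme classes."""
    return PhonemeInventory(
        consonants=frozenset("".join(CONSONANT_CLASSES.values())),
        vowels=frozenset("".join(VOWEL_CLASSES.values())),
    )


def default_viseme_map() -> VisemeMap:
    mapping: dict[str, str] = {}
    for cls, members in {**CONSONANT_CLASSES, **VOWEL_CLASSES}.items():
        for ph in members:
            mapping[ph] = cls
    return VisemeMap(mapping)


@dataclass(frozen=True)
class WordEntry:
    """One lexical item: spelling, phonemic form, and lexical statistics.

    ``frequency`` is a nonnegative occurrence rate (per-million by
    convention); ``familiarity`` a 1-7 subjective rating; ``difficulty``
    carries the easy/hard lexical-competition label when one exists.
    """

    orthography: str
    phono: str
    familiarity: float = 7.0
    frequency: float = 0.0
    difficulty: str = "unlabeled"  # easy | hard | unlabeled

    def __post_init__(self) -> None:
        if not self.phono:
            raise LexiconError("empty phonemic transcription")
        if self.difficulty not in ("easy", "hard", "unlabeled"):
            raise LexiconError(f"bad difficulty label {self.difficulty!r}")

    def with_difficulty(self, label: str) -> "WordEntry":
        return replace(self, difficulty=label)


class Lexicon:
    """Ordered collection of :class:`WordEntry`, keyed by phonemic string."""

    def __init__(self, entries: Iterable[WordEntry],
                 inventory: PhonemeInventory | None = None):
        self.inventory = inventory or default_inventory()
        self._entries: list[WordEntry] = []
        self._by_phono: dict[str, WordEntry] = {}
        for e in entries:
            for pos, sym in enumerate(e.phono):
                if sym not in self.inventory:
                    raise LexiconError(
                        f"word {e.orthography!r}: symbol {sym!r} at position "
                        f"{pos} not in the phoneme inventory")
            if e.phono in self._by_phono:
                raise LexiconError(f"duplicate phonemic form {e.phono!r}")
            self._entries.append(e)
            self._by_phono[e.phono] = e

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries)

    def __contains__(self, phono: str) -> bool:
        return phono in self._by_phono

    def __getitem__(self, phono: str) -> WordEntry:
        return self._by_phono[phono]

    @property
    def entries(self) -> list[WordEntry]:
        return list(self._entries)

    def phono_strings(self) -> list[str]:
        return [e.phono for e in self._entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.orthography, e.phono, e.familiarity, e.frequency, e.difficulty)
             for e in self._entries],
            columns=["orthography", "phono", "familiarity", "frequency",
                     "difficulty"],
        )


DEFAULT_COLUMNS = {
    "orthography": "orthography",
    "phono": "phono",
    "familiarity": "familiarity",
    "frequency": "frequency",
    "difficulty": "difficulty",
}


def load_lexicon(path: str | Path,
                 columns: Mapping[str, str] | None = None,
                 inventory: PhonemeInventory | None = None,
                 min_familiarity: float | None = 5.0,
                 require_cvc: bool = False) -> Lexicon:
    """Read and validate a lexicon CSV.

    ``columns`` maps the canonical field names to the file's column names;
    ``familiarity`` and ``difficulty`` columns are optional.  When a
    familiarity column is present, rows rated below ``min_familiarity`` are
    excluded (the standard "known word" selection rule).  ``require_cvc``
    additionally enforces consonant-vowel-consonant structure row by row.

    Invalid rows (unknown symbol, duplicate form, malformed structure) raise
    :class:`LexiconError` naming the offending row.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    inventory = inventory or default_inventory()

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for field_name in ("orthography", "phono"):
        if cols[field_name] not in df.columns:
            raise LexiconError(
                f"required column {cols[field_name]!r} (for {field_name}) "
                f"missing from {path}")
    has_fam = cols["familiarity"] in df.columns
    has_freq = cols["frequency"] in df.columns
    has_diff = cols["difficulty"] in df.columns

    entries: list[WordEntry] = []
    for idx, row in df.iterrows():
        phono = row[cols["phono"]]
        for pos, sym in enumerate(phono):
            if sym not in inventory:
                raise LexiconError(
                    f"row {idx}: symbol {sym!r} at position {pos} of "
                    f"{phono!r} is not in the phoneme inventory")
        if require_cvc and not is_cvc(phono, inventory):
            raise LexiconError(f"row {idx}: {phono!r} is not CVC")
        fam = float(row[cols["familiarity"]]) if has_fam else 7.0
        if has_fam and min_familiarity is not None and fam < min_familiarity:
            continue
        freq = float(row[cols["frequency"]]) if has_freq else 0.0
        if freq < 0:
            raise LexiconError(f"row {idx}: negative frequency {freq}")
        diff = row[cols["difficulty"]] if has_diff else ""
        entries.append(WordEntry(
            orthography=row[cols["orthography"]],
            phono=phono,
            familiarity=fam,
            frequency=freq,
            difficulty=diff if diff else "unlabeled",
        ))
    try:
        return Lexicon(entries, inventory)
    except LexiconError as err:
        raise LexiconError(f"{path}: {err}") from err


def is_cvc(phono: str, inventory: PhonemeInventory | None = None) -> bool:
    inv = inventory or default_inventory()
    return (len(phono) == 3
            and phono[0] in inv.consonants
            and phono[1] in inv.vowels
            and phono[2] in inv.consonants)


def to_visemes(phono: str, vmap: VisemeMap | None = None) -> str:
    """Transcribe a phonemic string into its viseme string, position-wise."""
    vmap = vmap or default_viseme_map()
    out = []
    for pos, sym in enumerate(phono):
        if sym not in vmap:
            raise LexiconError(
                f"symbol {sym!r} at position {pos} has no viseme class")
        out.append(vmap[sym])
    return "".join(out)


def edit_distance_is_one(a: str, b: str) -> bool:
    """True iff the strings differ by exactly one substitution, addition, or
    deletion of a single symbol.  O(len) specialised test, no DP table."""
    la, lb = len(a), len(b)
    if abs(la - lb) > 1 or (a == b):
        return False
    if la == lb:
        return sum(x != y for x, y in zip(a, b)) == 1
    if la > lb:
        a, b, la, lb = b, a, lb, la
    # a is shorter by one: check b minus one symbol equals a
    i = 0
    while i < la and a[i] == b[i]:
        i += 1
    return a[i:] == b[i + 1:]


def phonological_neighbors(target: WordEntry, lexicon: Lexicon) -> set[WordEntry]:
    """All other lexicon entries one phoneme edit away (the 1-phoneme metric:
    a single addition, deletion, or substitution)."""
    if target.phono not in lexicon:
        raise LexiconError(f"{target.phono!r} not in lexicon")
    return {e for e in lexicon
            if e.phono != target.phono
            and edit_distance_is_one(target.phono, e.phono)}


def neighborhood_density(lexicon: Lexicon) -> dict[str, int]:
    """Phonological neighbor count for every word, via signature buckets.

    Substitution neighbors share a wildcard pattern (one position masked);
    addition/deletion neighbors share a deletion signature.  This is
    O(total length) instead of the all-pairs scan.
    """
    sub_buckets: dict[str, list[str]] = {}
    del_index: dict[str, list[str]] = {}  # deletion result -> words it came from
    words = lexicon.phono_strings()
    word_set = set(words)
    for w in words:
        for i in range(len(w)):
            sub_buckets.setdefault(w[:i] + "\x00" + w[i + 1:], []).append(w)
            del_index.setdefault(w[:i] + w[i + 1:], []).append(w)

    counts: dict[str, int] = {}
    for w in words:
        nbrs: set[str] = set()
        for i in range(len(w)):
            for other in sub_buckets.get(w[:i] + "\x00" + w[i + 1:], ()):
                nbrs.add(other)
            short = w[:i] + w[i + 1:]
            if short in word_set:          # deletion neighbor
                nbrs.add(short)
            for longer in del_index.get(w, ()):  # addition neighbors
                nbrs.add(longer)
        nbrs.discard(w)
        counts[w] = len(nbrs)
    return counts


def lec_partition(lexicon: Lexicon,
                  vmap: VisemeMap | None = None) -> dict[str, set[WordEntry]]:
    """Partition the lexicon into lexical equivalence classes.

    Keys are viseme strings; each word lands in exactly one class, the one
    keyed by its own transcription.
    """
    vmap = vmap or default_viseme_map()
    classes: dict[str, set[WordEntry]] = {}
    for e in lexicon:
        classes.setdefault(to_visemes(e.phono, vmap), set()).add(e)
    return classes
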
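"""Classification and tabulation of visual-only identification errors.

Each record pairs a visually presented stimulus with the modal (most
frequent) incorrect response.  Errors are classified by whether the response
falls in the stimulus's lexical equivalence class (identical viseme strings),
whether it is a phonological neighbor (one phoneme edit away), and — for
different-LEC errors — by the kind and position of the viseme edit
(single-viseme addition / deletion / substitution, or "other" when more than
one viseme changed).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .lexicon import (VisemeMap, WordEntry, default_viseme_map,
                      edit_distance_is_one, to_visemes)
from .stats import StatsError, TestResult, chisq_2x2, chisq_gof

__all__ = ["ErrorRecord", "ErrorTable", "classify_error", "tabulate",
           "run_error_tests", "load_behavior", "records_from_behavior"]

EDIT_KINDS = ("addition", "deletion", "substitution", "other", "none")
POSITIONS = ("onset", "vowel", "final", "none")


@dataclass(frozen=True)
class ErrorRecord:
    stimulus: WordEntry
    response: WordEntry
    same_lec: bool
    phono_neighbor: bool
    edit_kind: str      # addition | deletion | substitution | other | none
    position: str       # onset | vowel | final | none

    def __post_init__(self) -> None:
        if self.edit_kind not in EDIT_KINDS or self.position not in POSITIONS:
            raise ValueError("bad edit classification")
        if self.same_lec and (self.edit_kind != "none" or self.position != "none"):
            raise ValueError("same-LEC errors carry no viseme edit")
        if self.edit_kind == "other" and self.position != "none":
            raise ValueError("multi-viseme errors have no single position")


def _position_label(index: int, length: int) -> str:
    """Map a string index to onset / medial-vowel / final.  For the CVC
    three-viseme case this is exactly positions 1/2/3 -> O/V/F."""
    if index == 0:
        return "onset"
    if index == length - 1:
        return "final"
    return "vowel"


def _single_viseme_edit(sv: str, rv: str) -> tuple[str, str]:
    """(edit_kind, position) between two distinct viseme strings.

    Returns ("other", "none") when more than one viseme changed.  For
    additions/deletions the position is that of the inserted/removed viseme
    in the longer string.
    """
    if len(sv) == len(rv):
        diffs = [i for i, (a, b) in enumerate(zip(sv, rv)) if a != b]
        if len(diffs) == 1:
            return "substitution", _position_label(diffs[0], len(sv))
        return "other", "none"
    if abs(len(sv) - len(rv)) == 1:
        kind = "addition" if len(rv) > len(sv) else "deletion"
        short, long_ = (sv, rv) if len(rv) > len(sv) else (rv, sv)
        i = 0
        while i < len(short) and short[i] == long_[i]:
            i += 1
        if short[i:] == long_[i + 1:]:
            return kind, _position_label(i, len(long_))
        return "other", "none"
    return "other", "none"


def classify_error(stimulus: WordEntry, response: WordEntry,
                   vmap: VisemeMap | None = None) -> ErrorRecord:
    """Classify one stimulus/modal-error pair."""
    vmap = vmap or default_viseme_map()
    if stimulus.phono == response.phono:
        raise ValueError(
            f"{stimulus.orthography!r}: response equals stimulus "
            "(not an error trial)")
    sv = to_visemes(stimulus.phono, vmap)
    rv = to_visemes(response.phono, vmap)
    same_lec = sv == rv
    neighbor = edit_distance_is_one(stimulus.phono, response.phono)
    if same_lec:
        kind, pos = "none", "none"
    else:
        kind, pos = _single_viseme_edit(sv, rv)
    return ErrorRecord(stimulus=stimulus, response=response,
                       same_lec=same_lec, phono_neighbor=neighbor,
                       edit_kind=kind, position=pos)


@dataclass
class ErrorTable:
    """Cross-tabulations of classified errors.

    ``lec_table`` counts difficulty x (same/different LEC) x (neighbor or
    not); ``edit_table`` counts difficulty x edit kind x position over the
    different-LEC errors.
    """

    lec_table: pd.DataFrame
    edit_table: pd.DataFrame
    n_records: int

    def count(self, difficulty: str, same_lec: bool,
              neighbor: bool | None = None) -> int:
        t = self.lec_table
        m = (t.difficulty == difficulty) & (t.same_lec == same_lec)
        if neighbor is not None:
            m &= t.phono_neighbor == neighbor
        return int(t.loc[m, "count"].sum())

    def total(self, same_lec: bool | None = None,
              neighbor: bool | None = None) -> int:
        t = self.lec_table
        m = pd.Series(True, index=t.index)
        if same_lec is not None:
            m &= t.same_lec == same_lec
        if neighbor is not None:
            m &= t.phono_neighbor == neighbor
        return int(t.loc[m, "count"].sum())

    def edit_count(self, difficulty: str, kind: str,
                   position: str | None = None) -> int:
        t = self.edit_table
        m = (t.difficulty == difficulty) & (t.edit_kind == kind)
        if position is not None:
            m &= t.position == position
        return int(t.loc[m, "count"].sum())

    def single_vs_multi(self, difficulty: str) -> tuple[int, int]:
        """(single-viseme edits, multi-viseme "other") among different-LEC
        errors for one difficulty group."""
        single = sum(self.edit_count(difficulty, k)
                     for k in ("addition", "deletion", "substitution"))
        return single, self.edit_count(difficulty, "other")


def tabulate(records: list[ErrorRecord]) -> ErrorTable:
    """Aggregate classified records into the two summary tables."""
    rows = [(r.stimulus.difficulty, r.same_lec, r.phono_neighbor,
             r.edit_kind, r.position) for r in records]
    df = pd.DataFrame(rows, columns=["difficulty", "same_lec",
                                     "phono_neighbor", "edit_kind",
                                     "position"])
    lec = (df.groupby(["difficulty", "same_lec", "phono_neighbor"])
             .size().reset_index(name="count"))
    edit = (df[~df.same_lec]
            .groupby(["difficulty", "edit_kind", "position"])
            .size().reset_index(name="count"))
    return ErrorTable(lec_table=lec, edit_table=edit, n_records=len(df))


def run_error_tests(table: ErrorTable) -> dict[str, TestResult]:
    """The four chi-square analyses of the error patterns.

    1. Are errors more often in a different LEC than the same LEC?
    2. Are errors more often non-neighbors than phonological neighbors?
    3. Do easy vs hard words differ in different-LEC error counts?
    4. Among different-LEC errors, does the easy/hard split differ between
       single-viseme and multi-viseme changes? (2x2, margin expecteds)
    """
    n_diff = table.total(same_lec=False)
    n_same = table.total(same_lec=True)
    n_nonneigh = table.total(neighbor=False)
    n_neigh = table.total(neighbor=True)
    easy_diff = table.count("easy", same_lec=False)
    hard_diff = table.count("hard", same_lec=False)
    easy_single, easy_multi = table.single_vs_multi("easy")
    hard_single, hard_multi = table.single_vs_multi("hard")
    tests = {
        "diff_vs_same_lec": chisq_gof([n_diff, n_same]),
        "nonneighbor_vs_neighbor": chisq_gof([n_nonneigh, n_neigh]),
        "easy_vs_hard_diff_lec": chisq_gof([easy_diff, hard_diff]),
        "one_vs_multi_viseme_by_difficulty": chisq_2x2(
            [[easy_single, easy_multi], [hard_single, hard_multi]]),
    }
    return tests


def load_behavior(path) -> pd.DataFrame:
    """Read a behavioral table CSV: per-stimulus visual-only accuracy and
    the modal incorrect response."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["stimulus_orthography", "stimulus_phono",
                "modal_error_orthography", "modal_error_phono",
                "accuracy_pct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"behavioral table missing columns {missing}")
    df["accuracy_pct"] = df["accuracy_pct"].astype(float)
    return df


def records_from_behavior(behavior: pd.DataFrame, lexicon,
                          stimuli=None,
                          vmap: VisemeMap | None = None) -> list[ErrorRecord]:
    """Classify every stimulus/modal-error row of a behavioral table.

    ``stimuli`` (an iterable of labeled :class:`WordEntry`, e.g. a
    StimulusSet) supplies the easy/hard labels when the lexicon itself is
    unlabeled.  Responses absent from the lexicon are transcribed on the fly
    from the table's own ``modal_error_phono`` column (human responses were
    not restricted to the stimulus set).
    """
    labeled = {w.phono: w for w in stimuli} if stimuli is not None else {}
    records = []
    for _, row in behavior.iterrows():
        phono = row["stimulus_phono"]
        stim = labeled.get(phono) or lexicon[phono]
        rphono = row["modal_error_phono"]
        if rphono in lexicon:
            resp = lexicon[rphono]
        else:
            resp = WordEntry(orthography=row["modal_error_orthography"],
                             phono=rphono)
        records.append(classify_error(stim, resp, vmap))
    return records
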
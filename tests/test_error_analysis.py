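"""Error classification, tabulation, and the chi-square error tests.

The 76-record fixture reproduces the cell structure of the visual-only
error summary for 38 easy + 38 hard stimuli: per difficulty group the
same/different-LEC split with neighbor sub-splits, and for different-LEC
errors the single-viseme edit kind/position breakdown.
"""

import pytest

from avnet.error_analysis import (ErrorRecord, classify_error,
                                  records_from_behavior, run_error_tests,
                                  tabulate)
from avnet.lexicon import Lexicon, WordEntry, to_visemes
from avnet.synthetic import (LexiconGenSpec, ResponseGenSpec,
                             generate_lexicon, label_easy_hard,
                             simulate_visual_identification)


def W(phono, difficulty="unlabeled"):
    return WordEntry(phono, phono, difficulty=difficulty)


class TestClassifyError:
    def test_final_viseme_substitution(self):
        # "bes" vs "beC": different LEC via one final-position substitution
        rec = classify_error(W("pEt"), W("pES"))
        assert to_visemes("pEt") == "bes" and to_visemes("pES") == "beC"
        assert not rec.same_lec
        assert rec.edit_kind == "substitution" and rec.position == "final"

    def test_same_lec_phonological_neighbor(self):
        rec = classify_error(W("pEt"), W("bEt"))
        assert rec.same_lec and rec.phono_neighbor
        assert rec.edit_kind == "none" and rec.position == "none"

    def test_multi_viseme_change_is_other(self):
        rec = classify_error(W("pEt"), W("kon"))  # bes vs kon: 3 changes
        assert rec.edit_kind == "other" and rec.position == "none"

    def test_onset_and_vowel_substitutions(self):
        assert classify_error(W("pEt"), W("kEt")).position == "onset"
        assert classify_error(W("pEt"), W("pat")).position == "vowel"

    def test_addition_at_final_position(self):
        rec = classify_error(W("pEt"), W("pEts"))  # bes -> bess
        assert rec.edit_kind == "addition" and rec.position == "final"
        assert rec.phono_neighbor

    def test_deletion_at_final_position(self):
        rec = classify_error(W("pEts"), W("pEt"))
        assert rec.edit_kind == "deletion" and rec.position == "final"

    def test_classification_symmetric_in_distance(self):
        a, b = classify_error(W("pEt"), W("pES")), classify_error(W("pES"), W("pEt"))
        assert a.same_lec == b.same_lec
        assert a.phono_neighbor == b.phono_neighbor
        assert a.edit_kind == b.edit_kind

    def test_identical_response_rejected(self):
        with pytest.raises(ValueError, match="not an error"):
            classify_error(W("pEt"), W("pEt"))

    def test_record_invariants_enforced(self):
        with pytest.raises(ValueError):
            ErrorRecord(W("pEt"), W("bEt"), same_lec=True,
                        phono_neighbor=True, edit_kind="substitution",
                        position="final")
        with pytest.raises(ValueError):
            ErrorRecord(W("pEt"), W("kon"), same_lec=False,
                        phono_neighbor=False, edit_kind="other",
                        position="onset")


def _record(difficulty, same_lec, neighbor, kind="none", pos="none"):
    return ErrorRecord(W("pEt", difficulty), W("bEt"), same_lec=same_lec,
                       phono_neighbor=neighbor, edit_kind=kind, position=pos)


@pytest.fixture
def study_records():
    """76 records with the published cell structure.

    Easy: 27 different-LEC (1 neighbor / 26 not; edits 2 add-F, 1 del-F,
    6 sub-O, 2 sub-V, 7 sub-F, 9 other), 11 same-LEC (6 neighbor / 5 not).
    Hard: 22 different-LEC (6 / 16; edits 1 add-F, 1 del-F, 3 sub-O,
    2 sub-V, 11 sub-F, 4 other), 16 same-LEC (10 / 6).
    """
    recs = []

    def add(n, difficulty, same, neigh, kind="none", pos="none"):
        recs.extend(_record(difficulty, same, neigh, kind, pos)
                    for _ in range(n))

    # easy, different LEC (27), neighbor split 1/26
    add(1, "easy", False, True, "substitution", "final")
    add(2, "easy", False, False, "addition", "final")
    add(1, "easy", False, False, "deletion", "final")
    add(6, "easy", False, False, "substitution", "onset")
    add(2, "easy", False, False, "substitution", "vowel")
    add(6, "easy", False, False, "substitution", "final")
    add(9, "easy", False, False, "other")
    # easy, same LEC (11), neighbor split 6/5
    add(6, "easy", True, True)
    add(5, "easy", True, False)
    # hard, different LEC (22), neighbor split 6/16
    add(6, "hard", False, True, "substitution", "final")
    add(1, "hard", False, False, "addition", "final")
    add(1, "hard", False, False, "deletion", "final")
    add(3, "hard", False, False, "substitution", "onset")
    add(2, "hard", False, False, "substitution", "vowel")
    add(5, "hard", False, False, "substitution", "final")
    add(4, "hard", False, False, "other")
    # hard, same LEC (16), neighbor split 10/6
    add(10, "hard", True, True)
    add(6, "hard", True, False)
    return recs


class TestTabulate:
    def test_counts_match_prescription(self, study_records):
        tab = tabulate(study_records)
        assert tab.n_records == 76
        assert tab.count("easy", same_lec=False) == 27
        assert tab.count("easy", same_lec=True) == 11
        assert tab.count("hard", same_lec=False) == 22
        assert tab.count("hard", same_lec=True) == 16
        assert tab.count("easy", same_lec=False, neighbor=True) == 1
        assert tab.count("hard", same_lec=True, neighbor=True) == 10

    def test_derived_margins(self, study_records):
        tab = tabulate(study_records)
        assert tab.total(same_lec=False) == 49
        assert tab.total(same_lec=True) == 27
        assert tab.total(neighbor=True) == 23
        assert tab.total(neighbor=False) == 53

    def test_subtotals_add_to_grand_total(self, study_records):
        tab = tabulate(study_records)
        assert tab.total(same_lec=True) + tab.total(same_lec=False) == 76
        for diff in ("easy", "hard"):
            single, multi = tab.single_vs_multi(diff)
            assert single + multi == tab.count(diff, same_lec=False)

    def test_edit_kind_table(self, study_records):
        tab = tabulate(study_records)
        assert tab.edit_count("easy", "substitution", "onset") == 6
        assert tab.edit_count("hard", "substitution", "final") == 11
        assert tab.single_vs_multi("easy") == (18, 9)
        assert tab.single_vs_multi("hard") == (18, 4)


class TestRunErrorTests:
    def test_published_chi_square_statistics(self, study_records):
        tests = run_error_tests(tabulate(study_records))
        assert round(tests["diff_vs_same_lec"].statistic, 2) == 6.37
        assert round(tests["nonneighbor_vs_neighbor"].statistic, 2) == 11.84
        assert round(tests["easy_vs_hard_diff_lec"].statistic, 2) == 0.51
        assert round(tests["one_vs_multi_viseme_by_difficulty"].statistic,
                     2) == 1.43
        assert all(t.df == 1 for t in tests.values())


class TestBehaviorRoundTrip:
    def test_generated_tables_classify_cleanly(self):
        lex = generate_lexicon(LexiconGenSpec(n_words=400, seed=31))
        stim = label_easy_hard(lex, k_per_group=19, seed=32)
        beh = simulate_visual_identification(lex, stim,
                                             ResponseGenSpec(seed=33))
        recs = records_from_behavior(beh, lex, stimuli=stim)
        assert len(recs) == len(stim)
        assert all(r.stimulus.phono != r.response.phono for r in recs)
        assert all(r.stimulus.difficulty in ("easy", "hard") for r in recs)

    def test_unlexical_responses_transcribed_on_the_fly(self):
        import pandas as pd
        lex = Lexicon([WordEntry("pet", "pEt")])
        beh = pd.DataFrame([{"stimulus_orthography": "pet",
                             "stimulus_phono": "pEt",
                             "modal_error_orthography": "pets",
                             "modal_error_phono": "pEts",
                             "accuracy_pct": 10.0}])
        recs = records_from_behavior(beh, lex)
        assert recs[0].edit_kind == "addition"
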
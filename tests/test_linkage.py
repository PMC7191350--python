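"""Match-key cascade, validation score, deduplication, and review policy."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cohortlink.config import ConfigurationError, ScoreWeights, SimConfig, CorruptionRates
from cohortlink.linkage import (
    IdentifierRecord,
    MatchDecision,
    apply_review_policy,
    brute_force_match,
    build_key,
    cascade_match,
    evaluate_linkage,
    link,
    normalize,
    resolve_duplicates,
    score_pair,
)
from cohortlink.synthetic import simulate


def make_frame(rows, id_col):
    return pd.DataFrame(
        [
            {
                id_col: rid,
                "first_name": first,
                "last_name": last,
                "birth_date": pd.Timestamp(dob) if dob else pd.NaT,
                "ssn": ssn,
            }
            for rid, first, last, dob, ssn in rows
        ]
    )


class TestNormalize:
    def test_folds_case_diacritics_and_punctuation(self):
        rec = IdentifierRecord("  García ", "o'neil", dt.date(1980, 5, 2), "123-45-6789")
        out = normalize(rec)
        assert out == IdentifierRecord("GARCIA", "ONEIL", dt.date(1980, 5, 2), "123456789")

    def test_non_nine_digit_ssn_becomes_missing(self):
        assert normalize(IdentifierRecord("A", "B", None, "12345")).ssn == ""
        assert normalize(IdentifierRecord("A", "B", None, "123456789012")).ssn == ""

    def test_empty_first_name_is_retained(self):
        out = normalize(IdentifierRecord("", "Smith", dt.date(1990, 1, 1), ""))
        assert out.first_name == ""
        assert out.last_name == "SMITH"

    @given(
        st.text(max_size=20),
        st.text(max_size=20),
        st.one_of(st.none(), st.dates(dt.date(1920, 1, 1), dt.date(2010, 12, 31))),
        st.text(alphabet="0123456789-", max_size=12),
    )
    def test_idempotent(self, first, last, dob, ssn):
        once = normalize(IdentifierRecord(first, last, dob, ssn))
        assert normalize(once) == once


class TestBuildKey:
    MARGARET = normalize(IdentifierRecord("Margaret", "Smith", dt.date(1990, 1, 15), ""))

    def test_level2_truncates_first_name_to_six_letters(self):
        assert build_key(self.MARGARET, 2) == "MARGAR|SMITH|1990-01-15"

    def test_level1_requires_ssn(self):
        assert build_key(self.MARGARET, 1) is None
        with_ssn = normalize(IdentifierRecord("A", "B", None, "123456789"))
        assert build_key(with_ssn, 1) == "123456789"

    def test_level7_uses_three_letter_prefixes(self):
        rec = normalize(IdentifierRecord("Jonathan", "Williams", dt.date(1985, 3, 2), ""))
        assert build_key(rec, 7) == "WIL|JON|1985-03-02"

    def test_level3_skips_second_letter_of_last_name(self):
        rec = normalize(IdentifierRecord("Jonathan", "Williams", dt.date(1985, 3, 2), ""))
        # last letter 1 + last letters 3-8 + first letters 2-8 + DOB
        assert build_key(rec, 3) == "W|LLIAMS|ONATHAN|1985-03-02"

    def test_short_names_use_available_letters(self):
        rec = normalize(IdentifierRecord("Bo", "Ng", dt.date(1970, 6, 1), ""))
        # level 7 slices 1-3 fall back to the available prefixes
        assert build_key(rec, 7) == "NG|BO|1970-06-01"
        # level 3 needs last-name letter 3: too short, no key
        assert build_key(rec, 3) is None

    def test_dob_components(self):
        rec = normalize(IdentifierRecord("Jonathan", "Williams", dt.date(1985, 3, 2), ""))
        assert build_key(rec, 8) == "WILL|JONA|Y1985"
        assert build_key(rec, 9) == "JON|WIL|M03|Y1985"
        assert build_key(rec, 10) == "JON|WIL|D02|Y1985"

    def test_levels_9_and_11_coincide_as_printed(self):
        rec = normalize(IdentifierRecord("Jonathan", "Williams", dt.date(1985, 3, 2), ""))
        assert build_key(rec, 11) == build_key(rec, 9)

    def test_missing_dob_blocks_dob_levels(self):
        rec = normalize(IdentifierRecord("Jonathan", "Williams", None, "123456789"))
        assert build_key(rec, 2) is None
        assert build_key(rec, 1) == "123456789"

    def test_invalid_level_raises(self):
        with pytest.raises(ValueError, match="1..11"):
            build_key(self.MARGARET, 12)


class TestScore:
    def test_identical_records_score_100(self):
        rec = normalize(IdentifierRecord("Ann", "Lee", dt.date(1991, 2, 3), "111223333"))
        assert score_pair(rec, rec) == 100.0

    def test_total_disagreement_scores_0(self):
        a = normalize(IdentifierRecord("AAA", "BBB", dt.date(1990, 1, 1), "111111111"))
        b = normalize(IdentifierRecord("XYZ", "QRS", dt.date(1985, 2, 2), "222222222"))
        assert score_pair(a, b) == 0.0

    def test_missing_fields_drop_from_weighting(self):
        a = normalize(IdentifierRecord("Ann", "Lee", dt.date(1991, 2, 3), ""))
        b = normalize(IdentifierRecord("Ann", "Lee", dt.date(1991, 2, 3), "111223333"))
        assert score_pair(a, b) == 100.0

    def test_weights_must_be_positive_total(self):
        with pytest.raises(ConfigurationError, match="positive"):
            ScoreWeights(0, 0, 0, 0, 0, 0)

    @given(st.integers(0, 2**32 - 1))
    def test_symmetry_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)

        def rand_record():
            letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
            name = lambda: "".join(rng.choice(list(letters), size=rng.integers(1, 9)))
            dob = dt.date(int(rng.integers(1940, 2000)), int(rng.integers(1, 13)), int(rng.integers(1, 29)))
            ssn = f"{rng.integers(100000000, 999999999):09d}" if rng.random() < 0.7 else ""
            return IdentifierRecord(name(), name(), dob if rng.random() < 0.9 else None, ssn)

        a, b = rand_record(), rand_record()
        assert score_pair(a, b) == pytest.approx(score_pair(b, a))


class TestCascade:
    def test_shared_ssn_wins_at_level_1(self):
        registry = make_frame(
            [("R1", "Ann", "Lee", "1991-02-03", "111223333"),
             ("R2", "Bea", "Kim", "1992-03-04", "444556666")],
            "person_id",
        )
        roster = make_frame([("C1", "Anne", "Leigh", "1991-02-03", "111223333")], "roster_id")
        [d] = cascade_match(roster, registry)
        assert (d.registry_id, d.key_level) == ("R1", 1)

    def test_blank_ssn_falls_to_level_2_not_deeper(self):
        registry = make_frame([("R1", "Ann", "Lee", "1991-02-03", "111223333")], "person_id")
        roster = make_frame([("C1", "Ann", "Lee", "1991-02-03", "")], "roster_id")
        [d] = cascade_match(roster, registry)
        assert (d.registry_id, d.key_level) == ("R1", 2)

    def test_no_agreement_yields_unmatched(self):
        registry = make_frame([("R1", "Ann", "Lee", "1991-02-03", "111223333")], "person_id")
        roster = make_frame([("C1", "Zed", "Quux", "1955-05-05", "")], "roster_id")
        [d] = cascade_match(roster, registry)
        assert d.registry_id is None and d.key_level is None

    def test_duplicate_registry_ids_rejected(self):
        registry = make_frame(
            [("R1", "A", "B", "1990-01-01", "111111111"),
             ("R1", "C", "D", "1991-01-01", "222222222")],
            "person_id",
        )
        roster = make_frame([("C1", "A", "B", "1990-01-01", "")], "roster_id")
        with pytest.raises(ValueError, match="duplicate registry"):
            cascade_match(roster, registry)

    def test_matches_brute_force_oracle_on_noisy_instance(self):
        config = SimConfig(
            n_persons=200, seed=17,
            corruption_rates=CorruptionRates(0.4, 0.15, 0.15, 0.1),
            labs_per_person_mean=1.0, enroll_fraction=0.8,
        )
        persons, _, _, roster, _ = simulate(config)
        fast = cascade_match(roster, persons)
        slow = brute_force_match(roster, persons)
        as_set = lambda ds: {(d.roster_id, d.registry_id, d.key_level) for d in ds}
        assert as_set(fast) == as_set(slow)

    def test_cascade_minimality(self, noisy_sim):
        _, persons, _, _, roster, _ = noisy_sim
        decisions = link(roster, persons)
        reg_recs = {
            str(r.person_id): normalize(
                IdentifierRecord(r.first_name, r.last_name, r.birth_date.date(), str(r.ssn))
            )
            for r in persons.itertuples(index=False)
        }
        ros_recs = {
            str(r.roster_id): normalize(
                IdentifierRecord(
                    r.first_name, r.last_name,
                    r.birth_date.date() if not pd.isna(r.birth_date) else None,
                    "" if pd.isna(r.ssn) else str(r.ssn),
                )
            )
            for r in roster.itertuples(index=False)
        }
        for d in decisions:
            if not d.accepted:
                continue
            a, b = ros_recs[d.roster_id], reg_recs[d.registry_id]
            for lower in range(1, d.key_level):
                ka, kb = build_key(a, lower), build_key(b, lower)
                assert ka is None or kb is None or ka != kb

    def test_row_order_invariance(self, noisy_sim):
        _, persons, _, _, roster, _ = noisy_sim
        base = link(roster, persons)
        shuffled = link(
            roster.sample(frac=1, random_state=1),
            persons.sample(frac=1, random_state=2),
        )
        key = lambda ds: [(d.roster_id, d.registry_id, d.key_level, d.accepted) for d in ds]
        assert key(base) == key(shuffled)


class TestResolveDuplicates:
    def d(self, roster_id, registry_id, level, score):
        return MatchDecision(roster_id, registry_id, level, score=score)

    def test_lower_level_survives_registry_collision(self):
        decisions = [self.d("C1", "R1", 2, 90.0), self.d("C2", "R1", 7, 99.0)]
        out = resolve_duplicates(decisions)
        by_id = {x.roster_id: x for x in out}
        assert by_id["C1"].elimination_reason is None
        assert by_id["C2"].elimination_reason == "duplicate_loser"

    def test_score_breaks_level_ties(self):
        decisions = [self.d("C1", "R1", 2, 85.0), self.d("C2", "R1", 2, 95.0)]
        out = resolve_duplicates(decisions)
        by_id = {x.roster_id: x for x in out}
        assert by_id["C2"].elimination_reason is None
        assert by_id["C1"].elimination_reason == "duplicate_loser"

    def test_registry_id_breaks_full_ties(self):
        decisions = [self.d("C1", "R2", 2, 90.0), self.d("C1", "R1", 2, 90.0)]
        out = resolve_duplicates(decisions)
        kept = [x for x in out if x.elimination_reason is None]
        assert [(x.roster_id, x.registry_id) for x in kept] == [("C1", "R1")]

    def test_one_to_one_on_synthetic_run(self, noisy_sim):
        _, persons, _, _, roster, _ = noisy_sim
        accepted = [d for d in link(roster, persons) if d.accepted]
        assert len({d.roster_id for d in accepted}) == len(accepted)
        assert len({d.registry_id for d in accepted}) == len(accepted)


class TestReviewPolicy:
    def test_low_level_high_score_accepted(self):
        [d] = apply_review_policy([MatchDecision("C1", "R1", 3, score=95.0)])
        assert d.accepted and not d.review_flag

    def test_auto_reject_eliminates_partial_name_levels(self):
        [d] = apply_review_policy([MatchDecision("C1", "R1", 8, score=99.0)], policy="auto_reject")
        assert not d.accepted and d.elimination_reason == "manual_review" and d.review_flag

    def test_score_gate_enforces_threshold_at_80(self):
        [d] = apply_review_policy([MatchDecision("C1", "R1", 9, score=79.9)], policy="score_gate")
        assert not d.accepted and d.elimination_reason == "below_threshold"
        [d2] = apply_review_policy([MatchDecision("C1", "R1", 9, score=80.0)], policy="score_gate")
        assert d2.accepted

    def test_unknown_policy_rejected(self):
        with pytest.raises(ConfigurationError, match="policy"):
            apply_review_policy([], policy="flip_a_coin")


class TestEvaluation:
    def test_perfect_identifiers_give_perfect_linkage(self, clean_sim):
        _, persons, _, _, roster, truth = clean_sim
        ev = evaluate_linkage(link(roster, persons), set(truth.pairs))
        assert ev.precision == 1.0 and ev.recall == 1.0
        assert set(ev.per_level_accepted) == {1}

    def test_certain_ssn_missingness_moves_all_matches_to_level_2(self):
        config = SimConfig(
            n_persons=150, seed=19, corruption_rates=CorruptionRates(1.0, 0, 0, 0),
            labs_per_person_mean=1.0,
        )
        persons, _, _, roster, truth = simulate(config)
        ev = evaluate_linkage(link(roster, persons), set(truth.pairs))
        assert ev.recall == 1.0
        assert set(ev.per_level_accepted) == {2}

    def test_all_rejected_gives_undefined_precision_zero_recall(self, clean_sim):
        _, persons, _, _, roster, truth = clean_sim
        decisions = link(roster, persons, threshold=101.0)
        ev = evaluate_linkage(decisions, set(truth.pairs))
        assert ev.precision is None and ev.recall == 0.0

    def test_empty_truth_gives_undefined_recall(self, clean_sim):
        _, persons, _, _, roster, _ = clean_sim
        ev = evaluate_linkage(link(roster, persons), set())
        assert ev.recall is None

    def test_fallback_keys_never_lose_recall(self):
        config = SimConfig(
            n_persons=400, seed=23,
            corruption_rates=CorruptionRates(0.3, 0.1, 0.0, 0.0),
            labs_per_person_mean=1.0,
        )
        persons, _, _, roster, truth = simulate(config)
        pairs = set(truth.pairs)
        shallow = evaluate_linkage(link(roster, persons, levels=(1, 2)), pairs)
        full = evaluate_linkage(link(roster, persons), pairs)
        assert full.recall >= shallow.recall
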
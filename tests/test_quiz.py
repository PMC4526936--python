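"""Battery construction, the brute-force answer oracle, grading, and the
tutorial inclusion gate.

The oracle-equivalence suite re-derives every answer with an independent
naive counter written here (straight loops over the variant list, no shared
code paths with the implementation).
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from varreport.model import IMPORTANCE_ORDER, ReportDataset, canonical_order
from varreport.quiz import (
    CHOICE_OPTIONS,
    QUESTION_IDS,
    QuizError,
    ResponseSheet,
    TutorialResult,
    build_battery,
    grade_response,
    key_response_text,
    oracle_answers,
    parse_responses,
    tutorial_gate,
    write_responses,
)

from conftest import make_variant, random_dataset


# --------------------------------------------------------------------------
# independent naive oracle

def naive_key(ds: ReportDataset) -> dict[str, object]:
    def cmp(a, b):
        return "Greater than" if a > b else ("Less than" if a < b else "Equal to")

    high = [v for v in ds.variants if v.importance == "high"]
    low = [v for v in ds.variants if v.importance == "low"]
    wep = [
        v
        for v in ds.variants
        if v.impact == "pathogenic" and v.evidence == "well-established"
    ]
    up = [v for v in ds.variants if v.impact == "pathogenic" and v.evidence == "uncertain"]
    path = [v for v in ds.variants if v.impact == "pathogenic"]
    nonpath = [v for v in ds.variants if v.impact != "pathogenic"]

    conds: list[str] = []
    for v in ds.variants:
        for c in v.conditions:
            if c not in conds:
                conds.append(c)

    def risk(cond):
        w = {"low": 1, "medium": 2, "high": 4}
        total = 0
        for v in ds.variants:
            if cond in v.conditions:
                if v.impact == "pathogenic":
                    total += w[v.importance]
                elif v.impact == "protective":
                    total -= w[v.importance]
        return cmp(total, 0)

    options = conds[:8]
    learn = set()
    for c in options:
        for v in ds.variants:
            if (
                c in v.conditions
                and v.impact == "pathogenic"
                and v.importance in ("medium", "high")
            ):
                learn.add(c)
    return {
        "Q1": len(high),
        "Q2": len(wep),
        "Q3": cmp(len(low), len(high)),
        "Q4": cmp(len(up), len(wep)),
        "Q5": cmp(len(path), len(nonpath)),
        "Q6": {v.variant_id for v in high if v.impact == "pathogenic"},
        "Q7": risk(conds[0]),
        "Q8": risk(conds[1]),
        "Q9": learn,
    }


# --------------------------------------------------------------------------
# battery

class TestBattery:
    def test_nine_items_with_fixed_kinds(self, jamie):
        battery = build_battery(jamie)
        assert [q.id for q in battery] == list(QUESTION_IDS)
        kinds = [q.kind for q in battery]
        assert kinds == [
            "count_fill",
            "count_fill",
            "comparison_choice",
            "comparison_choice",
            "comparison_choice",
            "open_variants",
            "risk_choice",
            "risk_choice",
            "multi_select",
        ]

    def test_jamie_risk_prompts(self, jamie):
        battery = {q.id: q for q in build_battery(jamie)}
        assert "risk of developing" in battery["Q7"].prompt
        assert "stomach flu" in battery["Q7"].prompt
        assert "age-related macular degeneration" in battery["Q8"].prompt

    def test_choice_option_tokens(self, jamie):
        battery = {q.id: q for q in build_battery(jamie)}
        for qid in ("Q3", "Q4", "Q5"):
            assert battery[qid].options == (
                "Greater than",
                "Equal to",
                "Less than",
                "I don't know",
            )

    def test_too_few_conditions_rejected(self):
        ds = ReportDataset(
            subject="S",
            variants=(make_variant(1, conditions=("only one",)),),
        )
        with pytest.raises(QuizError, match="two linked conditions"):
            build_battery(ds)


# --------------------------------------------------------------------------
# oracle

class TestOracle:
    def test_toy_counts(self, toy):
        key = oracle_answers(toy)
        assert key.answers["Q1"] == 2
        assert key.answers["Q3"] == "Greater than"  # 5 low vs 2 high

    def test_protective_only_condition_is_less_than(self):
        variants = (
            make_variant(
                1, "protective", "well-established", "high", conditions=("condition C",)
            ),
            make_variant(2, "pathogenic", "likely", "medium", conditions=("other",)),
        )
        ds = canonical_order(ReportDataset(subject="S", variants=variants))
        key = oracle_answers(ds)
        qid = "Q7" if key.risk_conditions[0] == "condition C" else "Q8"
        assert key.answers[qid] == "Less than"

    def test_exhaustive_small_datasets_match_naive(self):
        """Every (impact, evidence, importance) combination appears across a
        sampled sweep of datasets up to 6 variants; the oracle must agree with
        the naive counter on each."""
        rng = np.random.default_rng(17)
        combos = list(
            itertools.product(
                ("pathogenic", "benign", "protective"),
                ("well-established", "likely", "uncertain"),
                ("low", "medium", "high"),
            )
        )
        pool = ("alpha syndrome", "beta disease", "gamma deficiency")
        for _ in range(300):
            size = int(rng.integers(2, 7))
            chosen = [combos[int(rng.integers(0, len(combos)))] for _ in range(size)]
            variants = tuple(
                make_variant(
                    i + 1,
                    impact=im,
                    evidence=ev,
                    importance=imp,
                    conditions=tuple(
                        pool[j] for j in range(3) if rng.random() < 0.5
                    ),
                )
                for i, (im, ev, imp) in enumerate(chosen)
            )
            ds = canonical_order(ReportDataset(subject="S", variants=variants))
            conds = {c for v in ds.variants for c in v.conditions}
            if len(conds) < 2:
                continue
            key = oracle_answers(ds)
            expected = naive_key(ds)
            for qid in QUESTION_IDS:
                got = key.answers[qid]
                want = expected[qid]
                if isinstance(want, set):
                    assert set(got) == want, qid
                else:
                    assert got == want, qid

    def test_seeded_synthetic_datasets_match_naive(self):
        rng = np.random.default_rng(2015)
        checked = 0
        while checked < 1000:
            ds = random_dataset(rng)
            conds = {c for v in ds.variants for c in v.conditions}
            if len(conds) < 2:
                continue
            key = oracle_answers(ds)
            expected = naive_key(ds)
            for qid in QUESTION_IDS:
                got = key.answers[qid]
                want = expected[qid]
                if isinstance(want, set):
                    assert set(got) == want, qid
                else:
                    assert got == want, qid
            checked += 1


# --------------------------------------------------------------------------
# grading

def perfect_sheet(ds, key, participant="p1", condition="table") -> ResponseSheet:
    return ResponseSheet(
        participant=participant,
        condition=condition,
        answers={qid: key_response_text(key, ds, qid) for qid in QUESTION_IDS},
        likert={},
    )


class TestGrading:
    def test_perfect_sheet_scores_ten(self, jamie):
        key = oracle_answers(jamie)
        rec = grade_response(perfect_sheet(jamie, key), key, jamie)
        assert rec.score == 10.0

    def test_blank_sheet_scores_zero(self, jamie):
        key = oracle_answers(jamie)
        sheet = ResponseSheet("p", "table", {q: "" for q in QUESTION_IDS})
        assert grade_response(sheet, key, jamie).score == 0.0

    def test_q9_fully_wrong_gives_eight(self, jamie):
        key = oracle_answers(jamie)
        sheet = perfect_sheet(jamie, key)
        wrong = set(key.multi_options) - set(key.answers["Q9"])
        complement = set(key.multi_options) - set(key.answers["Q9"]) | set()
        # answer with the exact complement: every option-level call is wrong
        answers = dict(sheet.answers)
        answers["Q9"] = ";".join(sorted(set(key.multi_options) - set(key.answers["Q9"])))
        rec = grade_response(
            ResponseSheet("p", "table", answers), key, jamie
        )
        assert rec.score == pytest.approx(8.0)
        assert rec.credits["Q9"] == 0.0

    def test_q6_partial_credit_and_penalty(self, jamie):
        key = oracle_answers(jamie)
        labels = {
            v.variant_id: v.label for v in jamie.variants
        }
        key_ids = sorted(key.answers["Q6"])
        assert len(key_ids) == 2
        base = {q: "" for q in QUESTION_IDS}
        # one correct of two -> half credit
        one = dict(base, Q6=labels[key_ids[0]])
        assert grade_response(ResponseSheet("p", "t", one), key, jamie).credits[
            "Q6"
        ] == pytest.approx(0.5)
        # one correct + one incorrect -> net zero
        non_key = next(v.label for v in jamie.variants if v.variant_id not in key_ids)
        mixed = dict(base, Q6=f"{labels[key_ids[0]]};{non_key}")
        assert grade_response(ResponseSheet("p", "t", mixed), key, jamie).credits[
            "Q6"
        ] == 0.0
        # gene-symbol, case-insensitive match also counts
        gene = next(v.gene for v in jamie.variants if v.variant_id == key_ids[0])
        upper = dict(base, Q6=gene.upper())
        assert grade_response(ResponseSheet("p", "t", upper), key, jamie).credits[
            "Q6"
        ] == pytest.approx(0.5)

    def test_out_of_vocabulary_choice_scores_zero(self, jamie):
        key = oracle_answers(jamie)
        sheet = perfect_sheet(jamie, key)
        answers = dict(sheet.answers, Q3="Way more")
        rec = grade_response(ResponseSheet("p", "t", answers), key, jamie)
        assert rec.credits["Q3"] == 0.0

    def test_bounds_and_monotonicity_randomized(self, jamie):
        """Score always in [0, 10]; correcting any single wrong answer never
        lowers the score; 10 is attained only by the key."""
        rng = np.random.default_rng(31)
        key = oracle_answers(jamie)
        truth = {q: key_response_text(key, jamie, q) for q in QUESTION_IDS}
        distractors = {
            **{q: ["0", "17", ""] for q in ("Q1", "Q2")},
            **{q: [o for o in CHOICE_OPTIONS] + [""] for q in ("Q3", "Q4", "Q5", "Q7", "Q8")},
            "Q6": ["", "GENE999", truth["Q6"].split(";")[0]],
            "Q9": ["", ";".join(sorted(key.multi_options)[:2])],
        }
        for _ in range(150):
            answers = {}
            for q in QUESTION_IDS:
                if rng.random() < 0.4:
                    answers[q] = truth[q]
                else:
                    opts = distractors[q]
                    answers[q] = opts[int(rng.integers(0, len(opts)))]
            sheet = ResponseSheet("p", "t", answers)
            rec = grade_response(sheet, key, jamie)
            assert 0.0 <= rec.score <= 10.0
            wrong = [q for q in QUESTION_IDS if answers[q] != truth[q]]
            if not wrong:
                assert rec.score == 10.0
            else:
                fix = wrong[int(rng.integers(0, len(wrong)))]
                fixed = dict(answers, **{fix: truth[fix]})
                rec2 = grade_response(ResponseSheet("p", "t", fixed), key, jamie)
                assert rec2.score >= rec.score - 1e-12


class TestTutorialGate:
    @pytest.mark.parametrize(
        "n_correct,included", [(0, False), (2, False), (3, True), (6, True)]
    )
    def test_threshold(self, n_correct, included):
        flags = tuple(i < n_correct for i in range(6))
        assert tutorial_gate(TutorialResult(flags)) is included

    def test_wrong_length_rejected(self):
        with pytest.raises(QuizError):
            tutorial_gate(TutorialResult((True,) * 5))  # type: ignore[arg-type]


def test_response_csv_round_trip(jamie):
    key = oracle_answers(jamie)
    sheets = [
        perfect_sheet(jamie, key, "p1", "bubble"),
        ResponseSheet(
            "p2",
            "table",
            {q: "" for q in QUESTION_IDS},
            likert={"Q10": 5, "Q11": 3, "Q12": None, "Q13": None, "Q14": 1,
                    "Q15": None, "Q16": 2},
            started_at="t0",
            finished_at="t1",
        ),
    ]
    text = write_responses(sheets)
    back = parse_responses(text)
    assert back[0].answers == sheets[0].answers
    assert back[1].likert["Q10"] == 5 and back[1].likert["Q12"] is None
    assert back[1].started_at == "t0"
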
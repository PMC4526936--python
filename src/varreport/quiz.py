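"""Comprehension-quiz battery, brute-force answer key, and 0-10 grading.

The battery mirrors the nine comprehension items used to compare the report
designs: two count fill-ins (high-importance variants; well-established
pathogenic variants), three count comparisons, one open "which variants would
you discuss with a clinician" item, two condition-risk comparisons, and one
"select all that apply" condition multi-select.  Ground truth is derived from
the dataset alone by direct counting, so any report rendering can be graded
against it.

Scoring rubric (totals 10):

* Q1-Q5, Q7, Q8 — 1 point each, exact match;
* Q6 — 1 point, fractional: (correct named - incorrect named)+ / |key|,
  gene-symbol/label matching case-insensitive;
* Q9 — 2 points, fractional: option-level agreement with the key over the
  8 options (a blank sheet item scores 0);
* blanks and out-of-vocabulary tokens score 0; totals are clipped to [0, 10].
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field

from .model import IMPORTANCE_ORDER, IMPORTANCE_WEIGHT, ReportDataset, VariantAnnotation

CHOICE_OPTIONS = ("Greater than", "Equal to", "Less than", "I don't know")

QUESTION_IDS = ("Q1", "Q2", "Q3", "Q4", "Q5", "Q6", "Q7", "Q8", "Q9")
LIKERT_IDS = ("Q10", "Q11", "Q12", "Q13", "Q14", "Q15", "Q16")

#: points available per question (sums to 10)
POINTS = {
    "Q1": 1.0,
    "Q2": 1.0,
    "Q3": 1.0,
    "Q4": 1.0,
    "Q5": 1.0,
    "Q6": 1.0,
    "Q7": 1.0,
    "Q8": 1.0,
    "Q9": 2.0,
}

MULTI_SELECT_SLOTS = 8


class QuizError(Exception):
    pass


@dataclass(frozen=True)
class Question:
    id: str
    kind: str  # count_fill | comparison_choice | open_variants | risk_choice | multi_select
    prompt: str
    options: tuple[str, ...] = ()
    subject_condition: str | None = None


@dataclass(frozen=True)
class AnswerKey:
    """Canonical answers per question id; values are ints, tokens, or frozensets."""

    answers: dict[str, object]
    risk_conditions: tuple[str, str]
    multi_options: tuple[str, ...]


@dataclass(frozen=True)
class ResponseSheet:
    participant: str
    condition: str
    answers: dict[str, str]  # question id -> raw answer text ("" = blank)
    likert: dict[str, int | None] = field(default_factory=dict)
    started_at: str = ""
    finished_at: str = ""


@dataclass(frozen=True)
class TutorialResult:
    correct: tuple[bool, bool, bool, bool, bool, bool]


@dataclass(frozen=True)
class ScoreRecord:
    participant: str
    condition: str
    score: float
    credits: dict[str, float]


# ---------------------------------------------------------------------------
# battery construction

def dataset_conditions(dataset: ReportDataset) -> list[str]:
    """Distinct condition names in canonical (first-appearance) order."""
    seen: list[str] = []
    for v in dataset.variants:
        for c in v.conditions:
            if c not in seen:
                seen.append(c)
    return seen


def risk_conditions(dataset: ReportDataset) -> tuple[str, str]:
    conds = dataset_conditions(dataset)
    if len(conds) < 2:
        raise QuizError(
            "battery needs at least two linked conditions to instantiate risk items"
        )
    return conds[0], conds[1]


def multi_select_options(dataset: ReportDataset) -> tuple[str, ...]:
    """Up to eight condition options for the select-all-that-apply item."""
    return tuple(dataset_conditions(dataset)[:MULTI_SELECT_SLOTS])


def build_battery(dataset: ReportDataset) -> list[Question]:
    subject = dataset.subject or "the subject"
    cond_a, cond_b = risk_conditions(dataset)
    options = multi_select_options(dataset)
    return [
        Question(
            "Q1",
            "count_fill",
            "The number of variants with high clinical importance: _______",
        ),
        Question(
            "Q2",
            "count_fill",
            "The number of variants that are well-established pathogenic: _______",
        ),
        Question(
            "Q3",
            "comparison_choice",
            f"The number of variants in {subject}'s report with low clinical "
            "importance is ________ the number of variants with high clinical "
            "importance.",
            CHOICE_OPTIONS,
        ),
        Question(
            "Q4",
            "comparison_choice",
            f"The number of uncertain pathogenic variants in {subject}'s report "
            "is ________ the number of well-established pathogenic variants.",
            CHOICE_OPTIONS,
        ),
        Question(
            "Q5",
            "comparison_choice",
            f"The number of potentially pathogenic variants in {subject}'s "
            "report is ________ the number of potentially benign or protective "
            "variants.",
            CHOICE_OPTIONS,
        ),
        Question(
            "Q6",
            "open_variants",
            f"Which variants would {subject} be most likely to discuss with a "
            "health care provider?",
        ),
        Question(
            "Q7",
            "risk_choice",
            f"{subject}'s risk of developing {cond_a} is ________ the average "
            "person.",
            CHOICE_OPTIONS,
            subject_condition=cond_a,
        ),
        Question(
            "Q8",
            "risk_choice",
            f"{subject}'s risk of developing {cond_b} is ________ the average "
            "person.",
            CHOICE_OPTIONS,
            subject_condition=cond_b,
        ),
        Question(
            "Q9",
            "multi_select",
            f"If you were {subject}, knowing this information, which of the "
            "following conditions would you be interested in learning more "
            "about? Select all that apply.",
            options,
        ),
    ]


# ---------------------------------------------------------------------------
# brute-force answer key

def _compare(a: int, b: int) -> str:
    if a > b:
        return "Greater than"
    if a < b:
        return "Less than"
    return "Equal to"


_RISK_SIGN = {"pathogenic": 1, "benign": 0, "protective": -1}


def condition_risk_answer(dataset: ReportDataset, condition: str) -> str:
    """Risk direction for a condition from its linked variants.

    Signed evidence score = sum over linked variants of
    sign(impact) x importance weight (pathogenic +, protective -, benign 0;
    weights 1/2/4 for low/medium/high).  Positive -> elevated risk.
    """
    score = 0
    for v in dataset.variants:
        if condition in v.conditions:
            score += _RISK_SIGN[v.impact] * IMPORTANCE_WEIGHT[v.importance]
    if score > 0:
        return "Greater than"
    if score < 0:
        return "Less than"
    return "Equal to"


def oracle_answers(dataset: ReportDataset) -> AnswerKey:
    """Ground-truth answers computed by direct counting over the dataset."""
    vs = dataset.variants
    n_high = sum(1 for v in vs if v.importance == "high")
    n_low = sum(1 for v in vs if v.importance == "low")
    n_wep = sum(
        1 for v in vs if v.impact == "pathogenic" and v.evidence == "well-established"
    )
    n_up = sum(1 for v in vs if v.impact == "pathogenic" and v.evidence == "uncertain")
    n_path = sum(1 for v in vs if v.impact == "pathogenic")
    n_other = sum(1 for v in vs if v.impact in ("benign", "protective"))
    cond_a, cond_b = risk_conditions(dataset)
    options = multi_select_options(dataset)
    discuss = frozenset(
        v.variant_id for v in vs if v.importance == "high" and v.impact == "pathogenic"
    )
    learn_more = frozenset(
        c
        for c in options
        if any(
            c in v.conditions
            and v.impact == "pathogenic"
            and IMPORTANCE_ORDER[v.importance] >= IMPORTANCE_ORDER["medium"]
            for v in vs
        )
    )
    answers: dict[str, object] = {
        "Q1": n_high,
        "Q2": n_wep,
        "Q3": _compare(n_low, n_high),
        "Q4": _compare(n_up, n_wep),
        "Q5": _compare(n_path, n_other),
        "Q6": discuss,
        "Q7": condition_risk_answer(dataset, cond_a),
        "Q8": condition_risk_answer(dataset, cond_b),
        "Q9": learn_more,
    }
    return AnswerKey(answers=answers, risk_conditions=(cond_a, cond_b), multi_options=options)


def key_response_text(key: AnswerKey, dataset: ReportDataset, qid: str) -> str:
    """The key's answer for ``qid`` rendered as a response-sheet string."""
    ans = key.answers[qid]
    if qid == "Q6":
        labels = sorted(
            v.label for v in dataset.variants if v.variant_id in ans  # type: ignore[operator]
        )
        return ";".join(labels)
    if qid == "Q9":
        return ";".join(sorted(ans))  # type: ignore[arg-type]
    return str(ans)


# ---------------------------------------------------------------------------
# grading

def _match_variants(named: list[str], dataset: ReportDataset) -> set[str]:
    """Resolve free-text variant mentions to variant ids (case-insensitive)."""
    index: dict[str, str] = {}
    for v in dataset.variants:
        for alias in (v.variant_id, v.gene, v.label):
            if alias:
                index.setdefault(alias.lower(), v.variant_id)
    return {index[t.lower()] for t in named if t.lower() in index}


def grade_response(
    sheet: ResponseSheet, key: AnswerKey, dataset: ReportDataset
) -> ScoreRecord:
    """Grade one response sheet against the answer key."""
    credits: dict[str, float] = {}
    for qid in QUESTION_IDS:
        raw = sheet.answers.get(qid, "").strip()
        if raw == "":
            credits[qid] = 0.0
            continue
        ans = key.answers[qid]
        if qid in ("Q1", "Q2"):
            try:
                credits[qid] = POINTS[qid] * float(int(raw) == ans)
            except ValueError:
                credits[qid] = 0.0
        elif qid in ("Q3", "Q4", "Q5", "Q7", "Q8"):
            if raw not in CHOICE_OPTIONS:
                credits[qid] = 0.0
            else:
                credits[qid] = POINTS[qid] * float(raw == ans)
        elif qid == "Q6":
            named = [t for t in raw.split(";") if t.strip()]
            matched = _match_variants(named, dataset)
            correct = len(matched & ans)  # type: ignore[operator]
            wrong = len(named) - correct
            if len(ans) == 0:  # type: ignore[arg-type]
                credits[qid] = POINTS[qid] if not named else 0.0
            else:
                credits[qid] = POINTS[qid] * max(0, correct - wrong) / len(ans)  # type: ignore[arg-type]
        else:  # Q9
            selected = {t for t in raw.split(";") if t.strip()}
            unknown = selected - set(key.multi_options)
            selected &= set(key.multi_options)
            agreements = sum(
                1
                for opt in key.multi_options
                if (opt in selected) == (opt in ans)  # type: ignore[operator]
            )
            # unknown tokens are disagreements by construction: log-and-zero rule
            credits[qid] = (
                POINTS[qid] * agreements / MULTI_SELECT_SLOTS if not unknown else 0.0
            )
    score = min(10.0, max(0.0, sum(credits.values())))
    return ScoreRecord(
        participant=sheet.participant,
        condition=sheet.condition,
        score=score,
        credits=credits,
    )


def tutorial_gate(result: TutorialResult) -> bool:
    """Include a participant iff at least 3 of the 6 pre-task items are correct."""
    if len(result.correct) != 6:
        raise QuizError("tutorial quiz has exactly six items")
    return sum(result.correct) >= 3


# ---------------------------------------------------------------------------
# serialization

RESPONSE_COLUMNS = (
    ["participant", "condition"]
    + [q.lower() for q in QUESTION_IDS]
    + [q.lower() for q in LIKERT_IDS]
    + ["started_at", "finished_at"]
)


def write_responses(sheets: list[ResponseSheet]) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(RESPONSE_COLUMNS)
    for s in sheets:
        row = [s.participant, s.condition]
        row += [s.answers.get(q, "") for q in QUESTION_IDS]
        row += [
            "" if s.likert.get(q) is None else str(s.likert[q]) for q in LIKERT_IDS
        ]
        row += [s.started_at, s.finished_at]
        writer.writerow(row)
    return buf.getvalue()


def parse_responses(text: str) -> list[ResponseSheet]:
    reader = csv.reader(io.StringIO(text))
    header = next(reader)
    if header != RESPONSE_COLUMNS:
        raise QuizError(f"unexpected response header: {header}")
    sheets = []
    for row in reader:
        rec = dict(zip(header, row))
        likert: dict[str, int | None] = {}
        for q in LIKERT_IDS:
            cell = rec[q.lower()]
            if cell == "":
                likert[q] = None
            else:
                val = int(cell)
                if not 1 <= val <= 5:
                    raise QuizError(f"Likert value {val} outside 1..5")
                likert[q] = val
        sheets.append(
            ResponseSheet(
                participant=rec["participant"],
                condition=rec["condition"],
                answers={q: rec[q.lower()] for q in QUESTION_IDS},
                likert=likert,
                started_at=rec["started_at"],
                finished_at=rec["finished_at"],
            )
        )
    return sheets


def battery_json(questions: list[Question], key: AnswerKey, dataset: ReportDataset) -> str:
    doc = {
        "questions": [
            {
                "id": q.id,
                "kind": q.kind,
                "prompt": q.prompt,
                "options": list(q.options),
                "subject_condition": q.subject_condition,
            }
            for q in questions
        ],
        "answer_key": {
            qid: key_response_text(key, dataset, qid) for qid in QUESTION_IDS
        },
    }
    return json.dumps(doc, sort_keys=True, indent=1)
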
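"""Seeded generation of report datasets and simulated participant cohorts.

The generator emulates the kind of fictional single-subject dataset used to
compare report designs on identical data: a configurable number of variants in
every (importance, impact, evidence) cell, links into a fixed pool of
condition names, and plausible allele frequencies per impact class.  Gene
symbols are drawn from a fictional ``GENE###`` pool so the output can never be
mistaken for real medical content.

``simulate_responses`` fabricates participant response sheets with a planted
per-design correct-answer probability, which lets the downstream scoring and
ANOVA/Tukey pipeline be exercised end-to-end with known ground truth.

All sampling flows through one ``numpy.random.Generator`` seeded explicitly,
so identical seeds give byte-identical artifacts on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    EVIDENCE_VALUES,
    IMPACT_VALUES,
    IMPORTANCE_VALUES,
    GlossaryEntry,
    ReportDataset,
    VariantAnnotation,
    canonical_order,
    validate_dataset,
)
from .quiz import (
    CHOICE_OPTIONS,
    LIKERT_IDS,
    QUESTION_IDS,
    AnswerKey,
    ResponseSheet,
    key_response_text,
)

Cell = tuple[str, str, str]  # (importance, impact, evidence)

DEFAULT_CONDITION_POOL = (
    "stomach flu",
    "age-related macular degeneration",
    "Alzheimer's disease",
    "Parkinson's disease",
    "liver disease",
    "colon cancer",
    "diabetes",
    "emphysema",
    "tuberculosis",
    "eye disease",
)

#: plausible population allele-frequency ranges per impact class; these only
#: affect tooltip text, never any scored computation
DEFAULT_FREQUENCY_RANGES = {
    "pathogenic": (0.0001, 0.05),
    "protective": (0.001, 0.10),
    "benign": (0.05, 0.50),
}

GENE_POOL_SIZE = 500

#: default cell counts: a small report with all tiers and impacts populated,
#: pathogenic variants skewed toward higher importance
DEFAULT_COUNTS: dict[Cell, int] = {
    ("high", "pathogenic", "well-established"): 2,
    ("high", "pathogenic", "likely"): 1,
    ("medium", "pathogenic", "uncertain"): 2,
    ("medium", "benign", "likely"): 1,
    ("medium", "protective", "well-established"): 1,
    ("low", "benign", "well-established"): 2,
    ("low", "benign", "uncertain"): 2,
    ("low", "protective", "likely"): 1,
    ("low", "protective", "uncertain"): 2,
}

DESIGN_CONDITIONS = (
    "table",
    "bar",
    "bubble",
    "treemap",
    "heatmap",
    "zoom_treemap",
    "zoom_partition",
)


class SynthError(Exception):
    pass


@dataclass(frozen=True)
class SynthSpec:
    counts: dict[Cell, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    condition_pool: tuple[str, ...] = DEFAULT_CONDITION_POOL
    links_per_variant: tuple[int, int] = (1, 2)
    frequency_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FREQUENCY_RANGES)
    )
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.counts.values())
        if total < 1:
            raise SynthError("spec must request at least one variant")
        if any(n < 0 for n in self.counts.values()):
            raise SynthError("negative cell count")
        for imp, (lo, hi) in self.frequency_ranges.items():
            if not (0.0 <= lo <= hi <= 1.0):
                raise SynthError(f"invalid frequency range for {imp}: [{lo}, {hi}]")
        lo, hi = self.links_per_variant
        if not (0 <= lo <= hi):
            raise SynthError("invalid links_per_variant range")


@dataclass(frozen=True)
class ResponderModel:
    """Planted per-design accuracy for simulated participants."""

    p_correct: dict[str, float]
    count_noise: tuple[int, ...] = (1, 2, 3)  # magnitudes for wrong count answers
    seed: int = 0

    def validate(self) -> None:
        for cond, p in self.p_correct.items():
            if not 0.0 <= p <= 1.0:
                raise SynthError(f"invalid probability {p} for condition {cond!r}")


DEFAULT_GLOSSARY = (
    GlossaryEntry(
        "allele frequency",
        "How common a variant is: the fraction of chromosomes in the population "
        "that carry it.",
    ),
    GlossaryEntry(
        "homozygous",
        "Carrying the same variant on both chromosome copies.",
    ),
    GlossaryEntry(
        "pathogenic",
        "Reported to be harmful: associated with increased risk of a condition.",
    ),
    GlossaryEntry(
        "benign",
        "Reported to have no known effect on health.",
    ),
    GlossaryEntry(
        "protective",
        "Reported to reduce the risk of a condition.",
    ),
    GlossaryEntry(
        "well-established",
        "The evidence for the reported effect is strong and replicated.",
    ),
    GlossaryEntry(
        "uncertain",
        "The evidence for the reported effect is weak or preliminary.",
    ),
)


def generate_dataset(spec: SynthSpec, subject: str = "Jamie") -> ReportDataset:
    """Generate a validated dataset with exactly the requested cell counts."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    total = sum(spec.counts.values())
    if total > GENE_POOL_SIZE:
        raise SynthError(
            f"requested {total} variants but the gene pool has {GENE_POOL_SIZE} symbols"
        )
    gene_indices = rng.choice(GENE_POOL_SIZE, size=total, replace=False)
    variants = []
    i = 0
    # iterate cells in fixed enum order for determinism
    for importance in IMPORTANCE_VALUES:
        for impact in IMPACT_VALUES:
            for evidence in EVIDENCE_VALUES:
                count = spec.counts.get((importance, impact, evidence), 0)
                for _ in range(count):
                    gene = f"GENE{gene_indices[i] + 1:03d}"
                    lo, hi = spec.frequency_ranges[impact]
                    freq = float(rng.uniform(lo, hi))
                    n_links = int(
                        rng.integers(
                            spec.links_per_variant[0], spec.links_per_variant[1] + 1
                        )
                    )
                    n_links = min(n_links, len(spec.condition_pool))
                    if n_links:
                        picked = rng.choice(
                            len(spec.condition_pool), size=n_links, replace=False
                        )
                        conditions = tuple(
                            spec.condition_pool[j] for j in sorted(picked)
                        )
                    else:
                        conditions = ()
                    zygosity = ("heterozygous", "homozygous")[int(rng.integers(0, 2))]
                    residue = int(rng.integers(10, 999))
                    label = f"{gene} p.A{residue}T"
                    summary = (
                        f"{label} is a {evidence} {impact} variant of {importance} "
                        f"clinical importance"
                        + (
                            f" linked to {', '.join(conditions)}."
                            if conditions
                            else "."
                        )
                    )
                    variants.append(
                        VariantAnnotation(
                            variant_id=f"var{i + 1:04d}",
                            gene=gene,
                            label=label,
                            zygosity=zygosity,
                            allele_frequency=freq,
                            impact=impact,
                            evidence=evidence,
                            importance=importance,
                            conditions=conditions,
                            summary=summary,
                            links=(f"https://example.org/variant/{gene.lower()}",),
                        )
                    )
                    i += 1
    ds = canonical_order(
        ReportDataset(subject=subject, variants=tuple(variants), glossary=DEFAULT_GLOSSARY)
    )
    validate_dataset(ds)
    return ds


def jamie_fixture() -> ReportDataset:
    """The packaged canonical demo dataset for the fictional subject Jamie.

    Covers all three importance tiers, all three impacts, and mixed evidence
    levels.  The two first-appearing conditions (which instantiate the two
    risk items) are "stomach flu" and "age-related macular degeneration",
    each linked only to pathogenic variants so the risk direction is
    unambiguous; protective links use other conditions.
    """

    def v(i, gene, zyg, freq, impact, evidence, importance, conds, extra=""):
        label = f"{gene} p.{extra}" if extra else gene
        summary = (
            f"{label} is a {evidence} {impact} variant of {importance} clinical "
            f"importance" + (f" linked to {', '.join(conds)}." if conds else ".")
        )
        return VariantAnnotation(
            variant_id=f"jamie{i:02d}",
            gene=gene,
            label=label,
            zygosity=zyg,
            allele_frequency=freq,
            impact=impact,
            evidence=evidence,
            importance=importance,
            conditions=tuple(conds),
            summary=summary,
            links=(f"https://example.org/variant/{gene.lower()}",),
        )

    sf = "stomach flu"
    amd = "age-related macular degeneration"
    variants = (
        # high importance: the variants Jamie would discuss with a clinician
        v(1, "GENE101", "heterozygous", 0.004, "pathogenic", "well-established", "high",
          [sf], "R212W"),
        v(2, "GENE102", "homozygous", 0.012, "pathogenic", "likely", "high",
          [amd, "colon cancer"], "G55D"),
        v(3, "GENE103", "heterozygous", 0.03, "protective", "well-established", "high",
          ["emphysema"], "T89M"),
        # medium importance
        v(4, "GENE104", "heterozygous", 0.02, "pathogenic", "uncertain", "medium",
          ["diabetes"], "L310F"),
        v(5, "GENE105", "homozygous", 0.15, "benign", "likely", "medium",
          ["eye disease"], "S12P"),
        v(6, "GENE106", "heterozygous", 0.04, "pathogenic", "likely", "medium",
          ["Alzheimer's disease"], "E77K"),
        # low importance
        v(7, "GENE107", "homozygous", 0.22, "benign", "well-established", "low",
          [], "V5I"),
        v(8, "GENE108", "heterozygous", 0.31, "benign", "uncertain", "low",
          ["tuberculosis"], "P140S"),
        v(9, "GENE109", "heterozygous", 0.06, "protective", "likely", "low",
          ["liver disease"], "H23Y"),
        v(10, "GENE110", "homozygous", 0.09, "protective", "uncertain", "low",
          ["emphysema"], "D301N"),
        v(11, "GENE111", "heterozygous", 0.27, "benign", "likely", "low",
          ["Parkinson's disease"], "A66V"),
    )
    ds = canonical_order(
        ReportDataset(subject="Jamie", variants=variants, glossary=DEFAULT_GLOSSARY)
    )
    validate_dataset(ds)
    return ds


# ---------------------------------------------------------------------------
# simulated cohorts

def _wrong_choice(rng: np.random.Generator, correct: str) -> str:
    wrong = [o for o in CHOICE_OPTIONS if o != correct]
    return wrong[int(rng.integers(0, len(wrong)))]


def _wrong_count(rng: np.random.Generator, correct: int, noise: tuple[int, ...]) -> int:
    magnitude = noise[int(rng.integers(0, len(noise)))]
    offset = magnitude if rng.integers(0, 2) else -magnitude
    value = max(0, correct + offset)
    if value == correct:  # clamping at zero hit the true count; flip upward
        value = correct + magnitude
    return value


def simulate_responses(
    dataset: ReportDataset,
    key: AnswerKey,
    model: ResponderModel,
    n_per_condition: int,
) -> list[ResponseSheet]:
    """Simulate a balanced cohort of response sheets with planted accuracy."""
    model.validate()
    rng = np.random.default_rng(model.seed)
    sheets = []
    conditions = [c for c in DESIGN_CONDITIONS if c in model.p_correct]
    pid = 0
    for condition in conditions:
        p = model.p_correct[condition]
        for _ in range(n_per_condition):
            pid += 1
            answers: dict[str, str] = {}
            for qid in QUESTION_IDS:
                correct = rng.random() < p
                truth = key_response_text(key, dataset, qid)
                if correct:
                    answers[qid] = truth
                elif qid in ("Q1", "Q2"):
                    answers[qid] = str(
                        _wrong_count(rng, int(key.answers[qid]), model.count_noise)
                    )
                elif qid in ("Q3", "Q4", "Q5", "Q7", "Q8"):
                    answers[qid] = _wrong_choice(rng, str(key.answers[qid]))
                elif qid == "Q6":
                    # name one variant that is not in the key (or nothing)
                    non_key = sorted(
                        v.label
                        for v in dataset.variants
                        if v.variant_id not in key.answers["Q6"]  # type: ignore[operator]
                    )
                    answers[qid] = (
                        non_key[int(rng.integers(0, len(non_key)))] if non_key else ""
                    )
                else:  # Q9: flip one random option relative to the key
                    selected = set(key.answers["Q9"])  # type: ignore[arg-type]
                    flip = key.multi_options[
                        int(rng.integers(0, len(key.multi_options)))
                    ]
                    selected ^= {flip}
                    answers[qid] = ";".join(sorted(selected))
            likert = {q: int(rng.integers(1, 6)) for q in LIKERT_IDS}
            sheets.append(
                ResponseSheet(
                    participant=f"p{pid:05d}",
                    condition=condition,
                    answers=answers,
                    likert=likert,
                    started_at="2015-01-01T00:00:00Z",
                    finished_at="2015-01-01T00:12:00Z",
                )
            )
    return sheets
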
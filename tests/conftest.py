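"""Shared fixtures: the packaged Jamie dataset, a small counting fixture, and
random dataset helpers used by the oracle-equivalence suites."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from varreport.model import (
    EVIDENCE_VALUES,
    IMPACT_VALUES,
    IMPORTANCE_VALUES,
    ReportDataset,
    VariantAnnotation,
    canonical_order,
)
from varreport.synth import DEFAULT_GLOSSARY, SynthSpec, generate_dataset, jamie_fixture


def make_variant(
    i: int,
    impact: str = "benign",
    evidence: str = "likely",
    importance: str = "low",
    conditions: tuple[str, ...] = (),
    gene: str | None = None,
    frequency: float = 0.1,
    summary: str | None = None,
) -> VariantAnnotation:
    gene = gene or f"GENE{900 + i}"
    label = f"{gene} p.A{i}T"
    return VariantAnnotation(
        variant_id=f"v{i:03d}",
        gene=gene,
        label=label,
        zygosity="heterozygous",
        allele_frequency=frequency,
        impact=impact,
        evidence=evidence,
        importance=importance,
        conditions=conditions,
        summary=summary if summary is not None else f"{label} summary text.",
        links=(),
    )


@pytest.fixture(scope="session")
def jamie() -> ReportDataset:
    return jamie_fixture()


@pytest.fixture(scope="session")
def toy() -> ReportDataset:
    """2 high / 3 medium / 5 low variants; both high are well-established
    pathogenic, so the small counting examples have known answers."""
    cells = [
        ("pathogenic", "well-established", "high", ("migraine",)),
        ("pathogenic", "well-established", "high", ("gout",)),
        ("pathogenic", "uncertain", "medium", ("migraine",)),
        ("benign", "likely", "medium", ()),
        ("protective", "well-established", "medium", ("gout",)),
        ("benign", "well-established", "low", ()),
        ("benign", "uncertain", "low", ()),
        ("protective", "likely", "low", ("anemia",)),
        ("protective", "uncertain", "low", ()),
        ("pathogenic", "likely", "low", ("anemia",)),
    ]
    variants = tuple(
        make_variant(i + 1, impact=im, evidence=ev, importance=imp, conditions=conds)
        for i, (im, ev, imp, conds) in enumerate(cells)
    )
    return canonical_order(
        ReportDataset(subject="Toy", variants=variants, glossary=DEFAULT_GLOSSARY)
    )


def random_spec(rng: np.random.Generator, max_per_cell: int = 2) -> SynthSpec:
    """A random cell-count spec guaranteed to request at least one variant
    and at least two linked conditions (so the battery instantiates)."""
    cells = list(itertools.product(IMPORTANCE_VALUES, IMPACT_VALUES, EVIDENCE_VALUES))
    counts = {c: int(rng.integers(0, max_per_cell + 1)) for c in cells}
    if sum(counts.values()) == 0:
        counts[cells[int(rng.integers(0, len(cells)))]] = 1
    return SynthSpec(counts=counts, links_per_variant=(1, 2), seed=int(rng.integers(0, 2**31)))


def random_dataset(rng: np.random.Generator, max_per_cell: int = 2) -> ReportDataset:
    return generate_dataset(random_spec(rng, max_per_cell))
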
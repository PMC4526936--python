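"""Data model, validation, and I/O for annotated personal-genomics variant reports.

A report is a flat list of gene-variant annotations of the kind shown to
direct-to-consumer genetic-testing users: each variant carries a reported
direction of effect (pathogenic / benign / protective), the certainty of the
evidence behind that call (well-established / likely / uncertain), a
low/medium/high clinical-importance tier, a population allele frequency, the
conditions the variant has been linked to, and a free-text summary.

Two interchangeable serializations are supported: a tab-separated table and a
JSON document.  Both are canonical (fixed column order, lowercase enum tokens,
sorted JSON keys) so that serialization is deterministic and round-trips
byte-exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)

IMPACT_VALUES = ("pathogenic", "benign", "protective")
EVIDENCE_VALUES = ("well-established", "likely", "uncertain")
IMPORTANCE_VALUES = ("low", "medium", "high")
ZYGOSITY_VALUES = ("heterozygous", "homozygous", "unknown")

#: numeric order for clinical importance (low < medium < high)
IMPORTANCE_ORDER = {"low": 0, "medium": 1, "high": 2}

#: per-variant size weight used by area-proportional layouts and risk scoring
IMPORTANCE_WEIGHT = {"low": 1, "medium": 2, "high": 4}

TSV_COLUMNS = (
    "variant_id",
    "gene",
    "label",
    "zygosity",
    "frequency",
    "impact",
    "evidence",
    "importance",
    "conditions",
    "summary",
    "links",
)

_EMPTY = "."


class ReportError(Exception):
    """Base class for report I/O and validation failures."""


class ParseError(ReportError):
    """Structurally malformed input (bad column count, undecodable bytes)."""


@dataclass(frozen=True)
class Violation:
    """One machine-readable validation failure."""

    field: str
    message: str
    line: int | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = f" (line {self.line})" if self.line is not None else ""
        return f"{self.field}: {self.message}{loc}"


class ValidationError(ReportError):
    """Raised with the complete list of violations found, not just the first."""

    def __init__(self, violations: list[Violation]):
        self.violations = list(violations)
        super().__init__("; ".join(str(v) for v in violations))


def normalize_enum(token: str, allowed: tuple[str, ...]) -> str | None:
    """Map ``token`` onto its canonical enum value, or ``None`` if it is not one.

    Matching is case-insensitive and tolerates hyphen/space interchange
    ("Well established" -> "well-established").  Nothing else is coerced:
    an unrecognized token is an error at validation time, never a guess.
    """
    folded = token.strip().lower().replace(" ", "-")
    return folded if folded in allowed else None


@dataclass(frozen=True)
class VariantAnnotation:
    """A single annotated gene variant."""

    variant_id: str
    gene: str
    label: str
    zygosity: str
    allele_frequency: float
    impact: str
    evidence: str
    importance: str
    conditions: tuple[str, ...] = ()
    summary: str = ""
    links: tuple[str, ...] = ()

    def validate(self, line: int | None = None) -> list[Violation]:
        v: list[Violation] = []
        if not self.variant_id:
            v.append(Violation("variant_id", "empty variant_id", line))
        if self.impact not in IMPACT_VALUES:
            v.append(Violation("impact", f"invalid impact token {self.impact!r}", line))
        if self.evidence not in EVIDENCE_VALUES:
            v.append(Violation("evidence", f"invalid evidence token {self.evidence!r}", line))
        if self.importance not in IMPORTANCE_VALUES:
            v.append(Violation("importance", f"invalid importance token {self.importance!r}", line))
        if self.zygosity not in ZYGOSITY_VALUES:
            v.append(Violation("zygosity", f"invalid zygosity token {self.zygosity!r}", line))
        if not (
            isinstance(self.allele_frequency, (int, float))
            and 0.0 <= float(self.allele_frequency) <= 1.0
        ):
            v.append(
                Violation(
                    "frequency",
                    f"allele frequency {self.allele_frequency!r} outside [0, 1]",
                    line,
                )
            )
        return v


@dataclass(frozen=True)
class GlossaryEntry:
    term: str
    definition: str


@dataclass(frozen=True)
class ReportDataset:
    """An ordered, validated collection of variant annotations for one subject."""

    subject: str
    variants: tuple[VariantAnnotation, ...]
    glossary: tuple[GlossaryEntry, ...] = ()

    def __len__(self) -> int:
        return len(self.variants)


def validate_dataset(dataset: ReportDataset) -> None:
    """Raise :class:`ValidationError` listing every violation in ``dataset``."""
    violations: list[Violation] = []
    seen: set[str] = set()
    for i, var in enumerate(dataset.variants, start=1):
        violations.extend(var.validate(line=i))
        if var.variant_id in seen:
            violations.append(
                Violation("variant_id", f"duplicate variant_id {var.variant_id!r}", i)
            )
        seen.add(var.variant_id)
    terms: set[str] = set()
    for entry in dataset.glossary:
        if not entry.term:
            violations.append(Violation("term", "empty glossary term"))
        if entry.term in terms:
            violations.append(Violation("term", f"duplicate glossary term {entry.term!r}"))
        terms.add(entry.term)
    if violations:
        raise ValidationError(violations)


# ---------------------------------------------------------------------------
# effect rank (shared tie-break; the full category machinery lives in encoding)

_IMPACT_BLOCK = {"pathogenic": 0, "benign": 1, "protective": 2}
_EVIDENCE_STEP = {"well-established": 0, "likely": 1, "uncertain": 2}


def effect_rank(variant: VariantAnnotation) -> int:
    """Ordinal 1..9 "potential effect" rank; 1 = well-established pathogenic."""
    return 3 * _IMPACT_BLOCK[variant.impact] + _EVIDENCE_STEP[variant.evidence] + 1


def _tie_key(variant: VariantAnnotation) -> tuple[int, str]:
    return (effect_rank(variant), variant.label)


# ---------------------------------------------------------------------------
# sorting / filtering / searching

SORT_KEYS = ("importance", "impact_evidence", "frequency", "name")


def sort_variants(
    dataset: ReportDataset,
    key: str = "importance",
    descending: bool | None = None,
) -> list[VariantAnnotation]:
    """Return variants in a total, deterministic order.

    The default mirrors the standard report: clinical importance, most
    important first.  Ties always break by effect rank then label, so repeated
    calls give identical output.
    """
    if key not in SORT_KEYS:
        raise ValueError(f"unknown sort key {key!r}; expected one of {SORT_KEYS}")
    if descending is None:
        descending = key == "importance"

    if key == "importance":
        primary = lambda v: IMPORTANCE_ORDER[v.importance]
    elif key == "impact_evidence":
        # rank 1 is the strongest effect; "ascending" puts it first
        primary = lambda v: -effect_rank(v)
    elif key == "frequency":
        primary = lambda v: v.allele_frequency
    else:
        primary = lambda v: v.label

    sign = -1 if descending else 1
    if key == "name":
        # strings cannot be negated; sort ascending then reverse stably
        ordered = sorted(dataset.variants, key=lambda v: (v.label, *_tie_key(v)))
        if descending:
            ordered = sorted(ordered, key=lambda v: v.label, reverse=True)
        return ordered
    return sorted(
        dataset.variants,
        key=lambda v: (sign * primary(v), *_tie_key(v)),
    )


def canonical_order(dataset: ReportDataset) -> ReportDataset:
    """Dataset with variants in the canonical (default-sort) order."""
    return replace(dataset, variants=tuple(sort_variants(dataset)))


_FILTERABLE = {
    "variant_id",
    "gene",
    "label",
    "zygosity",
    "impact",
    "evidence",
    "importance",
}


def filter_variants(dataset: ReportDataset, predicate: dict[str, str]) -> ReportDataset:
    """Subset ``dataset`` to variants matching every field=value clause."""
    for fld in predicate:
        if fld not in _FILTERABLE:
            raise ValueError(f"cannot filter on unknown field {fld!r}")
    kept = tuple(
        v
        for v in dataset.variants
        if all(getattr(v, fld) == val for fld, val in predicate.items())
    )
    return replace(dataset, variants=kept)


def search_variants(dataset: ReportDataset, query: str) -> list[VariantAnnotation]:
    """Case-insensitive substring search over label, gene, conditions, summary."""
    q = query.lower()
    hits = []
    for v in dataset.variants:
        haystacks = (v.label, v.gene, v.summary, *v.conditions)
        if any(q in h.lower() for h in haystacks):
            hits.append(v)
    return hits


# ---------------------------------------------------------------------------
# serialization

def _format_frequency(f: float) -> str:
    return repr(float(f))


def _join(items: tuple[str, ...]) -> str:
    return ";".join(items) if items else _EMPTY


def _split(cell: str) -> tuple[str, ...]:
    if cell == _EMPTY or cell == "":
        return ()
    return tuple(cell.split(";"))


def write_report(dataset: ReportDataset, format: str = "tsv") -> bytes:
    """Serialize ``dataset`` canonically; ``parse_report`` inverts this exactly."""
    validate_dataset(dataset)
    if format == "tsv":
        lines = ["\t".join(TSV_COLUMNS)]
        for v in dataset.variants:
            lines.append(
                "\t".join(
                    (
                        v.variant_id,
                        v.gene or _EMPTY,
                        v.label or _EMPTY,
                        v.zygosity,
                        _format_frequency(v.allele_frequency),
                        v.impact,
                        v.evidence,
                        v.importance,
                        _join(v.conditions),
                        v.summary or _EMPTY,
                        _join(v.links),
                    )
                )
            )
        return ("\n".join(lines) + "\n").encode("utf-8")
    if format == "json":
        doc = {
            "subject": dataset.subject,
            "glossary": [
                {"term": g.term, "definition": g.definition} for g in dataset.glossary
            ],
            "variants": [
                {
                    "variant_id": v.variant_id,
                    "gene": v.gene,
                    "label": v.label,
                    "zygosity": v.zygosity,
                    "frequency": v.allele_frequency,
                    "impact": v.impact,
                    "evidence": v.evidence,
                    "importance": v.importance,
                    "conditions": list(v.conditions),
                    "summary": v.summary,
                    "links": list(v.links),
                }
                for v in dataset.variants
            ],
        }
        return (json.dumps(doc, sort_keys=True, indent=1) + "\n").encode("utf-8")
    raise ValueError(f"unknown format {format!r}")


def _parse_row(
    cells: list[str], line: int, violations: list[Violation]
) -> VariantAnnotation:
    def enum(col: str, token: str, allowed: tuple[str, ...]) -> str:
        norm = normalize_enum(token, allowed)
        if norm is None:
            violations.append(
                Violation(col, f"invalid {col} token {token!r}", line)
            )
            return token
        return norm

    freq_text = cells[4]
    try:
        freq = float(freq_text)
        if not 0.0 <= freq <= 1.0:
            violations.append(
                Violation("frequency", f"allele frequency {freq!r} outside [0, 1]", line)
            )
    except ValueError:
        violations.append(Violation("frequency", f"not a number: {freq_text!r}", line))
        freq = float("nan")
    var = VariantAnnotation(
        variant_id=cells[0],
        gene="" if cells[1] == _EMPTY else cells[1],
        label="" if cells[2] == _EMPTY else cells[2],
        zygosity=enum("zygosity", cells[3], ZYGOSITY_VALUES),
        allele_frequency=freq,
        impact=enum("impact", cells[5], IMPACT_VALUES),
        evidence=enum("evidence", cells[6], EVIDENCE_VALUES),
        importance=enum("importance", cells[7], IMPORTANCE_VALUES),
        conditions=_split(cells[8]),
        summary="" if cells[9] == _EMPTY else cells[9],
        links=_split(cells[10]),
    )
    return var


def parse_report(
    source: bytes | str,
    format: str = "tsv",
    subject: str = "",
    glossary: tuple[GlossaryEntry, ...] = (),
) -> ReportDataset:
    """Parse and validate a serialized report.

    Structural problems (undecodable bytes, wrong column count) raise
    :class:`ParseError` naming the offending line; semantic problems are
    accumulated and raised together as :class:`ValidationError`.
    """
    if isinstance(source, bytes):
        try:
            text = source.decode("utf-8")
        except UnicodeDecodeError as exc:
            raise ParseError(f"input is not valid UTF-8: {exc}") from exc
    else:
        text = source

    if format == "tsv":
        lines = text.split("\n")
        if lines and lines[-1] == "":
            lines.pop()
        if not lines:
            raise ParseError("empty input: missing header row")
        header = lines[0].split("\t")
        col_index: dict[str, int] = {}
        for i, name in enumerate(header):
            if name in TSV_COLUMNS:
                col_index[name] = i
            else:
                logger.warning("ignoring unknown column %r", name)
        missing = [c for c in TSV_COLUMNS if c not in col_index]
        if missing:
            raise ParseError(f"header missing required columns: {missing}")
        violations: list[Violation] = []
        variants: list[VariantAnnotation] = []
        for lineno, raw in enumerate(lines[1:], start=2):
            cells = raw.split("\t")
            if len(cells) != len(header):
                raise ParseError(
                    f"line {lineno}: expected {len(header)} columns, got {len(cells)}"
                )
            ordered = [cells[col_index[c]] for c in TSV_COLUMNS]
            variants.append(_parse_row(ordered, lineno, violations))
        if violations:
            raise ValidationError(violations)
        ds = ReportDataset(subject=subject, variants=tuple(variants), glossary=glossary)
        validate_dataset(ds)
        return canonical_order(ds)

    if format == "json":
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ParseError(f"invalid JSON: {exc}") from exc
        violations = []
        variants = []
        for i, rec in enumerate(doc.get("variants", []), start=1):
            known = {
                "variant_id",
                "gene",
                "label",
                "zygosity",
                "frequency",
                "impact",
                "evidence",
                "importance",
                "conditions",
                "summary",
                "links",
            }
            for k in rec:
                if k not in known:
                    logger.warning("ignoring unknown key %r", k)
            cells = [
                str(rec.get("variant_id", "")),
                str(rec.get("gene", "")) or _EMPTY,
                str(rec.get("label", "")) or _EMPTY,
                str(rec.get("zygosity", "")),
                str(rec.get("frequency", "nan")),
                str(rec.get("impact", "")),
                str(rec.get("evidence", "")),
                str(rec.get("importance", "")),
                ";".join(rec.get("conditions", [])) or _EMPTY,
                str(rec.get("summary", "")) or _EMPTY,
                ";".join(rec.get("links", [])) or _EMPTY,
            ]
            variants.append(_parse_row(cells, i, violations))
        if violations:
            raise ValidationError(violations)
        gloss = tuple(
            GlossaryEntry(term=g["term"], definition=g["definition"])
            for g in doc.get("glossary", [])
        )
        ds = ReportDataset(
            subject=doc.get("subject", subject),
            variants=tuple(variants),
            glossary=gloss or glossary,
        )
        validate_dataset(ds)
        return canonical_order(ds)

    raise ValueError(f"unknown format {format!r}")


def parse_glossary(source: bytes | str) -> tuple[GlossaryEntry, ...]:
    """Parse a two-column ``term<TAB>definition`` glossary file."""
    text = source.decode("utf-8") if isinstance(source, bytes) else source
    entries = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip():
            continue
        cells = raw.split("\t")
        if len(cells) != 2:
            raise ParseError(f"glossary line {lineno}: expected 2 columns, got {len(cells)}")
        entries.append(GlossaryEntry(term=cells[0], definition=cells[1]))
    return tuple(entries)
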
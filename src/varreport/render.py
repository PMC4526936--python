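"""Self-contained interactive documents from precomputed geometry.

Each design renders to a single HTML file with inline SVG: one embedded view
per enumerated zoom state, a 9-entry color legend, per-variant detail blocks,
and a clickable glossary.  All interactivity (zoom navigation, tooltip
display, table sorting) only toggles content that is precomputed here — the
documents fetch nothing and the generated bytes are identical across runs.

Variant details are shown in a fixed side panel rather than floating
tooltips, so detail text never occludes the plot area.
"""

from __future__ import annotations

import xml.sax.saxutils as sax
from dataclasses import dataclass

from .encoding import category_label, effect_category, encode_color, legend
from .layouts import (
    Circle,
    LayoutGeometry,
    Rect,
    ZoomState,
    enumerate_zoom_states,
    layout,
)
from .model import GlossaryEntry, ReportDataset, VariantAnnotation, sort_variants

VIEWBOX_W = 1200
VIEWBOX_H = 800

FRAME_FILL = "#e8e8e8"
FRAME_STROKE = "#999999"
SHAPE_STROKE = "#333333"


@dataclass(frozen=True)
class TooltipBlock:
    """The detail block shown for one variant in the side panel."""

    title: str
    body: tuple[tuple[str, str], ...]  # ordered (field name, text) pairs
    links: tuple[str, ...]
    glossary_terms: tuple[str, ...]  # glossary terms occurring in the body


def _esc(text: str) -> str:
    return sax.escape(text, {'"': "&quot;"})


def tooltip_content(
    variant: VariantAnnotation, glossary: tuple[GlossaryEntry, ...]
) -> TooltipBlock:
    """Deterministic detail block; glossary terms in the body are marked."""
    cat = effect_category(variant)
    body: list[tuple[str, str]] = [
        ("effect", category_label(cat)),
        ("importance", f"{variant.importance} clinical importance"),
        ("frequency", f"allele frequency {variant.allele_frequency:g}"),
    ]
    if variant.conditions:
        body.append(("conditions", ", ".join(variant.conditions)))
    if variant.summary:
        body.append(("summary", variant.summary))
    text = " ".join(t for _, t in body).lower()
    terms = tuple(g.term for g in glossary if g.term.lower() in text)
    return TooltipBlock(
        title=variant.label,
        body=tuple(body),
        links=variant.links,
        glossary_terms=terms,
    )


# ---------------------------------------------------------------------------
# SVG

def _fmt(x: float) -> str:
    return f"{x:.4f}".rstrip("0").rstrip(".")


def render_svg(geometry: LayoutGeometry, title: str = "") -> str:
    """One well-formed SVG document: group frames beneath variant shapes."""
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" viewBox="0 0 {VIEWBOX_W} {VIEWBOX_H}" '
        f'role="img" aria-label="{_esc(title)}">'
    ]
    for label, r in geometry.group_frames:
        parts.append(
            f'<rect class="frame" data-group="{_esc(label)}" '
            f'x="{_fmt(r.x * VIEWBOX_W)}" y="{_fmt(r.y * VIEWBOX_H)}" '
            f'width="{_fmt(r.width * VIEWBOX_W)}" height="{_fmt(r.height * VIEWBOX_H)}" '
            f'fill="{FRAME_FILL}" stroke="{FRAME_STROKE}"/>'
        )
    for s in geometry.shapes:
        common = (
            f'class="variant" data-variant="{_esc(s.variant_id or "")}" '
            f'fill="{s.fill}" stroke="{SHAPE_STROKE}"'
        )
        if isinstance(s.geometry, Circle):
            c = s.geometry
            parts.append(
                f'<circle {common} cx="{_fmt(c.cx * VIEWBOX_W)}" '
                f'cy="{_fmt(c.cy * VIEWBOX_H)}" r="{_fmt(c.r * min(VIEWBOX_W, VIEWBOX_H))}"/>'
            )
        else:
            r = s.geometry
            parts.append(
                f'<rect {common} x="{_fmt(r.x * VIEWBOX_W)}" y="{_fmt(r.y * VIEWBOX_H)}" '
                f'width="{_fmt(r.width * VIEWBOX_W)}" height="{_fmt(r.height * VIEWBOX_H)}"/>'
            )
    parts.append("</svg>")
    return "\n".join(parts)


# ---------------------------------------------------------------------------
# HTML

_SORT_JS = """
function sortTable(col, numeric) {
  var table = document.getElementById('report-table');
  var rows = Array.prototype.slice.call(table.tBodies[0].rows);
  var dir = table.getAttribute('data-dir') === 'asc' ? -1 : 1;
  table.setAttribute('data-dir', dir === 1 ? 'asc' : 'desc');
  rows.sort(function (a, b) {
    var x = a.cells[col].getAttribute('data-key');
    var y = b.cells[col].getAttribute('data-key');
    if (numeric) { x = parseFloat(x); y = parseFloat(y); }
    return (x < y ? -1 : x > y ? 1 : 0) * dir;
  });
  rows.forEach(function (r) { table.tBodies[0].appendChild(r); });
}
"""

_VIEW_JS = """
function showView(id) {
  var views = document.querySelectorAll('.zoom-view');
  views.forEach(function (v) { v.style.display = 'none'; });
  document.getElementById(id).style.display = 'block';
}
function showDetail(id) {
  var blocks = document.querySelectorAll('.detail-block');
  blocks.forEach(function (b) { b.style.display = 'none'; });
  var el = document.getElementById(id);
  if (el) { el.style.display = 'block'; }
}
"""

_CSS = """
body { font-family: sans-serif; margin: 1em; }
.layout { display: flex; gap: 1em; }
.plot { flex: 3; }
.side-panel { flex: 1; border-left: 1px solid #ccc; padding-left: 1em; }
.detail-block { display: none; }
.legend-swatch { display: inline-block; width: 1em; height: 1em;
                 border: 1px solid #333; margin-right: 0.4em; }
.glossary dt { font-weight: bold; }
table.report { border-collapse: collapse; }
table.report td, table.report th { border: 1px solid #999; padding: 0.3em; }
.zoom-view { display: none; }
.zoom-view.overview { display: block; }
"""


def _state_id(state: ZoomState) -> str:
    if not state.path:
        return "view-overview"
    return "view-" + "-".join(p.replace("|", "_").replace(" ", "_") for p in state.path)


def _glossary_html(glossary: tuple[GlossaryEntry, ...]) -> str:
    items = []
    for g in glossary:
        items.append(
            f'<dt id="gloss-{_esc(g.term.replace(" ", "_"))}">{_esc(g.term)}</dt>'
            f"<dd>{_esc(g.definition)}</dd>"
        )
    return '<dl class="glossary">' + "".join(items) + "</dl>"


def _mark_glossary(text: str, block: TooltipBlock) -> str:
    """Wrap glossary-term occurrences in links into the glossary section."""
    out = _esc(text)
    for term in block.glossary_terms:
        target = _esc(term.replace(" ", "_"))
        out = out.replace(
            _esc(term), f'<a class="gloss-link" href="#gloss-{target}">{_esc(term)}</a>', 1
        )
    return out


def _detail_html(variant: VariantAnnotation, block: TooltipBlock) -> str:
    rows = []
    for name, text in block.body:
        rows.append(f'<p class="detail-{name}">{_mark_glossary(text, block)}</p>')
    links = "".join(
        f'<li><a href="{_esc(u)}">{_esc(u)}</a></li>' for u in block.links
    )
    return (
        f'<div class="detail-block" id="detail-{_esc(variant.variant_id)}">'
        f"<h3>{_esc(block.title)}</h3>" + "".join(rows) + f"<ul>{links}</ul></div>"
    )


def _legend_html(scheme: str) -> str:
    rows = []
    for cat, color, label in legend(scheme):
        rows.append(
            f'<li><span class="legend-swatch" style="background:{color.hex}"></span>'
            f"{_esc(label)}</li>"
        )
    return '<ol class="legend">' + "".join(rows) + "</ol>"


def _table_html(dataset: ReportDataset) -> str:
    from .layouts import TABLE_COLUMNS

    head = []
    for i, (fld, title, sortable) in enumerate(TABLE_COLUMNS):
        numeric = "true" if fld == "frequency" else "false"
        if sortable:
            head.append(
                f'<th><button onclick="sortTable({i}, {numeric})">'
                f"{_esc(title)} &#x2195;</button></th>"
            )
        else:
            head.append(f"<th>{_esc(title)}</th>")
    rows = []
    from .model import IMPORTANCE_ORDER
    from .model import effect_rank as _rank

    for v in sort_variants(dataset):
        fill = encode_color(effect_category(v)).hex
        cells = [
            f'<td data-key="{_esc(v.label)}">{_esc(v.label)}</td>',
            f'<td data-key="{_esc(v.gene)}">{_esc(v.gene)}</td>',
            f'<td data-key="{IMPORTANCE_ORDER[v.importance]}">{_esc(v.importance)}</td>',
            f'<td data-key="{10 - _rank(v)}" style="background:{fill}">{_esc(v.impact)}</td>',
            f'<td data-key="{_esc(v.evidence)}">{_esc(v.evidence)}</td>',
            f'<td data-key="{v.allele_frequency!r}">{v.allele_frequency:g}</td>',
            f'<td data-key="{_esc(";".join(v.conditions))}">{_esc(", ".join(v.conditions))}</td>',
        ]
        rows.append(
            f'<tr onclick="showDetail(\'detail-{_esc(v.variant_id)}\')">'
            + "".join(cells)
            + "</tr>"
        )
    return (
        '<table class="report" id="report-table" data-dir="asc">'
        "<thead><tr>" + "".join(head) + "</tr></thead>"
        "<tbody>" + "".join(rows) + "</tbody></table>"
    )


def render_html(
    dataset: ReportDataset, design: str, scheme: str = "study3"
) -> str:
    """One self-contained document for a design: every zoom view precomputed."""
    states = enumerate_zoom_states(dataset, design)
    views = []
    for state in states:
        geo = layout(dataset, design, state, scheme)
        cls = "zoom-view overview" if not state.path else "zoom-view"
        nav = ""
        if state.path:
            crumb = " &rsaquo; ".join(_esc(p) for p in state.path)
            nav = (
                f'<p class="crumb">{crumb} '
                f"<button onclick=\"showView('view-overview')\">overview</button></p>"
            )
        views.append(
            f'<div class="{cls}" id="{_state_id(state)}">{nav}'
            + render_svg(geo, title=f"{design} view {'/'.join(state.path) or 'overview'}")
            + "</div>"
        )
    details = []
    for v in sort_variants(dataset):
        details.append(_detail_html(v, tooltip_content(v, dataset.glossary)))
    table = _table_html(dataset) if design == "table" else ""
    subject = dataset.subject or "Subject"
    return (
        "<!DOCTYPE html>\n"
        '<html lang="en"><head><meta charset="utf-8"/>'
        f"<title>{_esc(subject)} &#8212; {_esc(design)} report</title>"
        f"<style>{_CSS}</style>"
        "<script>//<![CDATA[\n"
        f"{_VIEW_JS}{_SORT_JS if design == 'table' else ''}"
        "\n//]]></script>"
        "</head><body>"
        f"<h1>{_esc(subject)}'s genome report ({_esc(design)})</h1>"
        '<div class="layout"><div class="plot">'
        + table
        + "".join(views)
        + '</div><div class="side-panel"><h2>Details</h2>'
        + "".join(details)
        + "<h2>Color key</h2>"
        + _legend_html(scheme)
        + "<h2>Glossary</h2>"
        + _glossary_html(dataset.glossary)
        + "</div></div></body></html>\n"
    )
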
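"""Deterministic geometry for the seven report designs.

All layouts place shapes on the unit square (origin top-left, y downward);
renderers scale to pixels.  Given the same dataset, design, and zoom state the
geometry is byte-identical across runs — there is no randomness and no
platform-dependent iteration order anywhere in this module.

Designs
-------
``table``          sortable rows, one per variant (the control condition)
``bar``            three importance panels; bar height encodes effect rank
``bubble``         three importance panels; circles at effect-rank bands
``treemap``        three importance boxes; selecting one reveals its variants
``heatmap``        equal cells, row-major, inside three gray importance boxes
``zoom_treemap``   3-level squarified hierarchy importance -> effect -> variant
``zoom_partition`` icicle bands, widths proportional to variant counts

The two ``zoom_*`` designs (and the one-level ``treemap``) are navigable; a
:class:`ZoomState` holds the selection path and every reachable view can be
enumerated so that rendered documents need no server.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .model import (
    IMPORTANCE_WEIGHT,
    ReportDataset,
    VariantAnnotation,
    effect_rank,
    sort_variants,
)
from .encoding import ALL_CATEGORIES, category_label, effect_category, encode_color

DESIGNS = (
    "table",
    "bar",
    "bubble",
    "treemap",
    "heatmap",
    "zoom_treemap",
    "zoom_partition",
)

#: importance tiers in display order (left to right / top to bottom)
IMPORTANCE_PANELS = ("high", "medium", "low")

# named layout constants (fractions of the unit canvas)
PANEL_GAP = 0.02
PANEL_PAD = 0.01
CELL_GAP_FRACTION = 0.1   # of a heatmap cell
BAR_GAP_FRACTION = 0.2    # of a bar slot
BUBBLE_RADIUS_FACTOR = 0.8
TABLE_HEADER_HEIGHT = 0.06

TABLE_COLUMNS = (
    ("label", "Variant", True),
    ("gene", "Gene", True),
    ("importance", "Clinical importance", True),
    ("impact", "Potential impact", True),
    ("evidence", "Evidence", True),
    ("frequency", "Allele frequency", True),
    ("conditions", "Conditions", False),
)


class LayoutError(Exception):
    pass


@dataclass(frozen=True)
class Rect:
    x: float
    y: float
    width: float
    height: float

    def area(self) -> float:
        return self.width * self.height


@dataclass(frozen=True)
class Circle:
    cx: float
    cy: float
    r: float


@dataclass(frozen=True)
class PlacedShape:
    kind: str  # rect | circle | bar
    geometry: Rect | Circle
    variant_id: str | None
    group_key: str | None
    fill: str


@dataclass(frozen=True)
class ZoomState:
    """Selection path into a navigable design; empty path = overview."""

    path: tuple[str, ...] = ()

    @property
    def depth(self) -> int:
        return len(self.path)


OVERVIEW = ZoomState()


@dataclass(frozen=True)
class LayoutGeometry:
    design: str
    zoom: ZoomState
    shapes: tuple[PlacedShape, ...]
    group_frames: tuple[tuple[str, Rect], ...]
    table_columns: tuple[tuple[str, str, bool], ...] | None = None


# ---------------------------------------------------------------------------
# squarified treemap core

def _worst_aspect(row: list[float], length: float, total: float, area: float) -> float:
    """Worst aspect ratio if ``row`` weights share a strip along ``length``."""
    scale = area / total
    areas = [w * scale for w in row]
    s = sum(areas)
    thickness = s / length
    worst = 0.0
    for a in areas:
        side = a / thickness
        worst = max(worst, side / thickness, thickness / side)
    return worst


def squarify(weights: list[float], container: Rect) -> list[Rect]:
    """Tile ``container`` with one rectangle per weight, areas proportional.

    Classic greedy squarified layout: weights are placed row by row along the
    container's shorter side, a row being closed as soon as adding the next
    weight would worsen the row's worst aspect ratio.  Input order is
    preserved in the output.
    """
    if any(w <= 0 for w in weights):
        raise LayoutError("squarify requires strictly positive weights")
    if container.width <= 0 or container.height <= 0:
        raise LayoutError("degenerate container")
    if not weights:
        return []

    total = sum(weights)
    area = container.area()
    rects: list[Rect | None] = [None] * len(weights)
    order = list(range(len(weights)))

    x, y, w, h = container.x, container.y, container.width, container.height
    i = 0
    while i < len(order):
        length = min(w, h)
        row = [order[i]]
        i += 1
        current = _worst_aspect([weights[j] for j in row], length, total, area)
        while i < len(order):
            candidate = row + [order[i]]
            cand_worst = _worst_aspect(
                [weights[j] for j in candidate], length, total, area
            )
            if cand_worst <= current:
                row = candidate
                current = cand_worst
                i += 1
            else:
                break
        # lay the row along the shorter side
        scale = area / total
        row_area = sum(weights[j] for j in row) * scale
        if w >= h:
            # vertical strip at the left edge
            strip_w = row_area / h
            cy = y
            for j in row:
                rh = (weights[j] * scale) / strip_w
                rects[j] = Rect(x, cy, strip_w, rh)
                cy += rh
            x += strip_w
            w -= strip_w
        else:
            strip_h = row_area / w
            cx = x
            for j in row:
                rw = (weights[j] * scale) / strip_h
                rects[j] = Rect(cx, y, rw, strip_h)
                cx += rw
            y += strip_h
            h -= strip_h
    return rects  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# hierarchy helpers

def _panel_variants(dataset: ReportDataset) -> dict[str, list[VariantAnnotation]]:
    """Variants per importance tier, each in canonical tie-break order."""
    ordered = sort_variants(dataset)  # importance desc, then rank, then label
    panels: dict[str, list[VariantAnnotation]] = {t: [] for t in IMPORTANCE_PANELS}
    for v in ordered:
        panels[v.importance].append(v)
    return panels


def effect_key(variant: VariantAnnotation) -> str:
    """Level-2 node key: ``impact|evidence``."""
    return f"{variant.impact}|{variant.evidence}"


_CATEGORY_KEYS = tuple(f"{c.impact}|{c.evidence}" for c in ALL_CATEGORIES)


def _hierarchy(dataset: ReportDataset) -> dict[str, dict[str, list[VariantAnnotation]]]:
    """importance -> effect key -> variants, all in deterministic order."""
    panels = _panel_variants(dataset)
    tree: dict[str, dict[str, list[VariantAnnotation]]] = {}
    for tier in IMPORTANCE_PANELS:
        cells: dict[str, list[VariantAnnotation]] = {}
        for key in _CATEGORY_KEYS:
            members = [v for v in panels[tier] if effect_key(v) == key]
            if members:
                cells[key] = members
        tree[tier] = cells
    return tree


def _fill(variant: VariantAnnotation, scheme: str) -> str:
    return encode_color(effect_category(variant), scheme).hex


def _panel_frames() -> list[tuple[str, Rect]]:
    """Three side-by-side importance panels spanning the unit canvas."""
    width = (1.0 - 2 * PANEL_GAP) / 3
    frames = []
    for i, tier in enumerate(IMPORTANCE_PANELS):
        frames.append((tier, Rect(i * (width + PANEL_GAP), 0.0, width, 1.0)))
    return frames


def _inner(rect: Rect, pad: float = PANEL_PAD) -> Rect:
    pad = min(pad, rect.width / 4, rect.height / 4)
    return Rect(rect.x + pad, rect.y + pad, rect.width - 2 * pad, rect.height - 2 * pad)


# ---------------------------------------------------------------------------
# zoom-state machinery

def _zoom_levels(design: str) -> int:
    if design in ("zoom_treemap", "zoom_partition"):
        return 2
    if design == "treemap":
        return 1
    return 0


def validate_zoom(dataset: ReportDataset, design: str, zoom: ZoomState) -> None:
    if design not in DESIGNS:
        raise LayoutError(f"unknown design {design!r}")
    max_depth = _zoom_levels(design)
    if zoom.depth > max_depth:
        raise LayoutError(f"design {design!r} does not support zoom path {zoom.path}")
    tree = _hierarchy(dataset)
    if zoom.depth >= 1:
        tier = zoom.path[0]
        if tier not in tree or not tree[tier]:
            raise LayoutError(f"invalid zoom node {tier!r}")
    if zoom.depth == 2:
        tier, key = zoom.path
        if key not in tree[tier]:
            raise LayoutError(f"invalid zoom node {key!r} under {tier!r}")


def enumerate_zoom_states(dataset: ReportDataset, design: str) -> list[ZoomState]:
    """Every reachable view: overview, then each non-empty node depth-first."""
    if design not in DESIGNS:
        raise LayoutError(f"unknown design {design!r}")
    states = [OVERVIEW]
    levels = _zoom_levels(design)
    if levels == 0:
        return states
    tree = _hierarchy(dataset)
    for tier in IMPORTANCE_PANELS:
        if not tree[tier]:
            continue
        states.append(ZoomState((tier,)))
        if levels >= 2:
            for key in _CATEGORY_KEYS:
                if key in tree[tier]:
                    states.append(ZoomState((tier, key)))
    return states


def zoom_navigate(
    dataset: ReportDataset, design: str, state: ZoomState, action: str, node: str | None = None
) -> ZoomState:
    """Apply ``select``/``back``/``reset`` to a zoom state, validating the result."""
    if action == "reset":
        return OVERVIEW
    if action == "back":
        if state.depth == 0:
            return OVERVIEW
        return ZoomState(state.path[:-1])
    if action == "select":
        if node is None:
            raise LayoutError("select requires a node key")
        candidate = ZoomState(state.path + (node,))
        validate_zoom(dataset, design, candidate)
        return candidate
    raise LayoutError(f"unknown action {action!r}")


# ---------------------------------------------------------------------------
# per-design layouts

def _layout_table(dataset: ReportDataset, scheme: str) -> LayoutGeometry:
    rows = sort_variants(dataset)
    n = len(rows)
    shapes = []
    row_h = (1.0 - TABLE_HEADER_HEIGHT) / n if n else 0.0
    for i, v in enumerate(rows):
        shapes.append(
            PlacedShape(
                kind="rect",
                geometry=Rect(0.0, TABLE_HEADER_HEIGHT + i * row_h, 1.0, row_h),
                variant_id=v.variant_id,
                group_key=None,
                fill=_fill(v, scheme),
            )
        )
    frames = (("header", Rect(0.0, 0.0, 1.0, TABLE_HEADER_HEIGHT)),)
    return LayoutGeometry(
        design="table",
        zoom=OVERVIEW,
        shapes=tuple(shapes),
        group_frames=frames,
        table_columns=TABLE_COLUMNS,
    )


def _layout_bar(dataset: ReportDataset, scheme: str) -> LayoutGeometry:
    panels = _panel_variants(dataset)
    shapes = []
    frames = _panel_frames()
    for tier, frame in frames:
        members = panels[tier]
        if not members:
            continue
        inner = _inner(frame)
        slot = inner.width / len(members)
        gap = slot * BAR_GAP_FRACTION
        for i, v in enumerate(members):
            height = inner.height * (10 - effect_rank(v)) / 9.0
            shapes.append(
                PlacedShape(
                    kind="bar",
                    geometry=Rect(
                        inner.x + i * slot + gap / 2,
                        inner.y + inner.height - height,
                        slot - gap,
                        height,
                    ),
                    variant_id=v.variant_id,
                    group_key=tier,
                    fill=_fill(v, scheme),
                )
            )
    return LayoutGeometry("bar", OVERVIEW, tuple(shapes), tuple(frames))


def _layout_bubble(dataset: ReportDataset, scheme: str) -> LayoutGeometry:
    panels = _panel_variants(dataset)
    shapes = []
    frames = _panel_frames()
    band_h = 1.0 / 9.0
    for tier, frame in frames:
        members = panels[tier]
        if not members:
            continue
        inner = _inner(frame)
        by_rank: dict[int, list[VariantAnnotation]] = {}
        for v in members:
            by_rank.setdefault(effect_rank(v), []).append(v)
        for rank in sorted(by_rank):
            row = by_rank[rank]
            slot = inner.width / len(row)
            cy = inner.y + (rank - 0.5) * band_h * inner.height
            r = BUBBLE_RADIUS_FACTOR * 0.5 * min(slot, band_h * inner.height)
            for i, v in enumerate(row):
                shapes.append(
                    PlacedShape(
                        kind="circle",
                        geometry=Circle(inner.x + (i + 0.5) * slot, cy, r),
                        variant_id=v.variant_id,
                        group_key=tier,
                        fill=_fill(v, scheme),
                    )
                )
    return LayoutGeometry("bubble", OVERVIEW, tuple(shapes), tuple(frames))


def _layout_heatmap(dataset: ReportDataset, scheme: str) -> LayoutGeometry:
    import math

    panels = _panel_variants(dataset)
    shapes = []
    frames = _panel_frames()
    for tier, frame in frames:
        members = panels[tier]
        if not members:
            continue
        inner = _inner(frame)
        cols = math.ceil(math.sqrt(len(members)))
        rows = math.ceil(len(members) / cols)
        cell_w = inner.width / cols
        cell_h = inner.height / rows
        gap_w = cell_w * CELL_GAP_FRACTION
        gap_h = cell_h * CELL_GAP_FRACTION
        for i, v in enumerate(members):
            r, c = divmod(i, cols)
            shapes.append(
                PlacedShape(
                    kind="rect",
                    geometry=Rect(
                        inner.x + c * cell_w + gap_w / 2,
                        inner.y + r * cell_h + gap_h / 2,
                        cell_w - gap_w,
                        cell_h - gap_h,
                    ),
                    variant_id=v.variant_id,
                    group_key=tier,
                    fill=_fill(v, scheme),
                )
            )
    return LayoutGeometry("heatmap", OVERVIEW, tuple(shapes), tuple(frames))


def _layout_treemap(dataset: ReportDataset, scheme: str, zoom: ZoomState) -> LayoutGeometry:
    tree = _hierarchy(dataset)
    if zoom.depth == 0:
        frames = _panel_frames()
        return LayoutGeometry("treemap", zoom, (), tuple(frames))
    tier = zoom.path[0]
    members = [v for cell in tree[tier].values() for v in cell]
    members = sorted(members, key=lambda v: (effect_rank(v), v.label))
    weights = [float(IMPORTANCE_WEIGHT[v.importance]) for v in members]
    rects = squarify(weights, Rect(0.0, 0.0, 1.0, 1.0))
    shapes = tuple(
        PlacedShape("rect", r, v.variant_id, tier, _fill(v, scheme))
        for v, r in zip(members, rects)
    )
    return LayoutGeometry("treemap", zoom, shapes, ((tier, Rect(0.0, 0.0, 1.0, 1.0)),))


def _layout_zoom_treemap(
    dataset: ReportDataset, scheme: str, zoom: ZoomState
) -> LayoutGeometry:
    tree = _hierarchy(dataset)

    def cell_weight(members: list[VariantAnnotation]) -> float:
        return float(sum(IMPORTANCE_WEIGHT[v.importance] for v in members))

    def place_variants(members, container, tier):
        # leaves carry equal weight within a cell
        rects = squarify([1.0] * len(members), container)
        return [
            PlacedShape("rect", r, v.variant_id, tier, _fill(v, scheme))
            for v, r in zip(members, rects)
        ]

    def place_cells(cells, container, tier):
        keys = list(cells)
        rects = squarify([cell_weight(cells[k]) for k in keys], container)
        frames, shapes = [], []
        for k, r in zip(keys, rects):
            frames.append((f"{tier}/{k}", r))
            shapes.extend(place_variants(cells[k], _inner(r), tier))
        return frames, shapes

    unit = Rect(0.0, 0.0, 1.0, 1.0)
    if zoom.depth == 2:
        tier, key = zoom.path
        members = tree[tier][key]
        shapes = place_variants(members, unit, tier)
        return LayoutGeometry(
            "zoom_treemap", zoom, tuple(shapes), ((f"{tier}/{key}", unit),)
        )
    if zoom.depth == 1:
        tier = zoom.path[0]
        frames, shapes = place_cells(tree[tier], unit, tier)
        return LayoutGeometry("zoom_treemap", zoom, tuple(shapes), tuple(frames))
    # overview: squarify the three tiers, then nest fully
    tiers = [t for t in IMPORTANCE_PANELS if tree[t]]
    if not tiers:
        return LayoutGeometry(
            "zoom_treemap", zoom, (), tuple((t, r) for t, r in _panel_frames())
        )
    weights = [
        cell_weight([v for cell in tree[t].values() for v in cell]) for t in tiers
    ]
    tier_rects = squarify(weights, unit)
    frames: list[tuple[str, Rect]] = []
    shapes: list[PlacedShape] = []
    for t, r in zip(tiers, tier_rects):
        frames.append((t, r))
        sub_frames, sub_shapes = place_cells(tree[t], _inner(r), t)
        frames.extend(sub_frames)
        shapes.extend(sub_shapes)
    return LayoutGeometry("zoom_treemap", zoom, tuple(shapes), tuple(frames))


def _layout_zoom_partition(
    dataset: ReportDataset, scheme: str, zoom: ZoomState
) -> LayoutGeometry:
    """Icicle: stacked horizontal levels, band widths proportional to counts."""
    tree = _hierarchy(dataset)

    def bands(groups: list[tuple[str, int]], container: Rect) -> list[tuple[str, Rect]]:
        total = sum(n for _, n in groups)
        out = []
        edges = [container.x]
        for _, n in groups:
            edges.append(edges[-1] + container.width * n / total)
        edges[-1] = container.x + container.width  # exact closure
        for (key, _), x0, x1 in zip(groups, edges, edges[1:]):
            out.append((key, Rect(x0, container.y, x1 - x0, container.height)))
        return out

    unit = Rect(0.0, 0.0, 1.0, 1.0)
    if zoom.depth == 0:
        tiers = [t for t in IMPORTANCE_PANELS if tree[t]]
        if not tiers:
            return LayoutGeometry(
                "zoom_partition", zoom, (), tuple(_panel_frames())
            )
        level_h = 1.0 / 3.0
        counts = [
            (t, sum(len(c) for c in tree[t].values())) for t in tiers
        ]
        frames = list(bands(counts, Rect(0.0, 0.0, 1.0, level_h)))
        shapes: list[PlacedShape] = []
        l2_frames: list[tuple[str, Rect]] = []
        for t, frame in frames:
            cell_counts = [(f"{t}/{k}", len(tree[t][k])) for k in tree[t]]
            l2 = bands(cell_counts, Rect(frame.x, level_h, frame.width, level_h))
            l2_frames.extend(l2)
            for (fk, l2rect), k in zip(l2, tree[t]):
                members = tree[t][k]
                leaf = bands(
                    [(v.variant_id, 1) for v in members],
                    Rect(l2rect.x, 2 * level_h, l2rect.width, level_h),
                )
                for v, (_, r) in zip(members, leaf):
                    shapes.append(PlacedShape("rect", r, v.variant_id, t, _fill(v, scheme)))
        return LayoutGeometry(
            "zoom_partition", zoom, tuple(shapes), tuple(frames + l2_frames)
        )
    if zoom.depth == 1:
        tier = zoom.path[0]
        level_h = 1.0 / 2.0
        cell_counts = [(f"{tier}/{k}", len(tree[tier][k])) for k in tree[tier]]
        l2 = bands(cell_counts, Rect(0.0, 0.0, 1.0, level_h))
        shapes = []
        for (fk, l2rect), k in zip(l2, tree[tier]):
            members = tree[tier][k]
            leaf = bands(
                [(v.variant_id, 1) for v in members],
                Rect(l2rect.x, level_h, l2rect.width, level_h),
            )
            for v, (_, r) in zip(members, leaf):
                shapes.append(PlacedShape("rect", r, v.variant_id, tier, _fill(v, scheme)))
        return LayoutGeometry("zoom_partition", zoom, tuple(shapes), tuple(l2))
    tier, key = zoom.path
    members = tree[tier][key]
    leaf = bands([(v.variant_id, 1) for v in members], unit)
    shapes = tuple(
        PlacedShape("rect", r, v.variant_id, tier, _fill(v, scheme))
        for v, (_, r) in zip(members, leaf)
    )
    return LayoutGeometry(
        "zoom_partition", zoom, shapes, ((f"{tier}/{key}", unit),)
    )


def layout(
    dataset: ReportDataset,
    design: str,
    zoom: ZoomState = OVERVIEW,
    scheme: str = "study3",
) -> LayoutGeometry:
    """Compute placed, colored geometry for one design and zoom state."""
    validate_zoom(dataset, design, zoom)
    if design == "table":
        return _layout_table(dataset, scheme)
    if design == "bar":
        return _layout_bar(dataset, scheme)
    if design == "bubble":
        return _layout_bubble(dataset, scheme)
    if design == "heatmap":
        return _layout_heatmap(dataset, scheme)
    if design == "treemap":
        return _layout_treemap(dataset, scheme, zoom)
    if design == "zoom_treemap":
        return _layout_zoom_treemap(dataset, scheme, zoom)
    return _layout_zoom_partition(dataset, scheme, zoom)


def geometry_json(geometry: LayoutGeometry) -> str:
    """Serialize geometry deterministically for golden-file comparison."""

    def shape_doc(s: PlacedShape):
        if isinstance(s.geometry, Rect):
            geo = {
                "x": s.geometry.x,
                "y": s.geometry.y,
                "width": s.geometry.width,
                "height": s.geometry.height,
            }
        else:
            geo = {"cx": s.geometry.cx, "cy": s.geometry.cy, "r": s.geometry.r}
        return {
            "kind": s.kind,
            "geometry": geo,
            "variant_id": s.variant_id,
            "group_key": s.group_key,
            "fill": s.fill,
        }

    doc = {
        "design": geometry.design,
        "zoom": list(geometry.zoom.path),
        "shapes": [shape_doc(s) for s in geometry.shapes],
        "group_frames": [
            {
                "label": label,
                "x": r.x,
                "y": r.y,
                "width": r.width,
                "height": r.height,
            }
            for label, r in geometry.group_frames
        ],
    }
    if geometry.table_columns is not None:
        doc["table_columns"] = [
            {"field": f, "title": t, "sortable": s} for f, t, s in geometry.table_columns
        ]
    return json.dumps(doc, sort_keys=True, indent=1)
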
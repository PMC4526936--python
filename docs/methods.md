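# Methods

This note documents the models, algorithms, constants, and design choices
behind `varreport`, and what its synthetic-data tests do and do not establish.

## Data model

A report is a flat, ordered list of variant annotations for a single subject.
Each annotation carries three closed vocabularies — impact {pathogenic,
benign, protective}, evidence {well-established, likely, uncertain},
importance {low < medium < high} — plus zygosity, an allele frequency in
[0, 1], linked condition names, a free-text summary, and links. Validation is
complete and collective: every violation in a file is reported in one
machine-readable list, not just the first.

Enum parsing is case-insensitive and tolerates hyphen/space interchange
("Well established" → `well-established`); any other token is an error, never
a guess — silent coercion hides data corruption. Zygosity is carried for
display only; no downstream computation reads it.

Serialization is canonical in both formats (fixed TSV column order, `.` for
empty fields, `;`-joined lists, lowercase enums; JSON with sorted keys), and
parsing re-sorts into the canonical order (importance descending, then effect
rank, then label), so `parse ∘ write` is the identity on canonical datasets
and `write ∘ parse` maps any valid file to its canonical form byte-exactly.
Frequencies are serialized with Python's shortest round-trip float repr so
the value survives a round trip bit-exactly.

**Tie-breaking everywhere** is (effect rank, label code-point order). This is
a global convention: sorting, panel ordering, hierarchy ordering, and
rendering all inherit it, which is what makes geometry and documents
byte-reproducible.

## Effect scale and color

The nine (impact, evidence) pairs are totally ordered into ranks 1–9:
pathogenic block, then benign, then protective; within a block
well-established, likely, uncertain. Placing benign before protective is a
package decision — the ordinal axis mixes severity and certainty and has no
single canonical order; we put the "no known effect" block between the two
directional blocks so that both ends of the scale are the high-certainty
directional categories.

Colors are frozen hex constants derived once from HLS coordinates: pathogenic
hue 0°, protective hue 220° (blue) in the primary scheme or 120° (green) in
the legacy scheme, lightness 0.55, saturation 0.90/0.55/0.25 for
well-established/likely/uncertain. The benign family is neutral gray and
steps lightness 0.92/0.95/0.98 instead of saturation. Red/blue is safe for
red-green color-vision deficiency; the red/green palette exists only to
reproduce the older two-level treemap prototype and is excluded from the
seven study designs. All 18 hex values are distinct, decodable back to their
category, and saturation is strictly decreasing in evidence uncertainty
within each colored family.

## Layout geometry

All designs place shapes on the unit square (origin top-left, y downward);
the renderer scales to a 1200x800 viewBox. Paddings and gaps are named
module constants; none of them is a measured quantity — the original designs
exist only as screenshots, so all spacing is a package decision.

* **Importance weights** for area-proportional layouts: low = 1, medium = 2,
  high = 4 per variant. Monotone, visually distinct, and documented; no
  published values exist.
* **squarify** is the classic greedy squarified treemap: rows are laid along
  the container's shorter side and a row is closed when adding the next
  weight would worsen the row's worst aspect ratio. Areas are exactly
  proportional to weights (to float round-off; conservation is tested at
  1e-9 relative).
* **bar**: three side-by-side importance panels; bar height is the affine
  map (10 − rank)/9 of panel height, so the most severe, best-established
  category is tallest. The axis direction is a decision.
* **bubble**: within each importance panel, a circle's vertical position is
  its effect-rank band (9 equal bands) and its horizontal position is a
  deterministic slot among the variants sharing that band; radius is 0.8 x
  half the smaller of slot width and band height, so non-overlap holds by
  construction. (A fixed ceil(sqrt(m)) column grid was considered but cannot
  simultaneously honor the rank-band vertical encoding; the per-band slots
  keep both.)
* **heatmap**: a row-major grid of equal cells (ceil(sqrt(m)) columns)
  inside three gray importance boxes.
* **treemap**: the overview shows three importance boxes; selecting one
  reveals its variants squarified by importance weight (one zoom level).
* **zoom_treemap**: three-level hierarchy importance → effect category →
  variant, squarified at each level; node weight is the sum of descendant
  variant weights and leaves share a cell's area equally. Every level is
  nested in the overview, so each zoom state shows each covered variant
  exactly once.
* **zoom_partition**: an icicle of three stacked rows; band widths are
  proportional to descendant variant *counts* and are computed from
  cumulative edges with the last edge pinned to the parent's right edge, so
  child widths sum exactly to the parent width.

Zoom states are selection paths (depth ≤ 2); `enumerate_zoom_states` lists
the overview plus every non-empty node, which lets documents precompute every
reachable view. Navigation (`select`/`back`/`reset`) validates against the
dataset's actual hierarchy.

## Rendering

Documents are single-file HTML with inline SVG, one embedded view per zoom
state, a 9-entry color key, the clickable glossary, and — for the table
design — client-side column sorting over precomputed sort keys. Variant
details (effect phrase, importance, frequency, conditions, summary verbatim,
links) live in a fixed side panel rather than floating tooltips: hovering
tooltips are known to occlude the plot and lose context, and a dedicated
panel is also far easier to test. Every glossary term occurring in a detail
block is emitted as a link into the glossary section. There are no
timestamps, no randomness, and no network fetches, so identical inputs give
byte-identical documents. Because detail blocks are shared across views, a
variant's summary appears exactly once per document (not once per embedded
view).

## Quiz battery, oracle, and rubric

The nine-item battery is templated on the dataset: two count fill-ins
(high-importance count; well-established pathogenic count), three count
comparisons (low vs high importance; uncertain vs well-established
pathogenic; pathogenic vs benign-or-protective), one open "discuss with a
clinician" item, two condition-risk comparisons, and an 8-option
"select all that apply" condition item. Choice items use exactly
{Greater than, Equal to, Less than, I don't know}.

Decisions the published materials do not fix:

* **Risk items** are instantiated on the first two distinct condition names
  in canonical variant order. The risk direction is the sign of
  Σ sign(impact) × importance-weight over linked variants (pathogenic +,
  protective −, benign 0; weights 1/2/4); zero or no links → "Equal to".
  This rule is exercised only on synthetic data constructed to be
  unambiguous.
* **Q6's key** is the high-importance pathogenic variants at any evidence
  level; restricting to well-established would collapse it into a subset of
  Q2 and degenerate on small fixtures.
* **Rubric** (totals 10): Q1–Q5, Q7, Q8 score 1 point each on exact match;
  Q6 scores 1 × max(0, correct − incorrect)/|key| with case-insensitive
  gene/label/id matching; Q9 scores 2 × (option-level agreements)/8. Blanks
  and out-of-vocabulary tokens score 0; "I don't know" earns nothing. If
  Q6's key is empty the item scores 1 for an empty response and 0 otherwise
  (the ratio is undefined); packaged fixtures always have a non-empty key.
* The tutorial gate includes a participant iff ≥ 3 of 6 pre-task items are
  correct; the tutorial content itself is supplied by the caller.

Properties tested: 0 ≤ score ≤ 10 always; 10 iff the sheet matches the key
everywhere; correcting any single answer never lowers the score; the oracle
agrees with an independently written naive counter on an exhaustive sweep of
small datasets and 1,000 seeded synthetic datasets.

## Synthetic data and simulated cohorts

`generate_dataset` produces exactly the requested count in every
(importance, impact, evidence) cell, draws fictional `GENE###` symbols
without replacement (real gene names are deliberately avoided so the fixture
cannot be mistaken for medical content), links variants into a fixed
condition pool, and samples allele frequencies uniformly within per-impact
ranges — pathogenic U(0.0001, 0.05), protective U(0.001, 0.10), benign
U(0.05, 0.50). The frequencies only affect tooltip text; no scored
computation reads them. All randomness flows through one explicitly seeded
`numpy` generator, so identical seeds give byte-identical reports.

The packaged `jamie_fixture` (11 variants) covers all tiers, impacts, and
evidence levels; its first two conditions are "stomach flu" and
"age-related macular degeneration", each linked only to pathogenic variants
so both risk items are unambiguous. The true composition of any real study's
mock dataset is unpublished; the fixture is representative, not a
reconstruction.

`simulate_responses` answers each item correctly with the design's planted
probability p, otherwise: a uniformly random wrong choice token; the true
count ± a noise magnitude from {1, 2, 3} truncated at 0 (re-flipped upward if
truncation lands on the truth); a non-key variant name for Q6; the key with
one option flipped for Q9. Assignment is balanced (n per design). This
responder is deliberately simple — no per-participant ability, no
item-difficulty structure, no demographics — so a green recovery test
establishes that the pipeline recovers planted mean orderings, not that the
model resembles human behavior.

## Statistics

Summaries use sample SDs (n−1); published SD values fed into the machinery
are assumed to use the same denominator (the source does not state it).
One-way ANOVA is the standard between/within decomposition with the F upper
tail; zero within-group variance with unequal means raises a degenerate-case
error rather than returning infinity, and all-identical data returns F = 0,
p = 1.

Tukey-Kramer works from (n, mean, SD) triples: pooled
MSE = Σ(nᵢ−1)sᵢ²/Σ(nᵢ−1), SE = √(MSE/2 · (1/nᵢ + 1/nⱼ)),
q = |Δmean|/SE, p_adj = 1 − F_Q(q; k, Σ(nᵢ−1)). The studentized-range CDF
is evaluated with scipy's numerically integrated implementation (outer
integral over the pooled scale, inner over location), which meets the 1e-6
absolute-accuracy requirement on the ranges used; it is cross-checked in the
tests against the k = 2 identity F_Q(q) = P(|t_ν| ≤ q/√2), 100,000-draw
Monte-Carlo simulation, and statsmodels' Tukey HSD on raw data. α defaults
to 0.05 two-sided; p-values are reported raw with significance flags applied
at the caller's α.

Recomputing the packaged published summaries reproduces the two headline
zoomable-vs-bubble comparisons at p < .001. The published borderline
table-vs-bubble comparison (reported at P = .04) does **not** reproduce
exactly from the rounded summary table (we obtain ≈ .079); with two-decimal
means/SDs and a 21-pair adjustment this is expected, and the package treats
it as a noted check, not an assertion.

## Known limitations

* No VCF ingestion, variant calling, or live database links; the package
  renders already-annotated reports.
* Layout spacing constants are conventions, not recovered measurements.
* The grading of open responses is normalized symbol matching, not NLP.
* The responder model cannot generate realistic per-item error correlations.
* The studentized-range evaluation relies on scipy; extremely large q with
  huge df can underflow to p_adj = 0, which is reported as 0.0.
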
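# varreport

Tools for building, rendering, and evaluating interactive personal-genomics
variant reports.

Direct-to-consumer genetic-testing users receive annotated reports listing
gene variants with a reported direction of effect (pathogenic, benign,
protective), the certainty of that call (well-established, likely, uncertain),
a low/medium/high clinical-importance tier, a population allele frequency,
linked conditions, and a free-text summary. How such a report is *presented*
strongly affects whether a non-expert understands it. This package implements
the full experimental apparatus for studying that question:

* a validated data model and canonical TSV/JSON I/O for annotated variant
  reports, with the tabular report's sort/filter/search semantics;
* the 9-level impact x certainty "potential effect" scale and two frozen color
  schemes (red/white/blue, plus a legacy red/green prototype palette);
* deterministic geometry for seven report designs — sortable table, bar
  chart, bubble graph, treemap, heat map, zoomable treemap, and zoomable
  (icicle) partition — including a squarified treemap layout and a zoom-state
  machine;
* self-contained interactive HTML documents (inline SVG, precomputed zoom
  views, side-panel detail blocks, clickable glossary, 9-entry color key);
* a nine-item comprehension-quiz battery with a brute-force answer oracle,
  a 0-10 grading rubric, and the 3-of-6 tutorial inclusion gate;
* seeded synthetic datasets and simulated participant cohorts with planted
  per-design accuracy;
* the study-analysis pipeline: per-design summaries, one-way ANOVA, and
  all-pairs Tukey-Kramer post hoc comparisons computed from summary
  statistics via the studentized range distribution.

## The statistics at the core

For designs (groups) $i = 1..k$ with sizes $n_i$, means $\bar y_i$, and sample
SDs $s_i$, the pooled within-group variance is

$$\mathrm{MSE} = \frac{\sum_i (n_i-1)s_i^2}{\sum_i (n_i-1)},$$

and each pair $(i,j)$ is compared with the Tukey-Kramer statistic

$$q_{ij} = \frac{|\bar y_i - \bar y_j|}{\sqrt{\dfrac{\mathrm{MSE}}{2}\left(\dfrac{1}{n_i}+\dfrac{1}{n_j}\right)}},
\qquad p_{ij} = 1 - F_Q(q_{ij};\,k,\,\nu),$$

where $F_Q$ is the CDF of the studentized range of $k$ means with
$\nu = \sum_i (n_i - 1)$ error degrees of freedom. Because only $(n_i, \bar
y_i, s_i)$ enter, the comparison can be run directly on published summary
tables.

## Worked example

```python
import varreport as vr

ds = vr.jamie_fixture()                 # packaged 11-variant demo dataset
key = vr.oracle_answers(ds)
print(key.answers["Q1"], key.answers["Q7"])
# 3 Greater than
#   (3 high-importance variants; the first risk condition, "stomach flu",
#    is linked only to a pathogenic variant, so risk is above average)

html = vr.render_html(ds, "bubble")     # self-contained interactive report
open("jamie_bubble.html", "w").write(html)

# simulate a cohort with planted per-design accuracy and analyze it
model = vr.ResponderModel(p_correct={"table": 0.5, "bubble": 0.8}, seed=7)
sheets = vr.simulate_responses(ds, key, model, n_per_condition=100)
records = [vr.grade_response(s, key, ds) for s in sheets]
doc = vr.analyze(records)
for s in doc["summaries"]:
    print(s["condition"], round(s["mean"], 2))
# table 5.94
# bubble 8.25
print(round(doc["tukey"][0]["p_adj"], 6))
# 0.0
```

The planted accuracies reappear as the ordering of mean comprehension scores,
and the table-vs-bubble gap is flagged by the Tukey comparison.

The same pipeline is available from a shell:

```bash
varreport synth --seed 42 --out report.tsv
varreport render --input report.tsv --design bubble --out report.html
varreport quiz --input report.tsv --out battery.json
varreport simulate --input report.tsv --seed 7 --out responses.csv
varreport grade --input report.tsv --responses responses.csv --out scores.csv
varreport analyze --scores scores.csv --out analysis.json
```

## Acceptance recomputation

`scripts/acceptance.py` recomputes, from the packaged published per-design
comprehension summary statistics (seven (mean, SD, n) triples), the
Tukey-Kramer adjusted p-values for the zoomable-treemap vs bubble-graph and
zoomable-partition vs bubble-graph comparisons, using the pooled-MSE and
studentized-range machinery above:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Documentation

`docs/methods.md` describes the models, layout algorithms, grading rubric,
synthetic-data assumptions, and numerical choices in detail.
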
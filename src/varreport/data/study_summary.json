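{
 "description": "Published per-design summary statistics from a seven-condition between-subjects comprehension study of personal-genomics report designs (0-10 comprehension score; 1-5 Likert perceived understanding). Means and SDs are as printed, rounded to two decimals; SDs are assumed to use the n-1 denominator.",
 "version": 1,
 "comprehension": [
  {"condition": "table", "n": 105, "mean": 5.65, "sd": 1.83},
  {"condition": "bar", "n": 103, "mean": 6.21, "sd": 1.56},
  {"condition": "bubble", "n": 115, "mean": 6.30, "sd": 1.44},
  {"condition": "treemap", "n": 102, "mean": 5.74, "sd": 1.72},
  {"condition": "heatmap", "n": 104, "mean": 6.25, "sd": 1.40},
  {"condition": "zoom_treemap", "n": 96, "mean": 4.63, "sd": 2.16},
  {"condition": "zoom_partition", "n": 105, "mean": 5.08, "sd": 1.90}
 ],
 "likert_perceived_understanding": [
  {"condition": "bubble", "mean": 4.31, "sd": 1.52},
  {"condition": "zoom_treemap", "mean": 3.29, "sd": 1.87},
  {"condition": "table", "mean": 3.62, "sd": 1.74}
 ],
 "notes": [
  "Reported cohort sizes are internally inconsistent in the source report: the abstract says 730 participants, the results section says 731, and the per-condition ns above sum to 730. The per-condition ns are taken as authoritative for recomputation.",
  "745 participants were recruited; those failing a 3-of-6 pre-task tutorial quiz were excluded.",
  "The published table-vs-bubble comparison is reported at P=.04; recomputing from these rounded summaries may not reproduce that borderline value exactly."
 ]
}
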
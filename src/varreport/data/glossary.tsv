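allele frequency	How common a variant is: the fraction of chromosomes in the population that carry it.
homozygous	Carrying the same variant on both chromosome copies.
heterozygous	Carrying a variant on only one of the two chromosome copies.
pathogenic	Reported to be harmful: associated with increased risk of a condition.
benign	Reported to have no known effect on health.
protective	Reported to reduce the risk of a condition.
well-established	The evidence for the reported effect is strong and replicated.
likely	The evidence for the reported effect is moderately strong.
uncertain	The evidence for the reported effect is weak or preliminary.
clinical importance	A low/medium/high priority reflecting how health-relevant a variant is.
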
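# Published validation confusion counts (1000 adjudicated notes) for a
# rule-based PDAC symptom extractor, with the metric values as printed in
# the source report: sensitivity/PPV/specificity/NPV as percentages (1
# decimal as printed) and F1 on [0,1] (2 decimals as printed).  Used as a
# reference input for metric-arithmetic checks, not produced by this
# package.
symptom_id	tp	tn	fp	fn	sensitivity_pct	ppv_pct	specificity_pct	npv_pct	f1
abdominal_epigastric_pain	156	824	4	16	90.7	97.5	99.5	98.1	0.94
anorexia_early_satiety	78	909	2	11	87.6	97.5	99.8	98.8	0.92
dark_urine	51	938	3	8	86.4	94.4	99.7	99.2	0.90
epigastric_bloating	53	935	1	11	82.8	98.2	99.9	98.8	0.90
nausea_vomiting	97	820	3	7	93.3	97	99.6	99.2	0.95
pale_stool	40	949	5	6	87	88.9	99.5	99.4	0.88
back_pain	95	882	6	17	84.8	94.1	99.3	98.1	0.89
fatigue	105	883	2	10	91.3	98.1	99.8	98.9	0.95
jaundice	90	905	1	4	95.7	98.9	99.9	99.6	0.97
malaise	52	941	2	5	91.2	96.3	99.8	99.5	0.94
pruritus	27	970	1	2	93.1	96.4	99.9	99.8	0.95
weight_loss	101	886	11	2	98.1	90.2	99.8	99.8	0.94
anxiety	79	911	3	7	91.9	96.3	99.7	99.2	0.94
depression	83	892	10	15	84.7	89.3	98.9	98.3	0.87
insomnia	62	925	7	6	91.2	89.9	99.3	99.4	0.91
dvt_lower	19	977	3	1	95	86.4	99.7	99.9	0.91
dvt_upper	21	972	4	3	87.5	84	99.6	99.7	0.86
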
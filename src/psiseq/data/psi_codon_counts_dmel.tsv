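# Psi-codon census of the D. melanogaster female-head transcriptome study.
# One row per (codon, Psi position) combination; 48 rows cover every
# uridine position across the 64 codons.  For each genome class:
# abundance = occurrences of the base codon in qualifying CDS regions,
# observed = called Psi sites landing on that codon position,
# expected_printed / adjp_printed = the study's published expectation and
# Bonferroni-adjusted binomial p (kept for cross-validation of the
# recomputation; they are outputs, not inputs, of the statistics).
# Total Psi sites in coding regions: T_nuclear=907, T_mito=99.
codon	nuclear_abundance	nuclear_expected_printed	nuclear_observed	nuclear_adjp_printed	mito_abundance	mito_expected_printed	mito_observed	mito_adjp_printed
ΨAA	5749	1	0	1.00	9	0	0	1.00
ΨAG	4827	1	0	1.00	1	0	0	1.00
ΨGA	3321	1	0	1.00	68	3	5	1.00
GCΨ	107656	26	45	1.29E-02	88	4	3	1.00
ΨGC	99092	24	21	1.00	1	0	0	1.00
ΨGU	43290	5	9	1.00	20	0	1	1.00
UGΨ	43290	5	2	1.00	20	0	0	1.00
GAΨ	207714	51	23	2.93E-04	36	2	0	1.00
ΨUC	160233	20	31	2.77E-01	13	0	0	1.00
UΨC	160233	20	14	1.00	13	0	0	1.00
ΨUU	105347	9	10	1.00	219	4	3	1.00
UΨU	105347	9	12	1.00	219	4	9	1.73E-01
UUΨ	105347	9	11	1.00	219	4	12	3.51E-03
GGΨ	96329	24	22	1.00	28	1	1	1.00
CAΨ	79960	20	14	1.00	51	3	0	1.00
AΨA	75401	18	1	7.44E-06	129	6	0	6.13E-02
AΨC	164918	40	7	2.99E-09	13	1	0	1.00
AΨU	127100	16	21	1.00	249	6	12	4.38E-01
AUΨ	127100	16	30	1.54E-02	249	6	8	1.00
CΨA	64763	16	2	7.87E-04	18	1	0	1.00
CΨC	102941	25	6	2.00E-04	0	0	0	1.00
CΨG	281351	69	201	9.12E-42	0	0	0	1.00
CΨU	70463	9	13	1.00	22	1	0	1.00
CUΨ	70463	9	10	1.00	22	1	1	1.00
ΨUA	36665	4	1	1.00	335	8	12	1.00
UΨA	36665	4	0	5.31E-01	335	8	7	1.00
ΨUG	124790	15	33	9.98E-04	9	0	1	1.00
UΨG	124790	15	46	1.65E-09	9	0	1	1.00
AΨG	174201	43	48	1.00	6	0	1	1.00
AAΨ	162114	40	11	2.22E-06	125	6	5	1.00
CCΨ	54987	13	12	1.00	56	3	0	1.00
CGΨ	64053	16	19	1.00	7	0	0	1.00
AGΨ	90230	22	3	2.02E-05	17	1	1	1.00
ΨCA	61588	15	1	1.93E-04	77	4	0	9.50E-01
ΨCC	144883	36	12	1.65E-04	6	0	0	1.00
ΨCG	120743	30	9	3.59E-04	3	0	0	1.00
ΨCU	54711	7	4	1.00	74	2	3	1.00
UCΨ	54711	7	9	1.00	74	2	1	1.00
ACΨ	76117	19	8	2.15E-01	73	4	2	1.00
GΨA	49291	12	0	2.52E-04	65	3	1	1.00
GΨC	100296	25	8	4.15E-03	1	0	0	1.00
GΨG	204607	50	68	2.55E-01	6	0	0	1.00
GΨU	84822	10	22	2.19E-02	52	1	2	1.00
GUΨ	84822	10	18	4.81E-01	52	1	2	1.00
ΨGG	74214	18	32	4.79E-02	2	0	0	1.00
ΨAC	136903	34	23	1.00	16	1	0	1.00
ΨAU	85677	10	6	1.00	87	2	0	1.00
UAΨ	85677	10	9	1.00	87	2	5	1.00
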
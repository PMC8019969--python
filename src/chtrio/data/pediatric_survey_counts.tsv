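disease	cohort_size	genes_ch_initial	genes_ch_filtered	samples_ch_initial	samples_ch_filtered	genes_ha_initial	genes_ha_filtered	samples_ha_initial	samples_ha_filtered	unique_ch_samples	unique_ch_genes
adolescent_idiopathic_scoliosis	16	3	1	2	1	7	5	4	4	1	1
congenital_heart_defects	709	29	15	63	18	134	102	193	129	11	11
disorders_of_sex_development	79	6	2	9	2	33	24	20	18	2	2
ewing_sarcoma	287	12	6	24	7	47	39	54	37	7	5
neuroblastoma	259	14	5	26	5	43	35	53	36	5	4
orofacial_cleft	107	4	3	7	4	19	16	19	13	3	3
syndromic_cranial_dysinnervation	172	8	4	15	6	32	28	36	27	6	3
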
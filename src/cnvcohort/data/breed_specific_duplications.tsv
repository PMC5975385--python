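# The most widely shared breed-specific duplications per breed in the same
# cohort; n_sharing is the number of animals of that breed carrying the CNV.
breed	n_sharing	chrom	start	end	location
BSW	10	5	74078801	74086100	intergenic
BSW	10	14	64001	89100	intergenic
FLV	6	17	72899301	72924700	intron of the ENSBTAG00000031160 gene
GUE	6	5	114221601	114225800	intergenic
GUE	6	8	56717001	56730400	intergenic
GUE	6	12	73428801	73437300	intergenic
GUE	6	25	19009101	19013400	intron of the ENSBTAG00000018560 (DNAH3) gene
RED	7	9	88596301	88599700	intron of the ENSBTAG00000015935 (IYD) gene
RED	7	X	36034701	36036900	intergenic
SIM	5	10	24513701	24528400	intergenic
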
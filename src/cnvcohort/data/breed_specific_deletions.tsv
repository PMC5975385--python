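# The most widely shared breed-specific deletions per breed in the same cohort.
breed	n_sharing	chrom	start	end	location
BSW	23	5	23616701	23623400	intergenic
FLV	5	12	76499501	76514300	intergenic
FLV	5	16	23946401	23947000	intergenic
FLV	5	18	63804801	63808200	upstream gene variant of ENSBTAG00000000688
FLV	5	28	7026301	7027000	intron of the ENSBTAG00000020361 (SLC35F3) gene
GUE	10	2	55348801	55371300	intergenic
RED	11	17	25081301	25083200	intergenic
SIM	5	18	63800101	63806400	start lost, coding sequence, 5' UTR, intron of the ENSBTAG00000000688 gene
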
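# The 20 most widely shared duplications in a 146-animal, 13-breed Bos taurus
# whole-genome cohort: representative coordinates (1-based closed, UMD3.1
# chromosome labels) and the reported genomic-location description.
chrom	start	end	location
2	136813001	136815100	intergenic
4	28200301	28203500	intergenic
8	70883001	70885000	intron of the ENSBTAG00000031916 gene (RHOBTB2)
8	74685001	74687800	intergenic
9	53617901	53621800	intergenic
18	50944801	50948100	intergenic
21	2128101	2130400	non coding transcript exon of the ENSBTAG00000048121 gene (SNORD116)
21	59331801	59334500	coding sequence variant and intron of ENSBTAG00000003152 gene
27	5516501	5519500	intron of the ENSBTAG00000033545 gene
27	28539101	28543700	intergenic
27	28543901	28548300	intergenic
27	28548501	28552600	intergenic
27	28878101	28881600	intergenic
28	1893701	1895100	transcript amplification in the ENSBTAG00000045518 gene (5S rRNA)
X	36208701	36209700	intergenic
X	36260901	36262400	intergenic
X	36673801	36676800	intergenic
X	64480501	64481800	intron of the ENSBTAG00000015670 gene (PAK3)
X	64504801	64512100	intron of the ENSBTAG00000015670 gene (PAK3)
X	138259801	138320600	intergenic
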
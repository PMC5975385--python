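# The 20 most widely shared deletions in the same cohort.
chrom	start	end	location
2	136815101	136816200	intergenic
2	136942201	136943800	intergenic
6	5358201	5360200	intergenic
6	5897301	5899100	intergenic
6	5903601	5904300	intergenic
6	6218501	6219600	intron of the ENSBTAG00000035764 gene
6	6548401	6549400	intergenic
7	34622901	34623700	intergenic
8	39388901	39389500	intergenic
8	62206601	62207700	intergenic
14	292501	294900	upstream gene variant of ENSBTAG00000046822 (U6 spliceosomal RNA)
14	322901	325800	upstream gene variant of ENSBTAG00000045988 (5S rRNA)
14	389001	391100	downstream gene variant of ENSBTAG00000045780 (5S rRNA)
16	7825301	7826200	intergenic
17	50668301	50670100	intergenic
21	2020201	2022100	upstream gene variant of ENSBTAG00000046925 (5S rRNA)
21	2025201	2026700	intergenic
X	35728601	35730000	intergenic
X	53961901	53963800	intergenic
X	54097401	54098700	intergenic
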
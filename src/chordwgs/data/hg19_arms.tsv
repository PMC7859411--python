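chrom	arm	start	end
chr1	p	0	121535434
chr1	q	124535434	249250621
chr2	p	0	92326171
chr2	q	95326171	243199373
chr3	p	0	90504854
chr3	q	93504854	198022430
chr4	p	0	49660117
chr4	q	52660117	191154276
chr5	p	0	46405641
chr5	q	49405641	180915260
chr6	p	0	58830166
chr6	q	61830166	171115067
chr7	p	0	58054331
chr7	q	61054331	159138663
chr8	p	0	43838887
chr8	q	46838887	146364022
chr9	p	0	47367679
chr9	q	50367679	141213431
chr10	p	0	39254935
chr10	q	42254935	135534747
chr11	p	0	51644205
chr11	q	54644205	135006516
chr12	p	0	34856694
chr12	q	37856694	133851895
chr13	p	0	16000000
chr13	q	19000000	115169878
chr14	p	0	16000000
chr14	q	19000000	107349540
chr15	p	0	17000000
chr15	q	20000000	102531392
chr16	p	0	35335801
chr16	q	38335801	90354753
chr17	p	0	22263006
chr17	q	25263006	81195210
chr18	p	0	15460898
chr18	q	18460898	78077248
chr19	p	0	24681782
chr19	q	27681782	59128983
chr20	p	0	26369569
chr20	q	29369569	63025520
chr21	p	0	11288129
chr21	q	14288129	48129895
chr22	p	0	13000000
chr22	q	16000000	51304566
chrX	p	0	58632012
chrX	q	61632012	155270560
chrY	p	0	10104553
chrY	q	13104553	59373566
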
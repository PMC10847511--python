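# Optional convenience arm table with GRCh37/hg19-style chromosome lengths and
# centromere-gap coordinates (UCSC gap-track convention). Supply your own table
# if your segments use a different build.
chrom	length	cen_start	cen_end
chr1	249250621	121535434	124535434
chr2	243199373	92326171	95326171
chr3	198022430	90504854	93504854
chr4	191154276	49660117	52660117
chr5	180915260	46405641	49405641
chr6	171115067	58830166	61830166
chr7	159138663	58054331	61054331
chr8	146364022	43838887	46838887
chr9	141213431	47367679	50367679
chr10	135534747	39254935	42254935
chr11	135006516	51644205	54644205
chr12	133851895	34856694	37856694
chr13	115169878	16000000	19000000
chr14	107349540	16000000	19000000
chr15	102531392	17000000	20000000
chr16	90354753	35335801	38335801
chr17	81195210	22263006	25263006
chr18	78077248	15460898	18460898
chr19	59128983	24681782	27681782
chr20	63025520	26369569	29369569
chr21	48129895	11288129	14288129
chr22	51304566	13000000	16000000
chrX	155270560	58632012	61632012
chrY	59373566	10104553	13104553
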
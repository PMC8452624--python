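chrom	length	centromere
chr1	249250621	125000000
chr2	243199373	93300000
chr3	198022430	91000000
chr4	191154276	50400000
chr5	180915260	48400000
chr6	171115067	61000000
chr7	159138663	59900000
chr8	146364022	45600000
chr9	141213431	49000000
chr10	135534747	40200000
chr11	135006516	53700000
chr12	133851895	35800000
chr13	115169878	17900000
chr14	107349540	17600000
chr15	102531392	19000000
chr16	90354753	36600000
chr17	81195210	24000000
chr18	78077248	17200000
chr19	59128983	26500000
chr20	63025520	27500000
chr21	48129895	13200000
chr22	51304566	14700000
chrX	155270560	60600000
chrY	59373566	12500000
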
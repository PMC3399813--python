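# Synthetic per-chromosome L1 amplicon position counts (not derived from any
# genome annotation): chromosome-length-proportional with mild enrichment on
# AT-rich chromosomes and depletion on GC-rich ones. Total ~21,676 positions.
chrom	n_positions
chr1	1594
chr2	1789
chr3	1394
chr4	1590
chr5	1391
chr6	1259
chr7	1018
chr8	1028
chr9	903
chr10	858
chr11	864
chr12	858
chr13	920
chr14	685
chr15	659
chr16	461
chr17	389
chr18	599
chr19	208
chr20	403
chr21	261
chr22	229
chrX	1786
chrY	529
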
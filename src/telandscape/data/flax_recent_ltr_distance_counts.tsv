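# Distances from recent (100% intra-element LTR similarity) LTR insertions
# to the closest predicted gene in the flax WGS assembly, binned. Used as
# example input for the nearest-gene frequency table.
distance_bin	n_scaffolds_over_1mb	n_all_scaffolds
0-1000	13	31
1001-2000	4	12
2001-3000	2	5
3001-4000	1	4
4001-5000	1	2
>5000	7	18
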
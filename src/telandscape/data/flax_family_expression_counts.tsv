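# Putative expression of de novo TE families in the flax WGS assembly:
# families per superfamily and families with at least one EST hit at the
# 70% EST-coverage rule. Used as example input for the expression table.
superfamily	n_families	n_expressed
Copia	819	77
Gypsy	263	20
L1	115	1
hAT	68	7
Mutator	60	0
En-Spm	38	1
Helitron	32	0
Harbinger	15	0
Tc1-Mariner	7	0
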
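# Genome-wide TE annotation of the flax (Linum usitatissimum) WGS assembly:
# per-superfamily match counts and occupied base pairs, as published for the
# 318,250,901-bp assembly. Used as example input for the genome TE table.
# assembly_bp=318250901
superfamily	n_matches	bp_occupied
Copia	89951	29594882
Gypsy	72626	25123127
unclassified-LTR	2797	902298
DIRS	2	102
Penelope	548	30214
RTE	11	618
L1	27632	6684243
unclassified-SINE	1	49
Tc1-Mariner	191	38231
hAT	7935	1986522
Mutator	21124	6320424
P	2	96
Harbinger	1384	344876
En-Spm/CACTA	8330	2372592
Helitron	2154	434859
unclassified	95	8981
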
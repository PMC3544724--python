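# Wicker-style TE taxonomy used throughout the package.
# superfamily	order	te_class	aliases (| separated; matched case-insensitively against
#                                  GFF3 types/attributes and RepeatMasker class/family labels)
Copia	LTR	retrotransposon	LTR/Copia|Copia|Ty1-Copia|RLC
Gypsy	LTR	retrotransposon	LTR/Gypsy|Gypsy|Ty3-Gypsy|RLG
unclassified-LTR	LTR	retrotransposon	LTR|LTR/unknown|LTR/Unknown|RLX
DIRS	DIRS	retrotransposon	LTR/DIRS|DIRS|RYD
Penelope	PLE	retrotransposon	LINE/Penelope|Penelope|PLE|RPP
RTE	LINE	retrotransposon	LINE/RTE|RTE|RIR
L1	LINE	retrotransposon	LINE/L1|L1|RIL
unclassified-SINE	SINE	retrotransposon	SINE|SINE/unknown|RSX
Tc1-Mariner	TIR	DNA-transposon	DNA/TcMar|Tc1-Mariner|TcMar|Tc1/Mariner|DTT
hAT	TIR	DNA-transposon	DNA/hAT|hAT|DTA
Mutator	TIR	DNA-transposon	DNA/MULE|DNA/MULE-MuDR|Mutator|MuDR|MULE|DTM
P	TIR	DNA-transposon	DNA/P|P-element|DTP
Harbinger	TIR	DNA-transposon	DNA/PIF-Harbinger|Harbinger|PIF-Harbinger|DTH
En-Spm/CACTA	TIR	DNA-transposon	DNA/CMC-EnSpm|En-Spm/CACTA|En-Spm|EnSpm|CACTA|CMC|DTC
Helitron	Helitron	DNA-transposon	RC/Helitron|Helitron|DHH
unclassified	unclassified	unclassified	Unknown|unclassified|unknown
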
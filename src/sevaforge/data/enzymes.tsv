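# Restriction enzyme registry: canonical REBASE-style constants.
# cut_top / cut_bottom are offsets in nt from the 3' end of the
# recognition site to the top- and bottom-strand cuts (negative =
# inside the site). overhang length = cut_bottom - cut_top;
# positive -> 5' overhang, negative -> 3', zero -> blunt.
# name	recognition	cut_top	cut_bottom	kind
BsaI	GGTCTC	1	5	IIS
BbsI	GAAGAC	2	6	IIS
BsmBI	CGTCTC	1	5	IIS
BtgZI	GCGATG	10	14	IIS
AarI	CACCTGC	4	8	IIS
ApaI	GGGCCC	-1	-5	IIP
EcoRV	GATATC	-3	-3	IIP
SmaI	CCCGGG	-3	-3	IIP
AscI	GGCGCGCC	-6	-2	IIP
SwaI	ATTTAAAT	-4	-4	IIP
MluI	ACGCGT	-5	-1	IIP
PmeI	GTTTAAAC	-4	-4	IIP
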
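# Published 101-gene-classifier subtype calls for the six molecularly stable
# TNBC cell lines across five expression sources: two public array cohorts
# (GSE15361, GSE10890), CCLE RNA-seq (DepMap 19Q3), the xenograft tumors, and
# the original 2188-gene classifier call on cell-line data.  "*" marks a cell
# line not represented in that dataset (skipped in stability analysis).
cell_line	gse15361	gse10890	ccle	xenograft	tnbctype_2188
HCC70	BL2(0.22)	BL2(0.26)	BL2(0.27)	BL2(0.38)	BL2(0.24)
SUM149PT	BL2(0.14)	*	BL2(0.21)	BL2(0.37)	BL2(0.30)
HCC1806	*	BL2(0.42)	BL2(0.26)	BL2(0.49)	BL2(0.22)
BT549	M(0.18)	M(0.11)	M(0.15)	M(0.41)	M(0.21)
MDAMB453	LAR(0.30)	LAR(0.48)	LAR(0.40)	LAR(0.38)	LAR(0.53)
HCC2157	BL1(0.44)	*	BL1(0.40)	BL1(0.33)	BL1(0.66)
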
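# Published molecular subtype calls for 17 triple-negative breast cancer cell
# lines, in vitro and as mammary fat-pad xenograft tumors, under the original
# 2188-gene centroid classifier (tnbctype) and the reduced 101-gene classifier
# with IM overlay (tnbctype_im).  Cell values: SUBTYPE(rho), optionally
# ";dual:SUBTYPE(rho)" for a ranked dual subtype, or UNS when no centroid
# correlation exceeded the 0.1 cutoff.
cell_line	tnbctype_invitro	tnbctype_im_invitro	tnbctype_xenograft	tnbctype_im_xenograft
HCC70	BL2(0.24)	BL2(0.27);dual:BL1(0.25)	BL2(0.36)	BL2(0.38)
SUM149PT	BL2(0.3)	BL2(0.21);dual:M(0.17)	BL2(0.40)	BL2(0.37)
HCC1806	BL2(0.22)	BL2(0.26)	BL2(0.42)	BL2(0.49)
BT549	M(0.21)	M(0.15)	M(0.40)	M(0.41)
MDAMB453	LAR(0.53)	LAR(0.4)	LAR(0.37)	LAR(0.38)
HCC2157	BL1(0.66)	BL1(0.4)	BL1(0.68)	BL1(0.33)
SUM185PE	LAR(0.39)	UNS	UNS	LAR(0.32)
BT20	UNS	BL2(0.18)	LAR(0.36)	LAR(0.32)
MDAMB157	MSL(0.25)	LAR(0.12)	BL2(0.21)	LAR(0.17)
SUM159PT	MSL(0.14)	BL2(0.18);dual:LAR(0.16)	BL2(0.47)	BL2(0.54)
MDAMB468	BL1(0.19)	BL2(0.2);dual:BL1(0.13)	UNS	BL2(0.24);dual:M(0.23)
MDAMB231	MSL(0.12)	BL2(0.24)	UNS	BL2(0.25)
HCC1187	IM(0.22)	BL2(0.17)	BL2(0.32)	BL2(0.17);dual:BL1(0.14)
DU4475	IM(0.17)	BL1(0.14)	UNS	UNS
MDAMB436	MSL(0.13)	UNS	LAR(0.33)	LAR(0.39)
HCC1937	BL1(0.28)	BL2(0.37)	BL1(0.37)	BL2(0.34);dual:M(0.19)
HCC3153	BL1(0.24)	BL1(0.37)	UNS	M(0.45)
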
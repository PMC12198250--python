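EGFR_RELATED	synthetic stand-in: 36-gene EGFR-related scoring set	ABCA7	ACTB	ACTG1	AKT1	AREG	C12ORF57	CBL	CDC42	EEF1A1	EGF	EGFR	EPS8	ERBB2	ERBB3	GRB2	HBEGF	HOOK2	JUNB	MAPK1	MAPK3	MAT2A	NR4A1	PIK3CA	PLCG1	PTPN11	RAC1	RHOA	RHOB	SEMA4B	SHC1	SOS1	SRC	STAT3	TGFA	VAV2	VMP1
EGFR_SIG	synthetic stand-in: 32-gene derived EGFR signature (12 hub genes included)	ABCA7	ACTB	ACTG1	AREG	C12ORF57	CBL	CDC42	EEF1A1	EGF	EPS8	ERBB2	GRB2	HBEGF	HOOK2	JUNB	MAPK1	MAPK3	MAT2A	NR4A1	PLCG1	PTPN11	RAC1	RHOA	RHOB	SEMA4B	SHC1	SOS1	SRC	STAT3	TGFA	VAV2	VMP1
EGFR_HUB	synthetic stand-in: 12 consensus hub genes	ABCA7	ACTB	ACTG1	C12ORF57	EEF1A1	HOOK2	JUNB	MAT2A	NR4A1	RHOB	SEMA4B	VMP1
CRISPR_RESISTANCE_VERIFIED	the four CRISPR-verified immune-resistance members of the signature	MAT2A	JUNB	C12ORF57	NR4A1
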
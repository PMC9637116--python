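gene	function1	function2	phenotype	actionable
CYP2B6	increased	increased	UM	1
CYP2B6	increased	normal	RM	1
CYP2B6	decreased	increased	Indeterminate	0
CYP2B6	increased	none	IM	1
CYP2B6	normal	normal	NM	0
CYP2B6	decreased	normal	IM	1
CYP2B6	none	normal	IM	1
CYP2B6	decreased	decreased	IM	1
CYP2B6	decreased	none	IM	1
CYP2B6	none	none	PM	1
CYP2C9	increased	increased	UM	1
CYP2C9	increased	normal	RM	1
CYP2C9	decreased	increased	Indeterminate	0
CYP2C9	increased	none	IM	1
CYP2C9	normal	normal	NM	0
CYP2C9	decreased	normal	IM	1
CYP2C9	none	normal	IM	1
CYP2C9	decreased	decreased	IM	1
CYP2C9	decreased	none	IM	1
CYP2C9	none	none	PM	1
CYP2C19	increased	increased	UM	1
CYP2C19	increased	normal	RM	1
CYP2C19	decreased	increased	Indeterminate	0
CYP2C19	increased	none	IM	1
CYP2C19	normal	normal	NM	0
CYP2C19	decreased	normal	IM	1
CYP2C19	none	normal	IM	1
CYP2C19	decreased	decreased	IM	1
CYP2C19	decreased	none	IM	1
CYP2C19	none	none	PM	1
CYP2D6	increased	increased	UM	1
CYP2D6	increased	normal	RM	1
CYP2D6	decreased	increased	Indeterminate	0
CYP2D6	increased	none	IM	1
CYP2D6	normal	normal	NM	0
CYP2D6	decreased	normal	NM	0
CYP2D6	none	normal	IM	1
CYP2D6	decreased	decreased	IM	1
CYP2D6	decreased	none	IM	1
CYP2D6	none	none	PM	1
CYP3A5	increased	increased	UM	1
CYP3A5	increased	normal	RM	1
CYP3A5	decreased	increased	Indeterminate	0
CYP3A5	increased	none	IM	1
CYP3A5	normal	normal	NM	1
CYP3A5	decreased	normal	IM	1
CYP3A5	none	normal	IM	1
CYP3A5	decreased	decreased	IM	1
CYP3A5	decreased	none	IM	1
CYP3A5	none	none	PM	0
DPYD	increased	increased	UM	1
DPYD	increased	normal	RM	1
DPYD	decreased	increased	Indeterminate	0
DPYD	increased	none	IM	1
DPYD	normal	normal	NM	0
DPYD	decreased	normal	IM	1
DPYD	none	normal	IM	1
DPYD	decreased	decreased	IM	1
DPYD	decreased	none	IM	1
DPYD	none	none	PM	1
NUDT15	increased	increased	UM	1
NUDT15	increased	normal	RM	1
NUDT15	decreased	increased	Indeterminate	0
NUDT15	increased	none	IM	1
NUDT15	normal	normal	NM	0
NUDT15	decreased	normal	IM	1
NUDT15	none	normal	IM	1
NUDT15	decreased	decreased	IM	1
NUDT15	decreased	none	IM	1
NUDT15	none	none	PM	1
SLCO1B1	increased	increased	UM	1
SLCO1B1	increased	normal	RM	1
SLCO1B1	decreased	increased	Indeterminate	0
SLCO1B1	increased	none	IM	1
SLCO1B1	normal	normal	NM	0
SLCO1B1	decreased	normal	IM-risk	1
SLCO1B1	none	normal	IM	1
SLCO1B1	decreased	decreased	high-risk	1
SLCO1B1	decreased	none	IM	1
SLCO1B1	none	none	PM	1
TPMT	increased	increased	UM	1
TPMT	increased	normal	RM	1
TPMT	decreased	increased	Indeterminate	0
TPMT	increased	none	IM	1
TPMT	normal	normal	NM	0
TPMT	decreased	normal	IM	1
TPMT	none	normal	IM	1
TPMT	decreased	decreased	IM	1
TPMT	decreased	none	IM	1
TPMT	none	none	PM	1
UGT1A1	increased	increased	UM	1
UGT1A1	increased	normal	RM	1
UGT1A1	decreased	increased	Indeterminate	0
UGT1A1	increased	none	IM	1
UGT1A1	normal	normal	NM	0
UGT1A1	decreased	normal	IM	1
UGT1A1	none	normal	IM	1
UGT1A1	decreased	decreased	PM	1
UGT1A1	decreased	none	PM	1
UGT1A1	none	none	PM	1
VKORC1	increased	increased	UM	1
VKORC1	increased	normal	RM	1
VKORC1	decreased	increased	Indeterminate	0
VKORC1	increased	none	IM	1
VKORC1	normal	normal	NM	0
VKORC1	decreased	normal	risk-carrier	1
VKORC1	none	normal	IM	1
VKORC1	decreased	decreased	risk-carrier	1
VKORC1	decreased	none	IM	1
VKORC1	none	none	PM	1
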
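name	network	x_mm	y_mm	z_mm	radius_mm
l_IPS	DAN	-25	-53	52	4.0
r_IPS	DAN	25	-53	52	4.0
l_DLPFC	ECN	-44	36	20	4.0
r_DLPFC	ECN	44	36	20	4.0
l_FI	SN	-38	26	-10	4.0
r_FI	SN	38	26	-10	4.0
l_PCC	DMN	-5	-52	41	4.0
l_mPFC	DMN	-1	49	-5	4.0
l_IFG	LN	-50	24	5	4.0
l_TPole	LN	-48	12	-32	4.0
l_HIPP	MN	-24	-20	-16	4.0
r_HIPP	MN	24	-20	-16	4.0
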
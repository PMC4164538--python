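family	required	forbidden	priority	min_copies
MYB	MYB_dna_bind,SANT_extra	-	10	1
MYB-related	MYB_dna_bind	SANT_extra	20	1
AP2-EREBP	AP2	B3	30	1
RAV	AP2,B3	-	5	1
ARF	B3,Auxin_resp	-	8	1
B3	B3	AP2,Auxin_resp	40	1
bZIP	bZIP_1	HLH	50	1
bHLH	HLH	bZIP_1	60	1
WRKY	WRKY	-	70	1
NAC	NAM	-	80	1
GRAS	GRAS	-	90	1
FAR1	FAR1	MULE	100	1
C2H2	zf-C2H2	-	110	1
HSF	HSF_dna_bind	-	120	1
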
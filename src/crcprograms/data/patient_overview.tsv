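patient	sex	origin	site	stage	ms_status	tp53	apc	kras
P1	m	liver met	Rectum	IV	MSS	X	X	X
P2	m	lung met	Caecum	IV	MSS	X	X	X
P3	f	liver met	Rectum	IV	MSS	X	X	X
P4	f	liver met	Ascending colon	IV	MSI	X	X	X
P5	f	primary	Transverse colon	IV	MSS	-	-	-
P6	f	primary	Caecum	IV	MSS	X	-	-
P7	m	liver met	Sigmoid	IV	MSS	-	X	X
P8	m	liver met	Caecum	IV	MSS	X	-	-
P9	m	primary	Rectum	IV	MSS	X	-	X
P10	m	primary	Sigmoid	IIIB	MSS	N/A	N/A	N/A
P11	m	primary	Rectum and caecum	IIIB	MSS	-	-	-
P12	m	primary	Rectum and transverse colon	II	MSI	X	X	X
O1	f	liver met	Sigmoid	IV	MSS	X	X	X
O2	f	liver met	Caecum	IV	MSS	X	X	X
O3	f	liver met	Ascending colon	IV	MSI	-	X	-
X1	m	primary	Rectum	I	N/A	N/A	N/A	N/A
X2	m	primary	Ascending colon	II	MSI	N/A	N/A	-
T1	m	primary	Sigmoid	III	N/A	N/A	N/A	N/A
T2	m	primary	Ascending colon	IV	N/A	N/A	N/A	N/A
T3	m	primary	Ascending colon	IVa	MSS	N/A	N/A	X
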
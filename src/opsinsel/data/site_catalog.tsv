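position	category	known_from	known_variants
44	spectral-tuning	SWS2	M/T
46	spectral-tuning	SWS1/2	F/T/L
49	spectral-tuning	RH2, SWS1	S/F/A/V/L
52	spectral-tuning	RH2, SWS1	L/M/T/F
83	spectral-tuning	RH1/2	D/N
86	spectral-tuning	RH2, SWS1	M/T/F/S/L/Y
90	spectral-tuning	SWS1	S/C
91	spectral-tuning	SWS1/2	V/I/S/P
93	spectral-tuning	SWS1	T/P/L/I
94	spectral-tuning	SWS2	A/S/C
96	spectral-tuning	RH1	Y/V
97	spectral-tuning	RH2, SWS2	T/A/S/C
102	spectral-tuning	RH1	Y/F
109	spectral-tuning	SWS1/2	V/A/G
113	spectral-tuning	SWS1	E/D
114	spectral-tuning	SWS1	A/G
116	spectral-tuning	SWS1/2	L/V/T
118	spectral-tuning	SWS1/2	S/T/A/G
122	spectral-tuning	RH1, SWS1/2	E/I/Q/M
124	spectral-tuning	RH1	A/S/G/V
132	spectral-tuning	RH1	A/S
164	spectral-tuning	RH2, LWS	S/A
181	spectral-tuning	LWS	H/Y
194	spectral-tuning	RH1	P/R
195	spectral-tuning	RH1	N/A
207	spectral-tuning	RH2	M/L
208	spectral-tuning	RH1	F/Y
211	spectral-tuning	RH1	H/C
261	spectral-tuning	RH1, SWS2, LWS	F/Y
265	spectral-tuning	SWS2	W/Y
269	spectral-tuning	SWS2, LWS	A/S/T
292	spectral-tuning	RH1/2, SWS2, LWS	A/S
295	spectral-tuning	RH1	A/S
299	spectral-tuning	RH1	A/S
300	spectral-tuning	RH1	I/T/L
47	kinetic/functional	SWS2	T
59	kinetic/functional	RH1	
83	kinetic/functional	RH1	D/N
288	kinetic/functional	RH1	
292	kinetic/functional	RH1	
299	kinetic/functional	RH1	A/S
54	chromophore-pocket	RH1	
119	chromophore-pocket	RH1, LWS	
160	chromophore-pocket	LWS	
47	chromophore-pocket	SWS1	
82	chromophore-pocket	SWS1	
120	chromophore-pocket	SWS1	
258	chromophore-pocket	SWS1, SWS2	
271	chromophore-pocket	SWS1	
307	chromophore-pocket	SWS1	
207	chromophore-pocket	SWS2	
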
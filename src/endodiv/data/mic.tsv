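extract_id	K. pneumoniae	S. aureus	E. coli	P. aeruginosa	S. typhimurium	B. subtilis	C. albicans
MC-1 L	-	-	-	-	-	-	-
MC-2 L	>100	25	100	100	100	>100	-
MC-3 L	-	-	-	-	-	-	-
MC-4 L	-	>100	>100	>100	>100	>100	-
MC-5 L	>100	-	-	-	-	-	-
MC-6 L	-	-	-	-	-	-	-
MC-8 L	-	100	-	100	-	-	-
MC-9 L	-	-	-	>100	-	-	-
MC-10 L	-	>100	-	-	>100	-	-
MC-12 L	>100	-	>100	>100	>100	-	-
MC-14 L	12.5	12.5 (MBC)	12.5 (MBC)	25 (MBC)	12.5 (MBC)	12.5	25
MC-15 L	-	>100	-	-	-	-	-
MC-16 L	-	100	>100	-	>100	>100	100
MC-17 L	-	-	-	-	-	-	-
MC-18 L	50	25	25	25	12.5	12.5	>100
MC-20 L	-	-	-	-	-	-	-
MC-24 L	12.5	12.5	12.5	12.5	12.5 (MBC)	25	-
MC-25 L	-	-	-	-	-	>100	-
MC-13R	-	>100	-	-	-	>100	-
MC-20R	-	>100	-	>100	-	-	-
MC-7 F	-	-	-	>100	-	-	-
MC-14 F	-	12.5 (MBC)	-	25	-	-	25
MC-17 F	-	>100	-	-	-	-	-
MC-21 F	-	-	-	-	-	-	-
MC-22 F	-	-	-	-	100	>100	-
MC-23 F	-	>100	>100	-	>100	-	-
MC-25 F	-	-	-	-	-	-	-
MC-26 F	-	-	-	-	-	-	-
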
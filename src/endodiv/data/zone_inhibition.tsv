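extract_id	K. pneumoniae	S. aureus	E. coli	P. aeruginosa	S. typhimurium	B. subtilis	C. albicans
MC-1 L	-	-	-	-	-	-	-
MC-2 L	10 ± 0.2	21 ± 0.2	22 ± 0.3	21 ± 0	22 ± 0.2	23 ± 0.2	-
MC-3 L	-	-	-	-	-	-	-
MC-4 L	-	12 ± 0.6	14 ± 0.5	12 ± 0.2	15 ± 0	10 ± 0.2	6 ± 0.4
MC-5 L	10 ± 0.3	-	-	-	-	-	-
MC-6 L	-	-	-	-	-	-	-
MC-8 L	-	9 ± 0.5	-	10 ± 0.3	-	-	-
MC-9 L	-	-	-	25 ± 0.5	-	-	-
MC-10 L	-	15 ± 0.3	-	-	10 ± 0	-	-
MC-12 L	15 ± 0.3	-	14 ± 0.2	12 ± 0.3	16 ± 0.3	-	27.5 ± 0.2
MC-14 L	13 ± 0.5	12 ± 0.2	13 ± 0.6	12 ± 0	15 ± 0.3	11 ± 0.5	11 ± 0.2
MC-15 L	-	14 ± 0.5	-	-	-	-	-
MC-16 L	-	17 ± 0	30	-	12 ± 0.2	18 ± 0.5	10 ± 0
MC-17 L	-	-	-	-	-	-	10 ± 0
MC-18 L	35 ± 1	24 ± 0	35 ± 0.3	28 ± 0.5	32 ± 0.2	27 ± 0.3	9 ± 1
MC-20 L	-	-	-	-	-	-	-
MC-24 L	10 ± 0.2	22 ± 1	17 ± 0.2	26 ± 0.5	17 ± 0.4	15 ± 0.3	-
MC-25 L	-	-	-	-	-	10 ± 0.4	-
MC-13R	-	10 ± 0.2	-	-	-	10 ± 0.7	-
MC-20R	-	10 ± 0.3	-	10 ± 0.4	-	-	-
MC-7 F	-	-	-	12 ± 0.4	-	-	-
MC-14 F	-	12 ± 0.4	-	10 ± 0.3	-	-	9 ± 1
MC-17 F	-	15 ± 0.4	-	-	-	-	-
MC-21 F	-	-	-	-	-	-	-
MC-22 F	-	-	-	-	17 ± 0.4	13 ± 0.2	-
MC-23 F	-	16 ± 0	22 ± 0.3	-	12 ± 0.5	-	-
MC-25 F	-	-	-	-	-	-	-
MC-26 F	-	-	-	-	-	-	-
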
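extract_id	A-549	HCT-116	MCF-7	PC-3
MC-1 L	13 ± 0.8	0 ± 0	13 ± 0.3	16 ± 0.5
MC-2 L	35 ± 1	22 ± 0.3	52 ± 0	10 ± 0
MC-3 L	33 ± 0.5	12 ± 0.4	20 ± 0.4	41 ± 0.4
MC-4 L	67 ± 1	65 ± 0.2	91 ± 0.2	79 ± 0.3
MC-5 L	0 ± 0	47 ± 0	76 ± 0	51 ± 0.4
MC-6 L	27 ± 0.5	35 ± 0.5	54 ± 0.5	56 ± 0.4
MC-8 L	98 ± 1	99 ± 0.4	94 ± 0.4	95 ± 0.4
MC-9 L	22 ± 0.8	10 ± 0.2	14 ± 0.3	48 ± 0.2
MC-10 L	47 ± 0	18 ± 0.4	45 ± 0.4	49 ± 0
MC-12 L	34 ± 1	29 ± 0.6	37 ± 0.2	58 ± 0
MC-14 L	96 ± 1	100 ± 0.2	94 ± 0.3	100 ± 0.2
MC-15 L	24 ± 0.8	51 ± 0.8	86 ± 0	59 ± 0.5
MC-16 L	59 ± 0	47 ± 0.2	88 ± 0.2	61 ± 0.2
MC-17 L	48 ± 1	23 ± 0	23 ± 0.5	25 ± 0
MC-18 L	100 ± 0	93 ± 0.5	100 ± 0.2	90 ± 0.2
MC-20 L	77 ± 1	82 ± 0.5	77 ± 0.2	63 ± 0.5
MC-24 L	77 ± 1	99 ± 0.4	88 ± 0.4	96 ± 0
MC-25 L	88 ± 1	100 ± 0.2	94 ± 0.3	99 ± 0.4
MC-13R	40 ± 1	20 ± 0.6	35 ± 0.2	50 ± 0.5
MC-20R	10 ± 1	1 ± 0.4	26 ± 0.2	5 ± 0
MC-7 F	83 ± 1	87 ± 0	92 ± 0.5	74 ± 0
MC-14 F	99 ± 0	100 ± 0.4	91 ± 0.5	100 ± 0
MC-17 F	53 ± 1	28 ± 0	0 ± 0	7 ± 0
MC-21 F	0 ± 0	8 ± 0.3	11 ± 0.3	17 ± 0
MC-22 F	84 ± 1	75 ± 0.3	88 ± 0.4	80 ± 0.2
MC-23 F	0 ± 0	9 ± 0.2	0 ± 0	33 ± 0.4
MC-25 F	45 ± 1	90 ± 0.2	77 ± 0	81 ± 0.6
MC-26 F	94 ± 0	87 ± 0.5	97 ± 0.5	91 ± 0.2
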
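extract_id	HCT-116	A-549	PC-3	T47D
MC-8 L	38.0 ± 0.08	24.3 ± 0.03	26.4 ± 0.06	19.7 ± 0.1
MC-14 L	<10 ± 0.0	<10 ± 0.0	<10 ± 0.0	<10 ± 0.0
MC-18 L	9.0 ± 0.02	4.8 ± 0.02	27.7 ± 0.06	19.6 ± 0.02
MC-24 L	<10 ± 0.0	<10 ± 0.0	<10 ± 0.0	<10 ± 0.0
MC-25 L	<10 ± 0.0	<10 ± 0.0	9.9 ± 0.02	12.7 ± 0.02
MC-7 F	32.2 ± 0.2	23.6 ± 0.02	32.3 ± 0.04	26 ± 0.04
MC-14 F	62.8 ± 0.5	<10 ± 0.0	23.3 ± 0.02	42.7 ± 0.3
MC-26 F	11.1 ± 0.01	<10 ± 0.0	11.7 ± 0.01	8.0 ± 0.02
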
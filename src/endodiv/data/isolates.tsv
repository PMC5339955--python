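isolate_code	tissue	taxon_label	accession	closest_match	identity_pct
MC-1 L	leaf	Colletotrichum boninense	KU527781	JQ676184	100
MC-2 L	leaf	Fusarium chlamydosporum	KU527782	KP641161	99
MC-3 L	leaf	Curvularia aeria	KU527783	KP131939	99
MC-4 L	leaf	Alternaria alternata	KU527784	GQ121322	100
MC-5 L	leaf	Aspergillus flavus	KU527785	KM285408	99
MC-6 L	leaf	Neosartorya hiratsukae	KU527786	GQ461906	98
MC-8 L	leaf	Aspergillus oryzae	KU680345	KT964480	93
MC-9 L	leaf	Penicillium commune	KU527787	KF938402	99
MC-10 L	leaf	Muscodor yucatanensis	KU527788	KJ572191	99
MC-12 L	leaf	Fusarium solani	KU527789	FJ426390	99
MC-14 L	leaf	Fusarium oxysporum	KU527790	JX406507	99
MC-15 L	leaf	Aspergillus sp.	KU527791	GQ352493	99
MC-16 L	leaf	Neurospora sp.	KU527792	KJ676544	99
MC-17 L	leaf	Aspergillus waksmanii	KU527793	EF669934	99
MC-18 L	leaf	Aspergillus fumigatus	KU527794	KM207771	99
MC-20 L	leaf	Cladosporium sp.	KU680346	KP050606	89
MC-24 L	leaf	Cladosporium tenuissimum	KU527795	KJ589554	100
MC-25 L	leaf	Fusarium sp.	KU527796	KC007281	100
MC-13R	root	Alternaria carthami	KU527797	JF710542	99
MC-20R	root	Cladosporium sp.	KU527798	JQ388271	99
MC-7 F	flower	Fusarium sp.	KU527799	KJ567458	99
MC-14 F	flower	Fusarium oxysporum	KU527800	KT876658	99
MC-17 F	flower	Colletotrichum gloeosporioides	KU527801	KM520010	99
MC-21 F	flower	Cladosporium cladosporioides	KU527802	KP900248	99
MC-22 F	flower	Fusarium oxysporum	KU527803	KF264963	100
MC-23 F	flower	Gibberella intermedia	KU527804	JQ846048	99
MC-25 F	flower	Fusarium redolens	KU527805	KJ540090	99
MC-26 F	flower	Fusarium oxysporum	KU527806	KF998987	99
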
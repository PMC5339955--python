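genus	order	class	phylum
Colletotrichum	Glomerellales	Sordariomycetes	Ascomycota
Fusarium	Hypocreales	Sordariomycetes	Ascomycota
Gibberella	Hypocreales	Sordariomycetes	Ascomycota
Neurospora	Sordariales	Sordariomycetes	Ascomycota
Muscodor	Xylariales	Sordariomycetes	Ascomycota
Curvularia	Pleosporales	Dothideomycetes	Ascomycota
Alternaria	Pleosporales	Dothideomycetes	Ascomycota
Cladosporium	Capnodiales	Dothideomycetes	Ascomycota
Aspergillus	Eurotiales	Eurotiomycetes	Ascomycota
Neosartorya	Eurotiales	Eurotiomycetes	Ascomycota
Penicillium	Eurotiales	Eurotiomycetes	Ascomycota
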
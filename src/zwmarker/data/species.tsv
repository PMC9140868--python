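designation	species	source	males	females
S1	Crinifer personatus	Wroclaw Zoo	1	1
S2	Crinifer piscator	captive, Poland	1	1
S3	Gallirex porphyreolophus	captive, Poland	1	6
S4	Menelikornis leucotis	captive, Poland	1	2
S5	Musophaga violacea	Wroclaw Zoo	3	4
S6	Proturacus erythrolophus	captive, Poland	19	13
S7	Proturacus leucolophus	captive, Poland	1	2
S8	Tauraco buffoni	captive, Poland	1	3
S9	Tauraco fischeri	captive, Poland	1	1
S10	Tauraco hartlaubi	captive, Poland	5	2
S11	Tauraco livingstonii	captive, Poland	1	3
S12	Tauraco persa	captive, Poland	3	5
S13	Tauraco schalowi	captive, Poland	2	1
S14	Tauraco schuettii	captive, Poland	1	1
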
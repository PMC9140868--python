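marker	fwd_name	fwd_seq	rev_name	rev_seq	gene
M1	P2	TCTGCATCGCTAAATCCTTT	P8	CTCCCAAGGATGAGRAAYTG	CHD1
M2	1272H	TCCAGAATATCTTCTGCTCC	1237L	GAGAAACTGTGCAAAACAG	CHD1
M3	CHD1i9-F	CAGCAGAAATCAATCCAAGAC	CHD1i9-R	CAGCCCATTTAACTGATAATCTC	CHD1
M4	2550F	GTTACTGATTCGTCTACGAGA	2718R	ATTGAAATGATCCAGTGCTTG	CHD1
M5	CHD1i16-F	GTCCTGATTTTCTCACAGATGG	CHD1i16-R	ATGATCCAGTGCTTGTTTCC	CHD1
M6	USP1	CTATGCCTACCACMTTCCTATTTGC	USP3	AGAAGATGSWCTGAARTCCAGCT	SPIN
M7	NIPBLi16-F	TTGTCAGAGTTGCTGGAGATAC	NIPBLi16-R	AATTTGATGGCACATAACTGTAG	NIPBL
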
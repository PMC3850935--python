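name	pattern	strand
G-box	CACGTG	
ABRE	ACGTGGC	
Box4	ATTAAT	
TCA-element	CCATCTTTTT	
MBS	CAACTG	
HSE	AGAANNTTCT	
TC-rich_repeats	ATTTTCTTCA	
circadian	CAANNNNATC	
Skn-1_motif	GTCAT	
W-box	TTGACC	
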
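chr3	188153283	188890671	LPP	0	+
chr4	55853647	55905086	EXOC1	0	+
chr7	150716605	150724284	GIMAP1	0	+
chr15	84235772	84245358	GOLGA6L4	0	+
chr15	84507884	84516814	GOLGA6L5P	0	-
chr15	82429815	82439153	GOLGA6L9	0	+
chr15	84350121	84359422	LOC102724093	0	+
chr5	71719274	71721048	CARTPT	0	+
chr5	113513693	113595285	YTHDC2	0	+
chr11	120336412	120489937	ARHGEF12	0	+
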
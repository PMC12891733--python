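v_gene	cdr3_aa	subjects	shared_antigens
TCRBV05.01.01	CASSRTCLKPEKTYF	S02;S03	G12A
TCRBV29.01.01	CASSYCPSCNFCCF	S01;S03	G12V
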
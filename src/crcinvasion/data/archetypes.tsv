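subtype	proliferation	crypt_base	epithelial	mesenchymal	emt_activation	caf	stromal	invasive_front	central_tumor
proliferative	1	1	0	-1	-1	-1	-1	-1	1
collective	1	0	1	-1	-1	-1	-1	-1	0
crypt-like	1	0	0	1	0	1	1	0	1
EMT	-1	0	0	1	1	1	1	0	-1
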
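name	subgroup
ref_IIa_1	IIa
ref_IIa_2	IIa
ref_IIb_1	IIb
ref_IIb_2	IIb
ref_IIc_1	IIc
ref_IIc_2	IIc
ref_IId_1	IId
ref_IId_2	IId
ref_IIe_1	IIe
ref_IIe_2	IIe
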
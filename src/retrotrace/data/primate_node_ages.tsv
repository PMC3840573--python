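node	age	age_upper
HomoPan	6.7	
Homininae	9.1	
Hominidae	15.8	
Hominoidea	20.6	
Cercopithecoidea	14.1	
Catarrhini	29.2	
Simiiformes	42.6	65.2
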
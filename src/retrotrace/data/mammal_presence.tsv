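taxon	P7	P9
Modo	absent	present
Loaf	present	present
Cafa	present	present
Aime	present	present
Eqca	present	present
Bota	present	present
Susc	present	present
Orcu	absent	present
Mumu	absent	present
Rano	absent	present
Hosa	present	present
Mamu	present	present
Caja	present	present
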
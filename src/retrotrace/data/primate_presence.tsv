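taxon	P1	P2	P3	P10
Hosa	present	present	present	present
Patr	present	present	present	present
Gogo	present	present	present	present
Poab	present	present	present	present
Nole	present	present	present	present
Mamu	present	present	absent	present
Chae	present	present	absent	present
Caja	present	absent	absent	present
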
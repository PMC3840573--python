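node	age	age_upper
Carnivora	43.0	
Zooamata	77.0	
Cetartiodactyla	61.9	
Laurasiatheria	78.0	
Murinae	20.9	
Glires	82.0	
Catarrhini	29.2	
Primates	42.6	
Euarchontoglires	90.0	
Boreoeutheria	92.0	
Eutheria	94.4	
Theria	163.9	167.4
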
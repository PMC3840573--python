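(Modo,(Loaf,((((Cafa,Aime)Carnivora,Eqca)Zooamata,(Bota,Susc)Cetartiodactyla)Laurasiatheria,((Orcu,(Mumu,Rano)Murinae)Glires,((Hosa,Mamu)Catarrhini,Caja)Primates)Euarchontoglires)Boreoeutheria)Eutheria)Theria;
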
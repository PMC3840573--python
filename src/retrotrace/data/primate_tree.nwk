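((((((Hosa,Patr)HomoPan,Gogo)Homininae,Poab)Hominidae,Nole)Hominoidea,(Mamu,Chae)Cercopithecoidea)Catarrhini,Caja)Simiiformes;
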
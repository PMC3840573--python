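>PPP1R2P9_synthetic synthetic 202-aa scaffold embedding the eight identified peptides at their reported ranges; filler elsewhere (not the real sequence)
MAGTSAGTSAGTSAGKNKSSSGSSVATSGQQSGGTIQDVKRKAGTSAGTSAGTSAGRATY
RDYDLMKANEPGTSYMSVQDNGEDSVRDVEGEDSVRGAGTSAGTSAGTSAGTSAGTSAGT
SAGTSAGTSAGTSAGTSAGTRRLHYNEELNIKLAGTSAGTSAGTSAGTSAGTSAGTSAGT
SAGTSAGTSAGTSAGTSAGTSA
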
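protein	peptide	range_start	range_end	n_spectra	mz_meas	z	score
PPP1R2P9	K.NKSSSGSSVATSGQQSGGTIQDVK.R	17	40	6	770.71	3	21.95
PPP1R2P9	K.SSSGSSVATSGQQSGGTIQDVK.R	19	40	6	1034.49	2	99.44
PPP1R2P9	K.SSSGSSVATSGQQSGGTIQDVKR.K	19	41	4	1112.54	2	38.09
PPP1R2P9	R.LHYNEELNIK.L	143	152	2	424.89	3	31.40
PPP1R2P9	K.ANEPGTSYMSVQDNGEDSVRDVEGEDSVR.G	68	96	2	1053.45	3	63.05
PPP1R2P9	R.RLHYNEELNIK.L	142	152	1	476.92	3	29.73
PPP1R2P9	R.ATYRDYDLMK.A	58	67	1	431.20	3	28.17
PPP1R2P9	K.ANEPGTSYMSVQDNGEDSVR.D	68	87	1	1086.46	2	69.26
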
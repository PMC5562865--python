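# Synthetic domain-architecture table for the human CNTN4 ectodomain.
# Six N-terminal IgC2 modules followed by four FnIII modules.  Each IgC2
# carries one internal disulfide bridge; residues inside the bridge
# (n_protected) are clamped and do not contribute to the unfolding length.
# The per-domain residue partitions below are synthetic placeholders: they
# are chosen to be consistent with the module sizes of the CNTN family
# (~90-100 aa per module, ~980 aa ectodomain) and with the published
# stretched-length ranges (IgC2 10-18 nm, FnIII 29-33 nm at 0.36-0.40
# nm/aa); they are not an exact transcription of any deposited sequence
# annotation.
# columns: name  dclass  n_res  n_protected  linker_after  d_fold
name	dclass	n_res	n_protected	linker_after	d_fold
IgC2_1	IgC2	95	56	5	4.5
IgC2_2	IgC2	96	55	4	4.5
IgC2_3	IgC2	94	51	5	4.5
IgC2_4	IgC2	97	40	6	4.5
IgC2_5	IgC2	98	40	4	4.5
IgC2_6	IgC2	96	37	5	4.5
FnIII_1	FnIII	97	0	4	4.5
FnIII_2	FnIII	96	0	5	4.5
FnIII_3	FnIII	94	0	4	4.5
FnIII_4	FnIII	93	0	0	4.5
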
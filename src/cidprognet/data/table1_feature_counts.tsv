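network_cohort	feature_type	n_90A	n_91A	n_181A
90A	I	0	0	0
90A	II	48	0	48
90A	III	1	1	0
90A	IV	82	0	0
181A	I	2	2	2
181A	II	140	0	140
181A	III	0	14	14
181A	IV	0	0	146
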
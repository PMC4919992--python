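sample_id	timepoint_days	treatment	delta_fum	c_fum	delta_nfum	c_nfum
D	32	13C	-2.10	42.0	-26.5	30.0
D	32	13C	-1.05	40.5	-26.9	29.0
D	32	13C	-3.40	43.2	-26.2	31.0
D	32	12C	-26.90	41.0	-26.4	29.5
D	32	12C	-27.40	42.5	-26.8	30.5
D	32	12C	-26.60	40.2	-26.1	29.0
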
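# WV-2-like band metadata: boxcar responses over [min_nm, max_nm]
band	center_nm	min_nm	max_nm	K	delta_lambda_um
coastal	427	400	450	0.009295654	0.0473
blue	478	450	510	0.01783568	0.0543
green	546	510	580	0.01364197	0.063
yellow	608	585	625	0.006810718	0.0374
red	659	630	690	0.01851735	0.0574
rededge	724	705	745	0.0058628	0.0393
nir1	831	770	895	0.02021583	0.0989
nir2	908	860	1040	0.009042234	0.0996
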
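# nuclide: At-211
# Synthetic decay-scheme fixture for testing (main emissions only, yields
# approximate); not a substitute for the evaluated nuclear data files.
# columns: kind	energy_MeV	yield	[spectrum]
alpha	5.8672	0.4180	-
alpha_recoil	0.1134	0.4180	-
photon	0.0787	0.2110	-
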
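# nuclide: Po-211
# Synthetic decay-scheme fixture for testing (main emissions only, yields
# approximate); not a substitute for the evaluated nuclear data files.
# columns: kind	energy_MeV	yield	[spectrum]
alpha	7.4503	0.9892
alpha	6.5681	0.0054
alpha_recoil	0.1440	0.9946
photon	0.5698	0.0054
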
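# nuclide: Bi-207
# Synthetic decay-scheme fixture for testing (main emissions only, yields
# approximate); not a substitute for the evaluated nuclear data files.
# columns: kind	energy_MeV	yield	[spectrum]
photon	0.5697	0.9775
photon	1.0637	0.7458
photon	1.7702	0.0687
electron	0.4816	0.0154
electron	0.9756	0.0709
electron	0.0567	0.0230
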
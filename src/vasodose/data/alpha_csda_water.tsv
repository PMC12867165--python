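# CSDA range of alpha particles in liquid water.
# Approximate values digitized from the standard public stopping-power
# compilations (ASTAR family); smooth and monotone, intended for
# desk-scale transport where sub-percent range fidelity is not required.
# columns: energy_MeV	csda_range_g_cm2
0.1	9.0e-5
0.25	1.7e-4
0.5	3.0e-4
1.0	5.9e-4
1.5	9.5e-4
2.0	1.40e-3
3.0	2.40e-3
4.0	3.60e-3
5.0	5.00e-3
6.0	6.60e-3
7.0	8.40e-3
8.0	1.03e-2
9.0	1.24e-2
10.0	1.46e-2
11.0	1.70e-2
12.0	1.96e-2
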
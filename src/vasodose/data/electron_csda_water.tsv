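# CSDA range of electrons in liquid water.
# Approximate values digitized from the standard public stopping-power
# compilations (ESTAR family), extended below 10 keV with a smooth
# power-law tail; positrons reuse this table (collisional component).
# columns: energy_MeV	csda_range_g_cm2
0.001	5.0e-6
0.002	1.5e-5
0.005	7.7e-5
0.01	2.515e-4
0.02	8.566e-4
0.03	1.756e-3
0.05	4.320e-3
0.07	7.920e-3
0.1	1.431e-2
0.2	4.479e-2
0.3	8.420e-2
0.5	1.766e-1
0.7	2.755e-1
1.0	4.367e-1
1.5	7.075e-1
2.0	9.785e-1
3.0	1.514e0
5.0	2.550e0
7.0	3.545e0
10.0	4.975e0
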
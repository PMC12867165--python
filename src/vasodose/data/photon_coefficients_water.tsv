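# Photon mass attenuation and mass energy-absorption coefficients for
# liquid water. Approximate values digitized from the standard public
# photon cross-section compilations (XCOM family).
# columns: energy_MeV	mu_over_rho_cm2_g	muen_over_rho_cm2_g
0.01	5.329	4.944
0.015	1.673	1.374
0.02	0.8096	0.5503
0.03	0.3756	0.1557
0.04	0.2683	0.06947
0.05	0.2269	0.04223
0.06	0.2059	0.03190
0.08	0.1837	0.02597
0.10	0.1707	0.02546
0.15	0.1505	0.02764
0.20	0.1370	0.02967
0.30	0.1186	0.03192
0.40	0.1061	0.03279
0.50	0.0969	0.03299
0.60	0.0896	0.03284
0.80	0.0786	0.03206
1.0	0.0707	0.03103
1.5	0.0575	0.02833
2.0	0.0494	0.02608
3.0	0.0397	0.02281
4.0	0.0340	0.02066
5.0	0.0303	0.01915
6.0	0.0277	0.01806
8.0	0.0243	0.01658
10.0	0.0222	0.01566
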
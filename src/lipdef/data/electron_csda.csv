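# electron continuous-slowing-down (CSDA) range in water; v1
# reconstructed from published stopping-power compilations
energy_MeV,csda_water_g_cm2
0.01,0.0002515
0.015,0.0005147
0.02,0.0008566
0.03,0.001756
0.04,0.002919
0.05,0.00432
0.06,0.00594
0.08,0.009773
0.1,0.01431
0.15,0.02817
0.2,0.04494
0.3,0.08421
0.4,0.1288
0.5,0.1766
0.6,0.2275
0.8,0.3362
1,0.4367
1.5,0.7075
2,0.9785
3,1.514
4,2.037
5,2.55
6,3.052
8,4.03
10,4.975
15,7.219
20,9.32
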
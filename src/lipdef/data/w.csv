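# photon mass interaction coefficients (cm^2/g), element W; v1
# reconstructed from published NIST-style compilations; see docs/methods.md for provenance and accuracy
# duplicated energies mark absorption edges (first row = below edge, second = above)
energy_MeV,mu_rho,mu_en_rho,pe,incoh,pair
0.004,1047,1035.66347,1035.66347,1.907991799e-10,0
0.005,590,578.6634704,578.6634704,6.55175161e-08,0
0.006,365,353.6634683,353.6634682,2.197626719e-06,0
0.008,169,157.6633623,157.6633607,0.0001097689262,0
0.0102,91,79.66248932,79.66247019,0.001000248057,0
0.0102,230,218.6624893,218.6624702,0.001000248057,0
0.012,180,168.6605774,168.6605113,0.002959129544,0
0.015,139,127.6547075,127.6544589,0.00901149716,0
0.02,65.73,57.11981214,57.11895198,0.02386009051,0
0.03,22.73,18.45696622,18.45419348,0.05328213823,0
0.04,10.67,8.077216441,8.072315852,0.07327270486,0
0.05,5.949,4.186160493,4.179258549,0.08551767955,0
0.06,3.713,2.422934875,2.414239307,0.09287235731,0
0.069525,2.552,0.5185478646,1.536318782,0.09705670992,0
0.069525,11.23,3.389935489,10.21431878,0.09705670992,0
0.08,7.81,2.942220065,7.002600964,0.09966475541,0
0.1,4.438,2.083964331,3.870599927,0.1013458681,0
0.15,1.581,0.8914874429,1.266387116,0.09833203191,0
0.2,0.7844,0.4550061255,0.5667092687,0.09297243452,0
0.3,0.3238,0.1776571386,0.1837696118,0.08301130645,0
0.4,0.1925,0.09813749608,0.08470335771,0.07520425792,0
0.5,0.1378,0.06679287984,0.04764681422,0.06907287246,0
0.6,0.1093,0.05163470546,0.03042814531,0.06412189972,0
0.8,0.08066,0.03792674422,0.01573465896,0.05654345026,0
1,0.06618,0.03180152596,0.009847082115,0.05093262673,0
1.25,0.05577,0.02904329696,0.007877665692,0.04560101656,0
1.5,0.05,0.02687742313,0.00656472141,0.0414735846,0
2,0.04433,0.02489006255,0.004923541057,0.03541311976,0.002622415296
3,0.04075,0.0252452283,0.003282360705,0.02787087486,0.008983718603
4,0.04038,0.0272073512,0.002461770529,0.02324952111,0.01432268772
5,0.04103,0.029485968,0.001969416423,0.02007769007,0.01876094699
6,0.0421,0.03177312332,0.001641180352,0.01774500766,0.02255943874
8,0.04472,0.03610531503,0.001230885264,0.01451288689,0.02888920853
10,0.04747,0.04001706771,0.0009847082115,0.01235784597,0.0340716767
15,0.05384,0.04816358996,0.000656472141,0.009140761956,0.0440179296
20,0.05893,0.05429919752,0.0004923541057,0.007332308697,0.05109135109
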
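# photon mass interaction coefficients (cm^2/g), element H; v1
# reconstructed from published NIST-style compilations; see docs/methods.md for provenance and accuracy
# duplicated energies mark absorption edges (first row = below edge, second = above)
energy_MeV,mu_rho,mu_en_rho,pe,incoh,pair
0.001,7.217,6.561981154,6.56143947,0.2779916739,0
0.0015,2.148,1.58292932,1.581978647,0.3259528501,0
0.002,1.059,0.5610528361,0.5597023333,0.348022499,0
0.003,0.5612,0.1187599617,0.1166327909,0.3670038499,0
0.004,0.4546,0.03535441114,0.03247306358,0.3744243979,0
0.005,0.4193,0.01270112246,0.009083010229,0.3777207635,0
0.006,0.4042,0.005740941176,0.00140099088,0.3791526568,0
0.008,0.3914,0.006095813914,0.0003914,0.3768944283,0
0.01,0.3854,0.007432402952,0.0003854,0.3755672235,0
0.015,0.3764,0.01062251909,0.0003764,0.3715090814,0
0.02,0.3695,0.01358119199,0.0003695,0.3664790624,0
0.03,0.357,0.0188519181,0.000357,0.3554052743,0
0.04,0.3458,0.02340239479,0.0003458,0.3447380012,0
0.05,0.3355,0.02734820289,0.0003355,0.3346975296,0
0.06,0.326,0.03078784093,0.000326,0.3253453681,0
0.08,0.3091,0.03645524804,0.0003091,0.3086026526,0
0.1,0.2944,0.04086513531,0.0002944,0.293983699,0
0.15,0.2651,0.04833870848,0.0002651,0.2647797489,0
0.2,0.2429,0.05273552491,0.0002429,0.2426257713,0
0.3,0.2112,0.05710145696,0.0002112,0.210974722,0
0.4,0.1893,0.05874053962,0.0001893,0.1891027289,0
0.5,0.1729,0.05913441217,0.0001729,0.1727219765,0
0.6,0.1599,0.05886552178,0.0001599,0.1597365327,0
0.8,0.1405,0.05749903631,0.0001405,0.140357485,0
1,0.1263,0.05564755721,0.0001263,0.1261724071,0
1.25,0.1129,0.05317787755,0.00010104,0.1127862708,1.186e-05
1.5,0.1027,0.05082685655,8.42e-05,0.1025050024,0.000110220797
2,0.0876,0.04652693336,6.315e-05,0.0874395836,9.694129192e-05
3,0.0691,0.03993519873,4.21e-05,0.0687593434,0.0002984117755
4,0.0581,0.03537577863,3.1575e-05,0.05733809328,0.0007302501519
5,0.0505,0.0318852953,2.526e-05,0.04950657857,0.0009681091874
6,0.045,0.0292158051,2.105e-05,0.04374991026,0.001229003434
8,0.0375,0.02537527352,1.57875e-05,0.0357767665,0.001707425559
10,0.0325,0.02265368048,1.263e-05,0.03046223369,0.002025123223
15,0.0254,0.01867213745,8.42e-06,0.0225304009,0.002861173275
20,0.0215,0.01638356619,6.315e-06,0.01807231036,0.00342137136
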
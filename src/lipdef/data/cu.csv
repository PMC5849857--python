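# photon mass interaction coefficients (cm^2/g), element Cu; v1
# reconstructed from published NIST-style compilations; see docs/methods.md for provenance and accuracy
# duplicated energies mark absorption edges (first row = below edge, second = above)
energy_MeV,mu_rho,mu_en_rho,pe,incoh,pair
0.001,10570,10564.96309,10564.96309,1.610889654e-19,0
0.0015,4418,4412.963087,4412.963087,2.707339779e-11,0
0.002,2154,2148.963087,2148.963087,7.513895839e-08,0
0.003,748.8,743.7630264,743.7630261,6.062267181e-05,0
0.004,342,336.9620975,336.9620898,0.0009969363082,0
0.005,187,181.9587739,181.9587322,0.004354517938,0
0.006,114,108.9526476,108.9525268,0.01055994421,0
0.008,52.55,47.48527019,47.48484271,0.02824400354,0
0.008979,38.5,21.60434021,33.42539814,0.03768857027,0
0.008979,278.4,176.6579382,273.3253981,0.03768857027,0
0.01,215.9,144.2361136,211.3534596,0.04727861766,0
0.015,74.05,56.53327295,71.71331672,0.08451415997,0
0.02,33.79,27.19271917,32.32083836,0.1067083075,0
0.03,10.92,9.065869397,10.13172422,0.1275044725,0
0.04,4.862,4.000340042,4.335515,0.1349525111,0
0.05,2.613,2.08654793,2.21623403,0.1371997818,0
0.06,1.593,1.216495633,1.270923608,0.1371217501,0
0.08,0.763,0.5160838178,0.521055683,0.1341407362,0
0.1,0.4584,0.2675800491,0.2578405267,0.1299070441,0
0.15,0.2217,0.09012673966,0.06996826692,0.1191874701,0
0.2,0.1559,0.05051881564,0.02713296674,0.1100828601,0
0.3,0.1119,0.03294805563,0.007037592956,0.09636394288,0
0.4,0.09413,0.02949170684,0.002705310651,0.08658129437,0
0.5,0.08362,0.02833717582,0.00131749652,0.07917601739,0
0.6,0.07625,0.02769526167,0.000757441304,0.0733080456,0
0.8,0.06605,0.02669482493,0.0003560552986,0.06445495437,0
1,0.05901,0.02575151672,0.000243207988,0.05796954758,0
1.25,0.05261,0.02460142976,0.0001945663904,0.05184403927,5.878532586e-05
1.5,0.04803,0.02359582485,0.0001621386587,0.04712021453,0.0003904913184
2,0.04205,0.02220786833,0.000121603994,0.04020483344,0.001521768601
3,0.03599,0.02110415998,8.106932933e-05,0.03162227405,0.004196526155
4,0.03318,0.02105230576,6.0801997e-05,0.026371984,0.00669637567
5,0.03177,0.02144362171,4.86415976e-05,0.02277102586,0.008917737682
6,0.03108,0.02203788175,4.053466467e-05,0.02012375235,0.01089304887
8,0.03074,0.02343119244,3.04009985e-05,0.01645683757,0.01423999111
10,0.03103,0.0248519015,2.43207988e-05,0.01401245263,0.01698504451
15,0.03247,0.02795639785,1.621386587e-05,0.01036404972,0.02208609404
20,0.03408,0.03048883437,1.21603994e-05,0.008313380519,0.0257524084
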
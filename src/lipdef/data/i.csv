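# photon mass interaction coefficients (cm^2/g), element I; v1
# reconstructed from published NIST-style compilations; see docs/methods.md for provenance and accuracy
# duplicated energies mark absorption edges (first row = below edge, second = above)
energy_MeV,mu_rho,mu_en_rho,pe,incoh,pair
0.001,6081.63202,6073.207765,6073.207765,6.235442235e-47,0
0.0015,2212.314644,2203.890389,2203.890389,3.116618593e-26,0
0.002,1082.025854,1073.601599,1073.601599,1.443092736e-17,0
0.003,398.020715,389.5964598,389.5964598,2.992647665e-10,0
0.004,198.2119982,189.7877427,189.7877426,3.454980661e-07,0
0.004557,145.4242587,137,137,3.516638712e-06,0
0.004557,378.6784903,370.2542316,370.2542315,3.516638712e-06,0
0.005,300.6766399,292.2523706,292.2523705,1.419228077e-05,0
0.005188,274.4242787,266.0000002,266,2.347387835e-05,0
0.005188,593.3920577,584.9677792,584.967779,2.347387835e-05,0
0.006,409.2344441,400.8100578,400.8100562,0.0001326194613,0
0.008,198.1392004,189.7133747,189.7133505,0.001594622601,0
0.01,114.6319465,106.2019064,106.2017958,0.005895517455,0
0.015,44.32286975,37.00863315,37.00791235,0.02613534665,0
0.02,22.00404133,17.51850371,17.51676371,0.04826588451,0
0.03,8.355369006,6.108166773,6.104029138,0.07951034376,0
0.0332,6.587536218,1.713620428,4.69,0.08607938792,0
0.0332,36.09753622,12.46508832,34.2,0.08607938792,0
0.04,21.69044194,9.59608564,20.3,0.09626449552,0
0.05,12.31647851,6.567838279,11.35,0.1050553346,0
0.06,7.725245282,4.548109036,7,0.1095712761,0
0.08,3.672821548,2.369000347,3.2,0.1124071572,0
0.1,1.988538599,1.309296204,1.64,0.1116215846,0
0.15,0.7310346669,0.4625373164,0.516,0.1053948582,0
0.2,0.3806407848,0.2172062989,0.219,0.09852145452,0
0.3,0.1815250816,0.08447847926,0.0656,0.08712357009,0
0.4,0.1227571735,0.05057905694,0.0277,0.07861248658,0
0.5,0.09687837096,0.03819613126,0.0142,0.07205007646,0
0.6,0.08247293825,0.03250029473,0.00824,0.06680027775,0
0.8,0.06666208718,0.02756249657,0.00362,0.05882144894,0
1,0.05757278349,0.02516767561,0.00191,0.05294481674,0
1.25,0.05049125106,0.02354453832,0.00125,0.04737711439,0.0001153574973
1.5,0.04574491319,0.02237137409,0.0009,0.04307499533,0.0005508785445
2,0.0404151933,0.0212395742,0.00055,0.03676727053,0.002408708138
3,0.03597536985,0.02124435721,0.0003,0.02892781808,0.006439489963
4,0.03483364185,0.02253885817,0.000215,0.02412813588,0.01031667112
5,0.03502626775,0.02432014934,0.00017,0.02083504019,0.01390974385
6,0.03582348143,0.02626184942,0.00014,0.01841362251,0.01719232636
8,0.03801915393,0.03004934661,0.000105,0.01505904035,0.02281141582
10,0.04046020283,0.03356138477,8.4e-05,0.01282259585,0.02752560475
15,0.04587077451,0.04063370475,5.6e-05,0.009484266699,0.03631803914
20,0.05044279801,0.04616914399,4.2e-05,0.0076077661,0.04278601099
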
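# photon mass interaction coefficients (cm^2/g), element C; v1
# reconstructed from published NIST-style compilations; see docs/methods.md for provenance and accuracy
# duplicated energies mark absorption edges (first row = below edge, second = above)
energy_MeV,mu_rho,mu_en_rho,pe,incoh,pair
0.001,1650,1648.859277,1648.859277,4.986560177e-07,0
0.0015,540,538.8591003,538.8590998,0.0001776349722,0
0.002,245,243.8572087,243.8572007,0.002076767889,0
0.003,78,76.84284659,76.8427508,0.01652663619,0
0.004,33.9,32.96840938,32.96810697,0.03929740187,0
0.005,17.9,17.22074438,17.22015117,0.06192927373,0
0.006,10.7,10.1641453,10.1632146,0.08130913733,0
0.008,4.69,4.302704496,4.301043141,0.1097668299,0
0.01,2.373,2.057552227,2.055147897,0.1281377878,0
0.015,0.8071,0.5670593659,0.5628799829,0.1515382321,0
0.02,0.442,0.231683676,0.2258816255,0.160943053,0
0.03,0.2562,0.07245613841,0.06380857972,0.1661747271,0
0.04,0.2076,0.03788147006,0.0268160463,0.1654481985,0
0.05,0.1871,0.02730170027,0.01415704069,0.1628672669,0
0.06,0.1753,0.02346958616,0.008521985958,0.1596467036,0
0.08,0.161,0.02194856827,0.00404717555,0.1528355739,0
0.1,0.1514,0.02257930895,0.002384669361,0.1463344157,0
0.15,0.1347,0.02502049795,0.0009606662514,0.132516705,0
0.2,0.1229,0.02681163403,0.0004758877027,0.1217262573,0
0.3,0.1066,0.02882040279,0.0002194418696,0.106065258,0
0.4,0.09546,0.02961706808,0.0001673521326,0.09511364213,0
0.5,0.08715,0.0298061039,0.0001447709168,0.08688997058,0
0.6,0.08058,0.02964724641,9.866747134e-05,0.08040094636,0
0.8,0.07076,0.02894053481,7.155913448e-05,0.07064296057,0
1,0.06361,0.02801676526,6.875666338e-05,0.06351202576,0
1.25,0.0569,0.02678461488,5.500533071e-05,0.05678620939,4.002527834e-05
1.5,0.05179,0.0256139999,4.583777559e-05,0.0516040626,0.0001270417839
2,0.04442,0.02357724282,3.437833169e-05,0.04402301502,0.0003552388341
3,0.03562,0.0206518682,2.291888779e-05,0.03462032809,0.0009734671436
4,0.03047,0.01871637674,1.718916585e-05,0.02887050139,0.001580457595
5,0.02708,0.01736868996,1.375133268e-05,0.02492757999,0.002137482017
6,0.02469,0.01639573185,1.14594439e-05,0.02202916619,0.002648549566
8,0.02154,0.01509501478,8.594582923e-06,0.01801466075,0.003516280169
10,0.01959,0.01430223811,6.875666338e-06,0.01533871269,0.004244114135
15,0.01698,0.01330669617,4.583777559e-06,0.01134484507,0.005630438775
20,0.01575,0.01292202001,3.437833169e-06,0.009100062301,0.006646425358
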
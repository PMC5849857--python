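# photon mass interaction coefficients (cm^2/g), element O; v1
# reconstructed from published NIST-style compilations; see docs/methods.md for provenance and accuracy
# duplicated energies mark absorption edges (first row = below edge, second = above)
energy_MeV,mu_rho,mu_en_rho,pe,incoh,pair
0.001,4590.950717,4589.428265,4589.428265,1.855384384e-08,0
0.0015,1549.116172,1547.593689,1547.593689,2.962601406e-05,0
0.002,694.9512192,693.4281198,693.4281173,0.0006490903217,0
0.003,217.1362036,215.6050226,215.6049718,0.008779016973,0
0.004,93.15364875,91.60533113,91.60513054,0.02606542882,0
0.005,47.89258024,46.72184442,46.72140208,0.0461781518,0
0.006,27.69390167,26.79855552,26.79781087,0.06505480499,0
0.008,11.62738219,11.02272484,11.02128704,0.09499652097,0
0.01,5.951932533,5.490345919,5.488177191,0.1155814895,0
0.015,1.836381811,1.526177519,1.522224528,0.1433296027,0
0.02,0.865056066,0.6133939563,0.6077961095,0.1552786467,0
0.03,0.3779437465,0.1747631882,0.1662788661,0.1630379105,0
0.04,0.2585343896,0.07749165551,0.06655860472,0.1634689819,0
0.05,0.2132155447,0.04597799403,0.03294241445,0.1615157247,0
0.06,0.1907664542,0.03365718132,0.01880055789,0.1586750331,0
0.08,0.1678986124,0.02576679509,0.00793012868,0.1522829642,0
0.1,0.1551128258,0.02425483773,0.004106863824,0.1459962668,0
0.15,0.1360594975,0.0254024111,0.001362139499,0.132408972,0
0.2,0.123655766,0.02697552006,0.0006446513517,0.1217037125,0
0.3,0.1069316707,0.02884929268,0.0002384581167,0.1061018739,0
0.4,0.09561614476,0.029579034,0.0001126087974,0.09516760793,0
0.5,0.08728962123,0.02980542406,0.000123787368,0.08694944832,0
0.6,0.08069660604,0.02965488349,8.399458199e-05,0.08046165121,0
0.8,0.0708564129,0.02896318918,7.08564129e-05,0.07070011584,0
1,0.06371648228,0.02806644132,9.397759463e-05,0.0635676002,0
1.25,0.05697118882,0.02682589081,7.51820757e-05,0.05683758179,2.316411071e-05
1.5,0.05184948434,0.0256491295,6.265172975e-05,0.05165166756,0.000110617965
2,0.04460901931,0.02367468161,4.698879732e-05,0.04406450162,0.0004836753857
3,0.03598410838,0.02089016982,3.132586488e-05,0.03465353496,0.001293067741
4,0.03099699044,0.01910528045,2.349439866e-05,0.02889839611,0.002071616649
5,0.02776590099,0.01791053991,1.879551893e-05,0.02495175742,0.002793115784
6,0.02552006375,0.01708054526,1.566293244e-05,0.02205058156,0.003452267607
8,0.02262543596,0.01603823201,1.174719933e-05,0.01803221824,0.004580596615
10,0.0208908588,0.01546696471,9.397759463e-06,0.01535368224,0.005527219044
15,0.01865521283,0.01486531739,6.265172975e-06,0.01135593391,0.007292764659
20,0.01770535346,0.01477547834,4.698879732e-06,0.009108962733,0.008591551644
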
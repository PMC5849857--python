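"""Physical constants and element data used across the package."""

N_AVOGADRO = 6.02214076e23  # 1/mol
MEC2 = 0.51099895  # electron rest energy, MeV
R_E = 2.8179403262e-13  # classical electron radius, cm
SIGMA_THOMSON = 6.652458732e-25  # cm^2

# standard atomic masses, g/mol
ATOMIC_MASS = {
    "H": 1.008,
    "C": 12.011,
    "O": 15.999,
    "Cu": 63.546,
    "I": 126.90447,
    "W": 183.84,
}

ATOMIC_NUMBER = {"H": 1, "C": 6, "O": 8, "Cu": 29, "I": 53, "W": 74}

# iodine K-shell data: edge energy as printed in the bundled tables,
# fluorescence yield, K-line energies and the Kalpha share of K x rays,
# and the K-shell share of photoelectric events above the edge.
IODINE_K_EDGE = 0.0332  # MeV
IODINE_OMEGA_K = 0.882
IODINE_E_KALPHA = 0.0286  # MeV
IODINE_E_KBETA = 0.0323  # MeV
IODINE_P_KALPHA = 0.843
IODINE_K_SHARE = 0.82

DENSITY_WATER = 1.0  # g/cm^3
DENSITY_LIPIODOL = 1.28  # g/cm^3
DENSITY_CU = 8.96  # g/cm^3
DENSITY_W = 19.3  # g/cm^3

PAIR_THRESHOLD = 2.0 * MEC2  # MeV
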
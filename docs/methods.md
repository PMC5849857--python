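# Methods

`lipdef` is a desk-scale Monte Carlo pipeline for studying radiation dose
enhancement in iodinated Lipiodol embedded in water under megavoltage
photon beams, with and without a flattening filter.  This note documents
the physical models, the data they rest on, the numerical choices, and the
limits of what the synthetic study can show.

## Problem and geometry

Lipiodol (ethiodized poppyseed oil, 480 mg iodine per millilitre, bulk
density 1.28 g/cm³) is used as an embolic and contrast agent in
transarterial chemoembolization of liver tumours and often remains in the
tumour during subsequent stereotactic body radiotherapy.  Because iodine
(Z = 53) photo-absorbs low-energy photons far more strongly than water, a
Lipiodol-filled volume receives extra dose from the low-energy part of the
photon field — and flattening-filter-free (FFF) beams, which are softer
than flattened (FF) beams, enhance the effect.

The virtual phantom is a 20 × 20 × 20 cm³ water cube with 0.2 cm isotropic
voxels (100³; the 2 mm dose grid), optionally containing a 3 × 3 × 3 cm³
Lipiodol cube whose proximal face lies at 5.0 cm depth, centred on the
beam axis.  The lateral voxel grid is offset by half a voxel so that the
beam axis passes through a voxel-centre column and the Lipiodol faces lie
exactly on voxel boundaries (15³ = 3375 Lipiodol voxels).  A 5 × 5 cm²
field is delivered from a point source at SSD 90 cm.  Voxel intervals are
half-open `[low, high)`; a position exactly on a boundary belongs to the
voxel above it, so the layer `[6.4, 6.6)` cm contains the Lipiodol-centre
depth of 6.5 cm.

## Materials

Water is H₂O at 1.0 g/cm³ with mass fractions from standard atomic
masses.  Lipiodol carries the iodine mass fraction fixed by the printed
recipe, 0.480/1.28 = 0.375; the organic remainder is modelled as ethyl
linoleate (C₂₀H₃₆O₂), the dominant fatty-acid ethyl ester of poppyseed
oil, distributed by stoichiometry.  Photon coefficients of low-Z organics
differ negligibly between candidate esters at these energies, so this
choice affects results well below the percent level.  All compound
coefficients use the mass-fraction additivity (Bragg) rule.

## Interaction-coefficient tables

Per-element tables (H, C, O, Cu, I, W) of `mu_rho`, `mu_en_rho` and the
photoelectric, incoherent and pair components are bundled as CSV package
data on a standard energy grid (1 keV – 20 MeV) with duplicated abscissae
at absorption edges.  They are reconstructed from published
NIST-style compilations as follows (see `scripts/make_xsection_tables.py`):

* **total attenuation** — transcribed anchor values (oxygen derived from
  the water and hydrogen entries by additivity);
* **incoherent** — exact Klein–Nishina cross section per electron times
  Z/A·N_A with a parametric binding-suppression factor calibrated per
  element;
* **coherent** — a two-power-law parametric model with a Thomson-limit
  cap (kept inside `mu_rho` for attenuation, excluded from interaction
  branching);
* **photoelectric** — the residual of the total below the pair threshold;
  for iodine it is anchored explicitly with K-edge (33.2 keV, jump
  ≈ 5.5×) and L-edge structure;
* **pair** — the residual above 1.022 MeV (iodine: Z²/A scaling of the
  oxygen residual with a screening factor);
* **mass energy absorption** — computed from the components as
  `pe·f_pe + incoh·f_KN + pair·(E − 1.022)/E`, where `f_pe` accounts for
  the escape of K-fluorescence photons and `f_KN` is the Klein–Nishina
  energy-transfer fraction.  Radiative losses of secondary electrons are
  neglected (a few per cent above ~10 MeV).

Spot checks against standard reference values give agreement within ~1 %
at MeV energies and within a few per cent in the 30–150 keV region
(e.g. water `mu/rho` at 1 MeV: 0.0707 cm²/g; water `mu_en/rho` at 1 MeV:
0.0312 cm²/g; iodine total at 50 keV: 12.3 cm²/g).  Interpolation is
log–log linear; a query exactly at a duplicated edge energy resolves to
the above-edge value.

Electron CSDA ranges in water are bundled from published stopping-power
compilations (0.5 MeV → 0.177 g/cm²); ranges in other media are obtained
by scaling with the Z/A ratio of the mixture and dividing by density,
which is adequate at the ~10 % level needed here (0.5 MeV: 1.77 mm in
water, 1.52 mm in Lipiodol).

The photoelectric/Compton balance implied by these tables: the two
components of water are equal near 0.028 MeV, of Lipiodol (37.5 % iodine)
near 0.17 MeV, and of elemental iodine near 0.27 MeV.  The often-quoted
0.3 MeV boundary for iodinated media corresponds to the element-table
value for iodine itself, not to the 37.5 % mixture; `crossover_energy`
reports the mixture value, found by bisection on the mixture-weighted
components above the highest absorption edge.

## Surrogate beam model

Vendor phase-space files for the TrueBeam head are proprietary, so the
beam is parametric: a Schiff-like thin-target bremsstrahlung shape
`n(E) ∝ (E_max/E − 1)` with endpoint at the nominal potential (6 or
10 MeV), hardened by 2 mm of tungsten-equivalent inherent filtration; the
FF variant is additionally attenuated by a copper-equivalent flattening
filter (2.0 cm at 6 MV, 1.5 cm at 10 MV) computed from the bundled Cu/W
tables.  Resulting mean energies: 6 MV 1.44 (FFF) / 1.81 (FF) MeV; 10 MV
2.02 / 2.43 MeV.  The model reproduces the orderings that the analysis
depends on — FFF softer than FF with the surplus concentrated below
1.5 MeV, and 10 MV harder than 6 MV — but it is *not* a spectrum match to
any specific linac: it carries only ≈ 3.5 % of fluence below 0.3 MeV at
6 MV FFF, less than a clinical FFF beam, which depresses the absolute
dose-enhancement magnitudes (below).  The source is an ideal point source
aimed uniformly over the field square at the surface; there is no head
scatter, electron contamination or MU calibration — all results are per
source photon.

## Transport

Analog photon transport by Woodcock delta-tracking.  The majorant is
region-wise: the Lipiodol bounding box carries its own majorant so that
low-energy photons in the surrounding water are not drowned in virtual
collisions (with a global majorant, a 50 keV photon in water would suffer
~20 virtual collisions per real one).  Interactions considered:
photoelectric absorption, Klein–Nishina Compton scattering (Kahn's
rejection method, exact at all energies), and pair production
(charged-pair energy deposited locally, two isotropic back-to-back
511 keV annihilation photons transported).  Coherent scattering is not
transported; its attenuation share is retained in the total and
reassigned proportionally to the other channels at collisions, which
biases low-energy fluence down by a few per cent.  Photons falling below
the 0.01 MeV cutoff deposit locally.

Iodine K-shell photoelectric events (energy ≥ 33.2 keV, shell sampled
from the iodine share of the mixture photoelectric coefficient times the
K-shell fraction 0.82) emit one K x ray with probability ω_K = 0.882:
Kα (28.6 keV) with probability 0.843, otherwise Kβ (32.3 keV).  The
photoelectron carries E − 33.2 keV; the non-radiated remainder of the
binding energy is deposited locally, so energy balance is exact per
event.

**Electron handling.**  Secondary electrons are not tracked; their
kinetic energy is deposited in the voxel of creation (kerma
approximation).  This is justified by the electron ranges at play: a
500 keV electron travels ≈ 1.8 mm in water and less in Lipiodol — about
one 2 mm voxel.  An optional `csda_line` mode spreads each electron's
energy uniformly along a straight line of CSDA length for sensitivity
checks.  A consequence of the kerma approximation is that the depth-dose
curve has no buildup region (its maximum sits in the first layer); depth
ratios at 6.5 cm, where transient electron equilibrium holds, are
unaffected.  Electron spectra are tallied *at creation* (set-in-motion
spectra) since local deposition has no electron tracks.

**Tallies.**  In the 2 mm layer containing 6.5 cm depth, restricted to
the 3 × 3 cm² Lipiodol footprint: a track-length photon fluence spectrum
(exact segment–box chord lengths, independent of the majorant) and
set-in-motion electron spectra with per-channel counters.  Both are
recorded on 100 log-spaced bins from 0.01 to 20 MeV — the 50-bin linear
0–20 MeV convention is also recorded, but 0.4 MeV-wide bins cannot
resolve the 0.03–0.04 MeV structure, so the log binning is the analysis
default.

**Random numbers.**  A counter-based per-history PRNG (splitmix64-seeded
xorshift128+): the stream of history *i* depends only on the run seed and
*i*.  Runs are therefore bit-reproducible, independent of chunking, and —
because `run_paired` gives the with- and without-Lipiodol runs the same
seed, coefficient tables and majorant regions — paired histories stay
correlated until their paths first differ inside the Lipiodol box.  This
correlated sampling cancels common-mode noise in the DEF ratio (observed
standard deviation of the centre-depth DEF at 2 × 10⁶ histories drops
from ~1.5 to ~0.5 percentage points, and to ~0.02 for the hard 6 MV FF
beam).

**Energy conservation** is enforced: emitted = deposited + escaped to
better than 10⁻⁶ relative (observed ~10⁻¹⁴); a violation raises.

## Analysis definitions

* **PDD** — central-axis dose per layer (3 × 3 voxel column average)
  normalized to 100 % at its maximum.
* **DEF** — `100 × (D_with/D_without − 1)` per depth layer, doses averaged
  over the central 15 × 15 voxel footprint; the headline value is read at
  the layer containing 6.5 cm.
* **PEG** (probability of electron generation) — per bin with centre
  `E_i` and unit-sum photon abundance `n_i`:
  `PEG_PE,i = n_i · (mu_en/rho)(E_i) · p_pe(E_i)` and likewise for the
  Compton channel with `p_ce`; `PEG_Total = PEG_PE + PEG_CE`; all three
  curves jointly normalized so the total's maximum is 1.  The channel
  probabilities come from the interaction branching (coherent excluded).
  The verbal definition of the score admits a second reading in which
  the weight is the dimensionless ratio `mu_en/mu` instead of
  `mu_en/rho`; both variants are implemented (`variant="muen"` default,
  `"ratio"` optional) and satisfy the same qualitative properties
  (photoelectric dominance in Lipiodol, Compton dominance in water,
  K-edge-band maximum), so the ambiguity is recorded rather than
  resolved.  The photon *count* spectrum is used as the abundance.
* **band_fraction** — fraction of spectrum weight in `[lo, hi)`, with
  partial bins weighted by covered width.

## Study conditions and problem sizes

The acceptance study runs four beams (6/10 MV × FF/FFF), each as a
correlated with/without pair at 2 × 10⁷ histories (≈ 50 s per pair on one
CPU core; clinical-grade studies use orders of magnitude more histories
with full treatment-head models).  The test suite runs the same study once per
session plus engine checks at 10⁵–10⁶ samples.  At 2 × 10⁷ histories the
statistical uncertainty of the centre-depth DEF is ≲ 0.3 percentage
points for the paired estimator.

## What the synthetic study shows — and what it does not

With the surrogate beams the pipeline reproduces the *mechanisms* and
*orderings* of the dose-enhancement effect:

* the in-Lipiodol photon spectrum develops a K-fluorescence structure
  (Kα 28.6 keV, Kβ 32.3 keV) absent in the all-water run, with a local
  spectral peak in the 0.03–0.04 MeV band;
* the photoelectric PEG in Lipiodol peaks at the K-fluorescence bin
  (≈ 0.028 MeV, just below the 0.03–0.04 band that contains the Kβ line
  and the K edge), and photoelectric PEG dominates Compton PEG in
  Lipiodol while the reverse holds in water;
* DEF(FFF) > DEF(FF) at both energies; the FFF−FF gap is larger at 6 MV
  than at 10 MV; DEF ≈ 0 proximal to the Lipiodol; FFF beams set more
  0–0.3 MeV electrons in motion at the Lipiodol centre than FF beams.

The *absolute* DEF magnitudes at the Lipiodol centre come out at roughly
0.5–5 % across the four beams — substantially below values reported in the
clinical-beam literature (7–17 %).  The dominant cause is the surrogate
beam's low-energy content: centre-depth enhancement is driven by the
sub-0.3 MeV dose fraction, and the Schiff-plus-attenuator model delivers
several times less of it than a clinical FFF beam.  The engine itself is
consistent: the in-water fluence spectrum at depth has the expected
~15 % of fluence below 0.3 MeV, and a first-order estimate that reweights
the tallied water spectrum by the Lipiodol/water `mu_en` ratio predicts
the measured DEF once Lipiodol self-shielding is accounted for.
Absolute-DEF comparisons against clinical beams therefore require
substituting a measured or vendor-derived spectrum (the CSV spectrum
interface exists for exactly this purpose); the orderings above are
robust to the surrogate.

Other known limitations: no coherent transport (few-per-cent low-energy
fluence bias), no condensed-history electron transport (no buildup
region; interface dose gradients at the Lipiodol faces are smeared at
the 2 mm scale), no Doppler broadening or binding effects in Compton
sampling, no bremsstrahlung from secondaries, no positron transport
beyond instant annihilation, and reconstructed rather than transcribed
coefficient tables (few-per-cent accuracy; the iodine K-edge position,
jump ratio and fluorescence data are exact to the printed precision).
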
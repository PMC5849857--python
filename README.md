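# lipdef

Monte Carlo analysis of radiation **dose enhancement in iodinated
Lipiodol** under megavoltage photon beams, with and without a flattening
filter.

Lipiodol (ethiodized poppyseed oil, 480 mg iodine/mL, density
1.28 g/cm³) is injected during transarterial chemoembolization of liver
tumours and often remains in the tumour during subsequent stereotactic
body radiotherapy.  Iodine's K-edge at 33.2 keV makes the deposit a
strong photo-absorber of the low-energy part of a clinical photon field,
so the deposit receives extra dose — more so under
flattening-filter-free (FFF) beams, whose spectra are softer than
flattened (FF) ones.  `lipdef` is a self-contained, desk-scale pipeline
for studying this effect: it is aimed at medical physicists and students
who want a transparent, fully reproducible model of the mechanism rather
than a clinical dose engine.

The package provides:

* **analog Monte Carlo photon transport** (Woodcock delta-tracking,
  Klein–Nishina Compton sampling, iodine K-fluorescence, pair
  production, kerma-approximation electron deposition) through a
  voxelized 20 cm water phantom containing an optional 3 × 3 × 3 cm³
  Lipiodol cube at 5 cm depth;
* a **surrogate linac beam model**: Schiff-like bremsstrahlung spectra
  for nominal 6 and 10 MV in FF and FFF variants, delivered as a
  divergent 5 × 5 cm² field at SSD 90 cm;
* bundled per-element **photon interaction-coefficient tables**
  (H, C, O, Cu, I, W) with K-edge structure, and electron CSDA ranges;
* the derived statistics: percentage depth dose (PDD), the depth-resolved
  **dose enhancement factor**

  DEF(d) = 100 × [D_with(d) / D_without(d) − 1]  (%)

  averaged over the Lipiodol footprint, and the **PEG** spectral score
  ("probability of electron generation"), which weighs the photon
  spectrum n(E) by the energy-absorption coefficient and the
  per-channel interaction probability,

  PEG_PE(E) = n(E) · (μ_en/ρ)(E) · p_PE(E),  PEG_CE likewise,
  PEG_Total = PEG_PE + PEG_CE,

  decomposing the electron-production propensity into photoelectric and
  Compton channels.

See `docs/methods.md` for the models, their assumptions and limits.

## Worked example

Write a config and run the paired (with/without Lipiodol) simulation of
a 6 MV FFF beam:

```yaml
# run.yaml
beam:
  nominal_MV: 6
  filtered: false      # FFF
run:
  histories: 2000000
  seed: 42
output_dir: results/demo
```

```text
$ lipdef simulate --config run.yaml
INFO paired runs: 6MV-FFF, 2000000 histories, seed 42
INFO run with: conservation defect 9.68e-14
INFO run without: conservation defect 8.62e-14
wrote results to results/demo

$ lipdef analyze results/demo
DEF at 6.5 cm depth: 3.22 %
PEG_PE maximum (lipiodol): 0.0279 MeV
analysis products written to results/demo
```

The two `simulate` runs conserve energy to machine precision
(emitted = deposited + escaped).  `analyze` reports a **3.2 % dose
enhancement** at the centre of the Lipiodol cube (6.5 cm depth) for this
surrogate FFF beam — the flattened 6 MV beam gives ≈ 0.7 % under
identical conditions, reproducing the FFF > FF ordering — and finds the
photoelectric PEG maximal at **0.0279 MeV**, the iodine Kα fluorescence
line just below the K edge, identifying K-shell photo-absorption as the
driver of the enhancement.  Output CSVs (PDD, DEF vs depth, photon and
electron spectra at 6.5 cm, PEG curves) and a four-panel `report.png`
land in the results directory.

The physics-table layer can be queried directly:

```text
>>> from lipdef import (make_water, make_lipiodol, crossover_energy,
...                     kedge_energy, csda_range, ELEMENTS)
iodine K edge            : 33.2 keV
PE/Compton equality water: 28.0 keV
PE/Compton equality Lip. : 173.0 keV
CSDA range 0.5 MeV e-    : 1.77 mm (water), 1.52 mm (Lipiodol)
```

The photoelectric effect dominates Compton scattering below ~0.03 MeV in
water but up to ~0.17 MeV in Lipiodol (and ~0.27 MeV in elemental
iodine), which is why the soft part of an FFF spectrum is converted to
dose so much more efficiently inside the deposit.

`lipdef reproduce-study` runs all four beams (6/10 MV × FF/FFF) and
prints a summary table of centre-depth DEFs, the crossover energies, the
K edge, and the qualitative ordering checks.

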
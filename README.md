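# loopdyn

Analysis pipeline for the loop-opening dynamics of nDsbD, the N-terminal
domain of the *E. coli* oxidoreductase DsbD. The cap loop (residues
D68–G72) shields the active-site cysteines C103/C109; its dynamics differ
between the oxidized (disulfide-bonded) and reduced states of the domain.
`loopdyn` links molecular-dynamics trajectory features of this loop to the
NMR observables that report on it, with a synthetic-data generator that
reproduces every input with known ground truth so all stages are testable
without simulations or spectra.

The package is written for structural-biology / biomolecular-NMR
practitioners who want a tested, reusable implementation of:

* **Trajectory features** — the F70 ring-centre to C109 Sγ distance,
  loop-opening event detection with hysteresis (open ≥ 10 Å, close < 6 Å,
  duration ≥ 1 ns), χ1 rotamer classification (gauche−/gauche+/trans) and
  populations, Shrake–Rupley SASA, hydrogen-bond occupancy, side-chain
  RMSD, mass-density occupancy grids, and φ/ψ series.
* **S² order parameters from ensembles** — the Lipari–Szabo estimator
  S² = (3/2) Σ_{αβ} ⟨μ̂_α μ̂_β⟩² − 1/2 over 5-ns blocks after removing
  overall tumbling, with bootstrap errors over blocks.
* **RDC back-calculation** — D = κ/R³ (A_x cos²θ₁ + A_y cos²θ₂ +
  A_z cos²θ₃) with κ = −(3/8π²) γ_I γ_S μ₀ ħ and R = 1.04 Å; alignment
  tensor by five-parameter Saupe least squares; agreement scored by
  Q = rms(D_calc − D_obs)/rms(D_obs).
* **Model-free analysis** — axially symmetric spectral densities
  (D∥/D⊥ = 2.0), dipolar + CSA relaxation rates (r_NH = 1.02 Å,
  Δσ = −160 ppm), model hierarchy {S²}, {S², τe}, {S², Rex}, {S², τe, Rex},
  {S²f, S²s, τs} with staged selection and Monte Carlo errors.
* **CPMG relaxation dispersion** — numerical two-state Bloch–McConnell
  propagation of in-phase ¹⁵N magnetization, global fits sharing pB and
  kex across residues and fields, multi-temperature fits constrained by
  Eyring transition-state theory and van't Hoff populations, and Δω sign
  determination from HSQC/HMQC peak positions.
* **Conservation scoring** — per-position residue-class percentages of a
  multiple sequence alignment in reference numbering.

## Worked example

```python
import numpy as np
from loopdyn.synthetic import ExchangeTruth, gen_dispersion_dataset
from loopdyn.dispersion import fit_global_two_state

truth = ExchangeTruth(pB=0.02, kex=1500.0,
                      dw={65: 2.5, 69: 3.0, 70: 1.8, 71: 2.2})
data = gen_dispersion_dataset(truth, fields=[500.0, 750.0],
                              noise_frac=0.02, seed=1)
model = fit_global_two_state(data, n_mc=20, seed=2)
print(f"pB = {100*model.pB:.2f}% +/- {100*model.errors['pB']:.2f}%")
print(f"kex = {model.kex:.0f} +/- {model.errors['kex']:.0f} s^-1")
```

prints

```
pB = 1.91% +/- 0.20%
kex = 1484 +/- 96 s^-1
```

i.e. the global two-state fit of 13-point dispersion curves (50–850 Hz,
two fields, 2% noise) recovers the planted 2% minor-state population and
exchange rate of 1500 s⁻¹ within the Monte Carlo uncertainty — the same
design used to characterise the cap-loop minor state of oxidized nDsbD.

The full pipeline can also be driven from the command line:

```bash
loopdyn simulate --outdir run --seed 11
loopdyn features --topology run/loop_trajectory.pdb --outdir run
loopdyn conserve --alignment run/alignment.fasta --reference ref --outdir run
loopdyn report --outdir run
```

or from a YAML config with `loopdyn run config.yaml`, which writes a
manifest with per-stage seeds and output hashes.

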
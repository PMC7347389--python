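# Methods

This note documents the models implemented in `loopdyn`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter.

## Order parameters from ensembles

Bond-vector series are obtained by least-squares superposition of every
frame on a reference structure (removing overall tumbling) followed by
normalisation of the N→H vectors. The generalized order parameter uses the
ensemble estimator

    S² = (3/2) Σ_{α,β} ⟨μ̂_α μ̂_β⟩² − ½,

evaluated in consecutive 5-ns blocks; the reported per-residue value is the
mean over blocks and the error is the standard deviation of that mean under
bootstrap resampling of blocks (sampling with replacement, seeded). The
estimator is validated against the diffusion-in-a-cone closed form
S = cos θ₀ (1 + cos θ₀)/2 at several cone half-angles: uniform-in-cone unit
vectors have ⟨P₂(cos θ)⟩ equal to that expression, so S² converges to its
square as the frame count grows. A single block yields an undefined (NaN)
error rather than zero. Block boundaries are taken on the time axis using
the sampling extent (n·dt), so a 1000-frame, 0.025-ns/frame series contains
exactly five 5-ns blocks.

## RDC back-calculation and the alignment tensor

Couplings follow D = κ/R³ (A_x cos²θ₁ + A_y cos²θ₂ + A_z cos²θ₃) with
κ = −(3/8π²) γ_I γ_S μ₀ ħ from CODATA constants (negative prefactor for the
one-bond ¹⁵N–¹H pair; output in Hz) and a uniform effective bond length
R = 1.04 Å. The alignment tensor is fit by linear least squares in the five
independent elements of the traceless symmetric Saupe matrix, solved by
SVD; the condition number of the design matrix is reported and
rank-deficient geometries (fewer than five independent bond orientations)
raise an error. Principal components are ordered |A_z| ≥ |A_y| ≥ |A_x|.
Ensemble back-calculation averages D over frames against a single fixed
tensor — appropriate when the overall fold is stable, which is the use case
here. Q = rms(D_calc − D_obs)/rms(D_obs); it is scale-covariant and equals
the relative noise level for uncorrelated Gaussian errors.

## Model-free analysis

The spectral density is the three-component axially symmetric form: with
the N–H vector at angle α to the unique diffusion axis, amplitudes
(3cos²α−1)²/4, 3cos²α sin²α, (3/4)sin⁴α attach to correlation times
1/(6D⊥), 1/(5D⊥+D∥), 1/(2D⊥+4D∥); Lipari–Szabo internal motion contributes
(1−S²) terms with 1/τ' = 1/τ_k + 1/τ_e. With D∥/D⊥ = 1 this reduces to the
isotropic J(ω) = (2/5)[S² τ_m/(1+ω²τ_m²) + …]. τ_m is a required input
(7 ns in the synthetic tests, a typical value for a ~14 kDa domain at
25 °C); D∥/D⊥ defaults to 2.0 and the diffusion tensor is fixed, not
co-fit. Rates use the standard dipolar + CSA expressions at the five
canonical frequencies with r_NH = 1.02 Å and Δσ = −160 ppm. The CSA axis is
taken 17° away from the N–H bond (configurable); its contribution is scaled
by P₂(cos 17°)², a common simplification of the non-colinearity correction.

Models 1–5 are fit by bounded least squares (tolerances 1e-12) with
multi-start over a log grid of internal correlation times (1 ps – 3 ns).
Model selection is staged: model 1 is accepted if its χ² passes a
goodness-of-fit test at α = 0.05; otherwise models 2/3 are screened by
F-test against model 1 and the better adequate one is chosen; models 4/5
are used only when no simpler model is adequate. Critical values default to
the analytic χ²/F distributions; this keeps repeated recovery experiments
cheap and behaves indistinguishably from simulation-calibrated cutoffs at
the data sizes used here. Monte Carlo errors are parameter standard
deviations over (by default 500, configurable) refits of noise-perturbed
back-calculated data, started from the fitted parameters.

T₁/T₂ extraction fits I(t) = I₀ e^(−t/T) with errors from Monte Carlo
replicates at the baseline-noise level; the NOE is the saturated /
unsaturated peak-height ratio with propagated errors (validated against
resampling).

## CPMG relaxation dispersion

The forward model propagates in-phase ¹⁵N transverse magnetization of a
two-state system through the CPMG train: complex 2×2 Bloch–McConnell
evolution for τ, an ideal 180° pulse (complex conjugation), evolution for
τ, repeated for an even echo count; ν_CPMG = n_echo/(2 T_rel), and
requested frequencies incompatible with an even integer count are moved to
the nearest valid value and logged. Matrix exponentials/powers use closed
2×2 eigen-forms, vectorised over the frequency grid.

Two readouts are provided. The default mirrors the experiment: R2eff =
−ln(|M_A(T_rel)|/p_A)/T_rel from the end-point major-state magnetization
starting at equilibrium populations. The "rate" readout returns the
slowest decay rate of the echo-pair propagator (dominant eigenvalue). The
Carver–Richards closed form describes the latter quantity; the numerical
rate readout agrees with it to machine precision over wide parameter
ranges, and the Luz–Meiboom fast-exchange form is matched within 1% where
it applies. The end-point readout differs from Carver–Richards by an
amplitude transient that grows with p_B and is largest at the lowest
refocusing frequencies (up to a few per cent of R2eff at p_B ≈ 5%,
T_rel = 40 ms); this is a property of the observable, not a numerical
error, and both generator and fitter use the same readout so fits are
internally consistent. Scalar-coupling/multiplet effects during the train
are neglected (in-phase approximation) — a known limitation relative to
full anti-TROSY/TROSY treatments.

Global single-temperature fits share p_B and k_ex across residues and
fields with per-residue |Δω| (ppm) and per-curve R2,0, weighted by the
R2eff errors, multi-started over a log grid of k_ex (10²–10⁵ s⁻¹) and p_B.
A no-exchange model (per-curve weighted means) is always compared; the
exchange model is kept only when its χ² improvement exceeds an AIC-style
penalty of two per extra parameter, so flat data returns p_B = 0. Errors
are Monte Carlo over replicate refits.

Multi-temperature fits parameterise populations by ΔG(T) = ΔH − TΔS, the
forward rate by Eyring k(T) = (k_B T/h) exp(−(ΔH‡ − TΔS‡)/RT), and let each
residue's Δω drift linearly about 25 °C (slope in ppb/K). The barrier
enthalpy is allowed slightly negative so a planted zero barrier is not
biased by a bound. With a single temperature the parameterization
degenerates gracefully to the single-temperature fit (with a conditioning
warning). Shift slopes of a few ppb/K move Δω by only ~0.05 ppm across a
25 K span, so their uncertainties are intrinsically large at 2% noise; the
recovery tests therefore check consistency within errors, not precision.

Sign determination of Δω compares pooled ¹⁵N peak positions between
single-quantum (HSQC) and multiple-quantum (HMQC) spectra: the exchange
shift of the major-state peak differs between SQ and the ZQ/DQ average,
and sign(δ_HSQC − δ_HMQC) = sign(Δω) for |Δω_N| below √3·k_ex. Differences
smaller than a threshold times the pooled replicate standard error return
"undetermined".

## Trajectory features

The loop-state coordinate is the distance from the unweighted centroid of
the six aromatic ring carbons (CG, CD1, CD2, CE1, CE2, CZ) to a target
atom (C109 Sγ). Event detection is a hysteresis state machine: open at the
first frame ≥ 10 Å, close at the first subsequent frame < 6 Å, discard
events shorter than 1 ns. Hysteresis avoids chatter in the partially-open
6–10 Å band; event boundaries are frame times (no sub-frame interpolation)
and events separated by brief closures are not merged (configurable
thresholds). χ1 wells are gauche− [−120°, 0°), gauche+ [0°, 120°), trans
elsewhere — the canonical −60°/+60°/180° well centres with boundaries at
the midpoints. The hydrogen-bond criterion is donor–acceptor ≤ 3.5 Å and
D–H…A ≥ 150°, best acceptor per frame, with a logged distance-only
fallback when hydrogens are absent. SASA is an own Shrake–Rupley
implementation (Bondi radii, 1.4 Å probe, 960 golden-spiral points per
atom; quadrature error < 1% on spheres, < 2% on overlapping pairs).
Side-chain RMSD superposes each frame on a core selection before measuring
the residue's side-chain heavy atoms, optionally conditioned on a
loop-state mask. Occupancy grids count atom visits per 0.5 Å voxel and
report max-normalised relative occupancy for iso-level thresholding.

## Conservation

Alignment columns are mapped to reference numbering by skipping reference
gaps (a bijection onto ungapped reference positions). Percentages default
to counting gaps in the denominator (percent of all sequences); the
alternative non-gap denominator is available since either convention is
defensible. Matching is case-insensitive; non-standard codes count as
their own class.

## Synthetic data: what it emulates and what it does not

The generator produces (i) cone-model bond vectors with known analytic S²
(solid-angle-uniform in the cone, optionally with an exponential memory
whose stationary distribution is unchanged); (ii) a minimal 5-residue
scaffold — carboxyl acceptor, amide donor/H, a PHE-like residue with chi1
atoms and a 6-membered ring, a CYS-like Sγ target — whose ring-centre
distance, χ1 states and hydrogen bond follow planted schedules exactly,
plus Gaussian coordinate jitter (σ = 0.2 Å by default, small against the
6/10 Å thresholds); fractional schedules are realised as exact counts by
largest-remainder rounding; (iii) relaxation tables forward-computed from
known model-free parameters with relative Gaussian noise (error columns
floored at 10⁻⁶ relative so they stay positive for noiseless data);
(iv) dispersion tables from the two-state forward model with
Eyring/van't Hoff-consistent temperature dependence (ΔS and ΔS‡ derived so
the 25 °C p_B and k_ex are reproduced exactly) and linear shift drift;
(v) toy alignments with exact planted column compositions. Study-like
defaults: p_B = 2%, k_ex = 1500 s⁻¹ at 25 °C, Δω 0.8–3 ppm, ΔH = −20
kJ/mol (minor state enthalpically favourable), ΔH‡ = 0, slope 2 ppb/K,
13 ν_CPMG points between 50 and 850 Hz at 500/750 MHz, T_rel = 40 ms,
five temperatures (10, 15, 20, 25, 35 °C; two fields at 15/25 °C), 2%
noise, τ_m = 7 ns, S² ≈ 0.8 with τ_e ≈ 100 ps for flexible-loop residues,
86%/14% gauche−/trans rotamer preference.

None of this is molecular mechanics: there is no force field, no water,
no thermostat, and the toy scaffold's geometry is schematic. Passing tests
therefore demonstrate that the *analysis* recovers planted truth under the
assumed error model (independent Gaussian noise), not that the error model
describes any particular spectrometer or that the features capture real
protein energetics. Coordinate jitter produces a small systematic
misclassification of χ1 states near well boundaries (planted 86% gauche−
measures ~84–86% at σ = 0.2 Å), which is the expected behaviour of a hard
classification under noise.

## Problem sizes and determinism

Every stochastic routine takes a seed; fixed seeds give bit-identical
outputs, and the pipeline derives per-stage seeds from a master seed by
stable hashing. Recovery experiments use desk-scale replicate counts
chosen as a compromise between statistical resolution and runtime: 10⁶
frames per cone angle for the S² oracle; 50–100 replicates with 50 Monte
Carlo refits each for model-free recovery; 15–20 replicates for global
dispersion recovery (reduced multi-start after verifying the full grid
lands in the same optimum); 10 Monte Carlo refits for the
multi-temperature fit. The crystal-structure comparisons (Cα RMSD of
1L6P/1JPE/3PFU and 5NHI) run only when the deposited PDB files are
provided under `data/pdb/`, since the package ships no third-party data.
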
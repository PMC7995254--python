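# Methods

## Scope and model

`exciton2des` implements the computational chain used to characterize small,
strongly coupled chlorophyll assemblies — the water-soluble chlorophyll
protein (WSCP) tetramer and systems like it — with two-dimensional electronic
spectroscopy (2DES):

1. **Excitonics.** Each pigment is a two-level site with transition energy
   `E_i` (cm⁻¹) and a Qy transition dipole `μ_i û_i` (Debye) located at its
   central Mg atom. Pairwise couplings are point-dipole couplings

       V = C κ μ_a μ_b / R³,   κ = û_a·û_b − 3(û_a·R̂)(û_b·R̂),

   with `C = 5034.1 cm⁻¹·Å³·D⁻²` (vacuum; an optional multiplicative
   screening factor is accepted but defaults to 1, because typical WSCP-scale
   couplings of ~100 cm⁻¹ at ~10 Å with μ ≈ 4.6 D arise without screening).
   The N×N Frenkel Hamiltonian (site energies on the diagonal, couplings off
   it) is diagonalized with `numpy.linalg.eigh`; exciton dipoles are the
   eigenvector-weighted sums of site dipole vectors and obey the
   dipole-strength sum rule exactly. For a degenerate dimer the exciton
   splitting is 2|V|, the quantity the DAS analysis compares against.

2. **Forward 2DES simulation.** An absorptive 2DES signal S(ω₁, ω₃; t₂) is
   synthesized as a sum of 2D Gaussian peaks (principal axes along the
   diagonal/antidiagonal) whose amplitudes follow named kinetic channels:
   first-order populations solving `dp/dt = K p` (matrix exponential), and
   overdamped coherence channels `a·exp(−t₂/τ_deph)`. Peak amplitudes are
   additionally weighted by a Gaussian laser spectrum evaluated at both ω₁
   and ω₃. Gaussian i.i.d. noise is added with σ defined as a fraction of
   the global noiseless maximum. Ground-state bleach / stimulated emission
   is positive.

3. **Global lifetime analysis.** Every pixel trace is fit by a shared sum of
   exponentials; the amplitude maps are the 2D decay-associated spectra
   (2D-DAS; positive = decaying, negative = rising). The fit is a variable
   projection: amplitudes are the exact per-pixel linear least-squares
   solution at any trial time constants, and a bounded trust-region search
   over log τ minimizes the pooled SSR.

4. **DAS interpretation.** Extrema of a DAS map are located (after a light
   Gaussian smoothing) and classified as diagonal / cross peaks; a positive
   diagonal + negative below-diagonal pair sharing an excitation column in a
   fast DAS estimates the relaxation gap; distinct diagonal extrema of the
   fastest DAS count the exciton states; and an observed/calculated gap
   ratio converts into an effective dipole via
   `μ_eff = μ_ref √(gap_obs/gap_calc)` (V ∝ μ² at fixed geometry).

## Design decisions that were genuinely open

* **Qy direction convention.** The unit vector from ring nitrogen NB to ND,
  a widely used convention for chlorophylls; the atom pair and the center
  atom (Mg) are configurable because conventions differ between studies.
  Under a different convention the absolute couplings can shift by a few
  cm⁻¹.
* **Degenerate site energies** within a complex by default (the 2V gap
  formula presumes degeneracy); per-site offsets are accepted through the
  `Chromophore` fields.
* **Frequency-domain forward model.** The generator produces Gaussian peaks
  with exponential amplitude traces rather than simulating third-order
  response functions. This keeps the forward model exactly inside the class
  the global fit assumes, so parameter-recovery tests measure the analysis
  chain, not lineshape-model mismatch. Consequences for realism are listed
  under *Limitations*.
* **Coherence channels are non-oscillatory.** The ~10 fs components are
  modelled as overdamped exponentials, matching how they appear in a
  multiexponential analysis; no damped cosines are fitted or generated.
* **Model-size choice by AIC.** The selection scan reports pooled AIC and
  BIC per k, with the parameter count k + k·(number of pixels), and chooses
  the k minimizing AIC. BIC's ln(n) penalty per amplitude over-penalizes
  the profiled linear amplitudes of variable projection: a weak but real
  component confined to a few peak regions (the 10 fs coherence channel at
  0.5 % noise reduces the pooled SSR by ~4 %, overwhelming by
  likelihood-ratio standards) cannot overcome a BIC penalty of
  npix·ln(n) ≈ 4×10⁵ on these grids, while AIC detects it with a ~2.5×
  margin and still rejects a fourth, spurious component (whose expected SSR
  gain, ~npix·σ², is half the AIC threshold).

## Numerical choices

* **SVD compression of the outer search.** The profiled SSR depends on the
  data matrix B (n_times × n_pixels) only through ‖(I−P_A)B‖²_F, which is
  invariant under right-multiplication by an orthogonal matrix. The outer τ
  search therefore runs on U·s from the thin SVD of B (at most
  n_times × n_times) and the full amplitude maps are solved once at the
  optimum — identical optimum, orders of magnitude faster when
  n_pixels ≫ n_times. Permutation of pixels is invariant up to
  floating-point reordering (~1e-9 relative).
* **log-τ parameterization** enforces positivity; bounds default to
  [1 fs, 100 ps]; a fitted τ within 1e-8 (log) of a bound sets a warning
  flag.
* **Multi-start:** 5 starts over fixed log-spaced windows spanning
  5 fs–5 ps (plus deterministic seeded jitter if more starts are requested);
  best pooled SSR wins, ties broken by the smallest fast τ. `tau_initial`,
  when given, replaces the first start.
* **Early-time mask:** t₂ < 15 fs is excluded by default (pulse-overlap
  region in measured data); the mask is a retained-point filter, not a
  truncation of the container.
* **Ill-conditioning:** `solve_amplitudes` rejects exponential bases with
  condition number above 1e8 and names the offending τ pair. Inside the
  outer search, `lstsq` handles transient near-degeneracy gracefully.
* **Eigenvector sign convention:** first nonzero component positive, so
  reruns and platforms agree bit-for-bit.
* **Degenerate inputs:** duplicate chromophore labels, non-symmetric
  Hamiltonians, non-unit Qy vectors, coincident centers, empty pigment
  selections, rate matrices with positive column sums, non-increasing
  axes, and schema violations of the on-disk container all raise typed
  errors naming the offending item; center–center distances below 2 Å set a
  point-dipole-invalid flag with a warning.

## The bundled recipes (what the generator emulates)

Four recipes named Lv-a, Lv-b, Bo-a, Bo-b emulate the two Chl a and two
Chl b WSCP complexes at 77 K:

| parameter | value | notes |
|---|---|---|
| t₂ grid | 0–1000 fs, step 7.5 fs | population-time scan |
| laser | center 15 380 cm⁻¹, FWHM 1839 cm⁻¹ | 8 fs transform-limited pulse (Δν̃ = 0.441/(Δt·c)) |
| frequency grids | 10 cm⁻¹ step, peaks ±350 cm⁻¹ | per complex |
| exciton states | Lv-a: 14 850/15 070; Bo-a: 14 600/14 830; Lv-b: 14 660/15 050/15 400/15 660; Bo-b: 14 620/14 900/15 300/15 650 cm⁻¹ | Chl a: two states 220–230 cm⁻¹ apart; Chl b: four states |
| downhill relaxation | 100 fs | upper exciton(s) feed below-diagonal cross peaks |
| slow drain | 2000 fs | ">1 ps" component, poorly determined inside the 1 ps window |
| coherence dephasing | 10 fs (Chl b recipes only) | amplitude 0.8/0.6 of the population peaks at diagonal/cross positions |
| noise σ | 1 % (Chl a), 0.5 % (Chl b) of the global max | i.i.d. Gaussian, seeded |

Linewidths (FWHM diag/antidiag 150–180/90–110 cm⁻¹) make the Lv complexes
slightly broader than Bo, and keep the four Chl b states resolvable at
their ≥260 cm⁻¹ separations. The kinetic schemes are built so that every
noiseless trace is exactly a sum of exponentials with rates {1/10, 1/100,
1/2000} fs⁻¹ (Chl b) or {1/100, 1/2000} fs⁻¹ (Chl a); recovered time
constants can therefore be compared against exact ground truth.

**What passing tests do and do not show.** Because the generator sits inside
the fitted model class, recovery tests validate the estimator, the
variable-projection implementation, model-size selection and the DAS
reading. They do not probe lineshape-model mismatch in real data: finite
pulse overlap, rephasing/non-rephasing weighting, vibronic progressions,
oscillatory coherences, solvent/phonon spectral diffusion (center-line
dynamics), scatter, or phasing errors. Real 2D-DAS also superimpose
excited-state absorption of opposite sign, which the generator omits.

## Problem sizes

The bundled full-scale datasets are 134 maps of ~90–175 px per axis
(1.1–4.0×10⁶ fitted points); a full generate + 2-component fit runs in
well under a minute, and the k = 1..4 selection scan on Bo-b in a few
seconds thanks to the SVD compression. Unit tests use the same recipes on
coarser (30–40 cm⁻¹) frequency grids, which leaves the kinetics and peak
pattern unchanged.

## Limitations

* Point-dipole couplings only; no transition charges/TrEsp, no CD
  rotational strengths, no vibronic structure in the stick spectra.
* Site energies are free parameters; the package does not model their
  structural origin.
* No target (compartmental) analysis: DAS are descriptive, the rate matrix
  is not fitted directly.
* No bootstrap error bars on τ; the noise-robustness property test
  (median/IQR of recovered τ over seeds) stands in for them.
* The effective-dipole inference reports the closed-form rescaling only; it
  deliberately does not pick which observed splitting to feed it.
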
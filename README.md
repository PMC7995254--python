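# exciton2des

Frenkel-exciton modelling of chlorophyll dimers/tetramers and global
lifetime analysis of two-dimensional electronic spectroscopy (2DES)
datasets, built around the water-soluble chlorophyll protein (WSCP) — a
tetramer binding four chlorophylls as two "open-sandwich" dimers — and
aimed at spectroscopists who want a tested, reusable version of the
analysis chain:

    geometry ──► couplings & exciton states
    recipe   ──► synthetic 2DES dataset ──► global fit (2D-DAS) ──► gaps,
                                                      states, effective dipoles

**The model.** Each chlorophyll is a site with Qy transition energy
`E_i` (cm⁻¹) and transition dipole `μ_i û_i` (Debye, direction NB→ND,
origin at Mg). Pairs couple through the point-dipole interaction
`V = C κ μ_a μ_b / R³` with `κ = û_a·û_b − 3(û_a·R̂)(û_b·R̂)` and
`C = 5034.1 cm⁻¹·Å³·D⁻²`; diagonalizing the site Hamiltonian gives exciton
energies and dipoles, with a degenerate-dimer splitting of `ΔE = 2V`.
2DES signal stacks S(ω₁, ω₃; t₂) are fitted globally as
`Σ_i A_i(ω₁, ω₃)·exp(−t₂/τ_i)` by variable projection (amplitudes solved
exactly per pixel, shared τ optimized on a log scale); the amplitude maps
`A_i` are 2D decay-associated spectra (2D-DAS): positive = decaying,
negative = rising. DAS coordinates then yield relaxation gaps, exciton
state counts, and — through `μ_eff = μ_ref √(gap_obs/gap_calc)` — an
effective in-protein transition dipole. See `docs/methods.md` for the full
account.

## Worked example

```python
from exciton2des import (Chromophore, build_hamiltonian, diagonalize,
                         exciton_gap, point_dipole_coupling)

a = Chromophore("chl1", [0, 0, 0], [0, 0, 1], 4.58, 15000.0)   # Chl a, Debye / cm^-1
b = Chromophore("chl2", [10, 0, 0], [0, 0, 1], 4.58, 15000.0)  # 10 A away, parallel
t = point_dipole_coupling(a, b)
print(f"V = {t.V:.1f} cm^-1, kappa = {t.kappa:.1f}, R = {t.distance_R:.1f} A")
m = diagonalize(build_hamiltonian([a, b]))
print(f"gap = {exciton_gap(m, 0, 1):.1f} cm^-1")
```

prints

```
V = 105.6 cm^-1, kappa = 1.0, R = 10.0 A
gap = 211.2 cm^-1
```

two parallel side-by-side dipoles (κ = 1) couple at 105.6 cm⁻¹, and the
degenerate dimer splits by exactly 2V.

The full pipeline — simulate one of the four bundled WSCP recipes, fit it
globally, and read the DAS — runs from the shell:

```sh
exciton2des run --complex Bo-b -o demo_bob --seed 1
cat demo_bob/analysis.json
```

```json
{
 "chosen_k": 3,
 "taus_fs": [10.04, 100.02, 2005.08],
 "n_states": 4,
 "state_energies_cm1": [14630.0, 14900.0, 15290.0, 15650.0],
 ...
}
```

(values abridged): model selection finds the three shared time constants of
the Chl b complex — the 10 fs overdamped coherence dephasing, the 100 fs
downhill exciton relaxation, and the slow (>1 ps) drain — and the fastest
DAS pinpoints four exciton states, each within one or two grid steps of the
recipe's ground-truth energies. Running `--complex Lv-a` instead gives
`chosen_k = 2`, τ ≈ 100 fs / 2000 fs and `relaxation_gap_cm1 = 220.0`, the
emission-frequency distance between the positive diagonal and negative
below-diagonal extrema of the fast DAS.

Other subcommands: `exciton2des couplings structure.pdb` (point-dipole
coupling table and exciton states from a PDB/mmCIF file),
`simulate` / `fit` / `analyze` for the individual stages, and
`exciton2des config --init pipeline.ini` for a commented configuration
file. The library surface mirrors the CLI; the global fitter is a
scikit-learn estimator (`GlobalExponentialFitter`) usable in sklearn
pipelines.

## Layout

```
src/exciton2des/
  excitonics.py   couplings, Hamiltonians, exciton states, structure parsing
  synthetic.py    forward 2DES simulation and the four bundled recipes
  globalfit.py    variable-projection global fitting (2D-DAS)
  dasanalysis.py  DAS extrema, gaps, state counts, effective dipoles
  io.py, cli.py   text dataset container, pipeline, command line
tests/            pytest suite (tests/test_acceptance.py holds the
                  end-to-end scientific checks)
```
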
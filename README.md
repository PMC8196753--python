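# physcluster

Physical-cluster-theory machinery for the gas-phase association equilibria

```
n W + X  <=>  W_nX
```

of an anion X (F⁻, Cl⁻, Br⁻, I⁻, or a configurable toy species) with rigid
ligands W (a rigid 3-site water by default), aimed at people studying ion
hydration through quasi-chemical theory: the free energies of small
hydration clusters are the building blocks from which inner-shell solvation
models are assembled, and the hard part is getting equilibrium constants
that remain honest when the underlying energy landscape is rough (many
shallow minima, floppy librations, split solvation shells).

Everything runs on a classical surrogate potential (fixed point charges +
Lennard-Jones, rigid ligands) so that every estimate can be validated
against brute-force configurational integrals — something that is
impossible on a quantum-chemical surface. The surrogate is qualitative by
design: it reproduces the H-bond-donation motif and surface-hydration
structures of halide–water clusters at trivial cost, with no claim of
quantitative fidelity to any electronic-structure method.

## The three routes to K_n

With the orientation measure normalised to one, the ideal-gas equilibrium
constant is the clustered-configuration integral

```
K_n = (1/n!) ∫_clustered  ∏ᵢ d³rᵢ ⟨dΩᵢ⟩  e^(−βU(W_nX)),        [Å^{3n}]
```

made dimensionless by the standard-state density ρ₀ (1 atm ideal gas by
default), reported as −RT ln(K_n ρ₀ⁿ).

1. **Harmonic (RRHO)** (`physcluster.rrho`): multi-start local minimisation
   from sampled frames, numerical Hessians in rigid-body coordinates,
   normal modes, and rigid-rotor harmonic-oscillator partition functions
   (quantum or classical vibrational statistics; the ligand-permutation n!
   applied explicitly).
2. **Rough-landscape step-wise chain** (`physcluster.roughscape`): for each
   sampled W_nX frame the decoupling energy of a distinguished ligand,

   ```
   ΔU_n = U(W_nX) − U(W_{n−1}X) − U(WX) + U(X),
   ```

   is evaluated on the frozen geometry; the thermal average of e^(βΔU_n)
   over the canonical stream gives the step factor, and

   ```
   K_n = K_1 · K_{n−1} / ( n · ⟨e^(βΔU_n)⟩_n )
   ```

   chains upward from an anchored K_1 (quadrature oracle by default, an
   experimental value if you have one). ΔU_n measures the crowding of the
   n-th ligand; it vanishes identically for n = 1 and in the ideal-ligand
   limit, where the chain collapses to K_n = K_1ⁿ/n!.
3. **Oracles** (`physcluster.oracle`): adaptive radial (and orientation
   grid) quadrature for K_1, seeded Monte Carlo integration for n ≤ 3, and
   the ideal-ligand closed form — the independent references against which
   both estimators are tested.

Supporting modules: `chem_model` (species, rigid-body geometry, the
surrogate PES with a pluggable radial-potential override), `sampler`
(constrained single-ligand Metropolis Monte Carlo under an explicit cluster
criterion, compact `ion_cutoff` or connectivity-based `stillinger`),
`structure` (neighborship-ordered radial densities ρ⁽ʲ⁾(r), cumulative
coordination counts n_{H|X}(r), βΔU histograms with Gaussian-model
overlays), and `workbench` (extended-XYZ / CSV / TOML / JSON IO and the
end-to-end pipeline). A `physcluster` CLI wraps the common operations
(`sample`, `rrho`, `roughscape`, `analyze`, `oracle`, `pipeline`,
`fixtures`).

## Worked example

```python
from physcluster.workbench import RunConfig, run_pipeline

table = run_pipeline(RunConfig(n_max=3, seed=11, output_dir="demo"))
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
```

which prints (≈20 s on one CPU):

```
 n             method  minus_rt_ln_k  uncertainty k1_provenance  criterion       seed      config_hash
 1         roughscape         -7.365        0.012        oracle ion_cutoff         11 783a68b793ecc9d4
 2         roughscape        -13.582        0.091        oracle ion_cutoff         11 783a68b793ecc9d4
 3         roughscape        -19.215        0.167        oracle ion_cutoff         11 783a68b793ecc9d4
 1 harmonic_classical         -6.807        0.000               ion_cutoff         11 783a68b793ecc9d4
 2 harmonic_classical         -9.692        0.000               ion_cutoff         11 783a68b793ecc9d4
 3 harmonic_classical        -14.894        0.000               ion_cutoff         11 783a68b793ecc9d4
 1          oracle_mc         -7.374        0.005        oracle ion_cutoff  704118334 783a68b793ecc9d4
 2          oracle_mc        -13.412        0.022        oracle ion_cutoff  598521961 783a68b793ecc9d4
 3          oracle_mc        -18.043        0.119        oracle ion_cutoff 1632761976 783a68b793ecc9d4
```

Reading the table: each row is −RT ln(K_n ρ₀ⁿ) in kcal/mol for W_nCl⁻ at
300 K (1 atm standard state, ion-cutoff cluster criterion, all seeds
echoed). The `oracle_mc` rows are the exact classical answer to within
their Monte Carlo error. The harmonic rows underbind increasingly with n —
the characteristic failure of the rigid-rotor harmonic-oscillator picture
on a rough landscape. The step-wise rough-landscape rows track the oracle
far more closely, while overshooting it slightly and increasingly with n:
the deletion-direction average ⟨e^(βΔU_n)⟩ converges from below at this
sampling length (100 frames here), a known limitation discussed in
`docs/methods.md`. Artifacts (trajectories, ΔU tables, results CSV/JSON,
config echo) land in `demo/`.

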
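# Methods

## Model and conventions

The package treats the association equilibria n W + X ⇌ W_nX of a
monoatomic anion X with rigid ligands W in the dilute-gas limit. All
internal units are Å, kcal/mol, amu and K, with
k_B = 0.0019872041 kcal/(mol·K) and the Coulomb prefactor
e²/(4πε₀) = 332.0637 kcal·Å/mol. Equilibrium constants are carried in
volume units (Å^{3n}) with the orientation measure of each rigid ligand
normalised to one; they are made dimensionless with the standard-state
number density ρ₀ — ideal gas at 1 atm and the run temperature by default,
1 M selectable — and reported as −RT ln(K_n ρ₀ⁿ). The convention is printed
with every free energy because nothing else in the output fixes it.

### Surrogate potential

Cluster energies U(W_nX) come from a classical pairwise surface: Coulomb
(dielectric 1) plus Lennard-Jones over all intersite pairs,
Lorentz–Berthelot combining for cross terms, no cutoffs or periodicity
(finite clusters, all pairs summed exactly). The default ligand is a
TIP3P-like rigid water (r_OH = 0.9572 Å, ∠HOH = 104.52°, q_H = +0.417 e,
LJ on O only: σ = 3.1506 Å, ε = 0.1521 kcal/mol). Ion LJ parameters grow
down the halide group (Cl⁻: σ = 4.40 Å, ε = 0.10 kcal/mol) so that binding
strength follows the familiar F > Cl > Br > I order; the Cl⁻–water dimer
minimum is ≈ −13.4 kcal/mol, the right order of magnitude for halide
hydration. These numbers are qualitative stand-ins: the surrogate exists so
that every estimator can be checked against exact classical references, not
to reproduce any electronic-structure surface. For user-supplied energies
(e.g. quantum-chemical single points) the step-wise estimator accepts a
plain CSV of subsystem energies (`workbench.read_decompositions`), and the
ion–ligand or ligand–ligand interaction can be overridden by an arbitrary
radial potential (`RadialPotential`), which is how the validation suites
build harmonic, Morse, square-well and soft-repulsion toys.

A hard-core guard (0.1 Å minimum intersite distance) bounds the surface:
configurations inside the guard are excluded from the PES domain (treated
as +∞ energy by the samplers and integrators, an error in the scalar API).
Without it the point-charge model has non-integrable Coulomb sinks.

### Cluster criteria

Two operational definitions of a "formed" cluster are provided and must be
reported with every result, because the equilibrium constants are defined
only relative to one:

* `ion_cutoff` (default, R = 4.5 Å): every ligand reference site within R
  of the ion. 4.5 Å lies beyond the surrogate's first-shell O peak
  (≈ 3.2 Å for Cl⁻). This is the compact definition under which the
  step-wise bookkeeping is internally consistent.
* `stillinger` (r_OO = 3.5 Å): the proximity graph (ion–O and O–O edges)
  is connected. This admits ramified clusters — a ligand held only through
  another ligand. Removing such a ligand disconnects the remainder, so the
  step-wise decomposition's W_{n−1}X sub-cluster is no longer clustered
  under the same definition: the chain acquires an inconsistency there. The
  sampler exposes `is_ramified` so the effect can be measured; with a
  first-shell-scale ion radius (3.5 Å) most sampled W₅Cl⁻ frames are
  ramified, which is demonstrated in the test suite rather than "fixed".
  The Monte Carlo oracle handles the stillinger domain by rejection
  counting against an enclosing ball; it is experimental and carries its
  own error bar.

## Sampling

Canonical configurations come from Metropolis Monte Carlo with
single-ligand rigid-body moves (translation uniform in a cube, rotation
about a random axis; one sweep = n attempted moves). Moves breaking the
cluster criterion or the hard-core guard are rejected outright, which makes
the sampled ensemble exactly the clustered-configuration integral with an
infinite-wall indicator — the estimators need nothing about dynamics, so
Markov-chain sampling replaces molecular dynamics at equal rigour for this
surface. Move amplitudes are tuned toward ≈ 40 % acceptance during
equilibration only and frozen afterwards, preserving detailed balance over
the production phase; a single seeded PCG64 generator drives each run and
the seed is echoed in every artifact.

The default cadence mirrors a 15 ps trajectory analysed over its last
10 ps at 0.1 ps spacing: 1500 sweeps, the first 500 discarded, a frame
stored every 10 sweeps — 100 frames. Sampler validity is established by a
two-state occupancy test against e^{−βΔE} and by bin-wise comparison of the
one-ligand radial marginal against e^{−βu(r)}r² quadrature at two
temperatures (autocorrelation-corrected multinomial errors).

## Harmonic route

Each trajectory seeds `n_starts = 20` uniformly spaced local minimisations
(L-BFGS with analytic rigid-body gradients; rotation-vector coordinates are
re-centred between cycles so the gradient stays exact at the working
point; convergence at max-|gradient| < 10⁻⁶ kcal/mol/Å). The lowest
converged minimum wins; ties below 10⁻⁸ kcal/mol go to the earliest start.

Normal modes are computed in generalised rigid-body coordinates — ion
translation, ligand centre-of-mass translations, ligand rotation vectors —
with a block-diagonal mass metric (masses and world-frame inertia tensors),
central-difference Hessians (default step 10⁻³; symmetrised, asymmetry
warned above 10⁻⁴), and projection of the exact global translation/rotation
generators before diagonalisation (6 zero modes nonlinear, 5 linear, 3 bare
atom; the count is determined by SVD rank of the generator basis, which
handles linear clusters automatically). Retained modes below 10 cm⁻¹
trigger a warning because quantum and classical vibrational factors diverge
there; no frequency floor is applied. Imaginary retained modes are an
error, never silently dropped.

K_n is assembled from q_trans/V, the classical rotor q_rot (σ = 1: the
optimised clusters are asymmetric, and free-water symmetry numbers cancel
between numerator and denominator, so σ_W = 1 as well; both overridable),
and q_vib — quantum (e^{−u/2}/(1−e^{−u}), u = βhν, zero-point included) or
classical (1/u) — divided by n! and by the free-species factors. The
classical variant has no Planck constants left after cancellation and is
exactly the Gaussian approximation to the configurational integral: the
test suite verifies it converges to the quadrature oracle across three
stiffness decades and agrees within 1 % for a stiff harmonic well, which
pins the full unit chain (Hessian → cm⁻¹ → partition functions).

## Rough-landscape route

For each stored W_nX frame and each ligand distinguished in turn (a
single-random-ligand mode exists for variance studies), the decoupling
energy ΔU_n = U(W_nX) − U(W_{n−1}X) − U(WX) + U(X) is evaluated with all
coordinates frozen; sub-cluster energies reuse the same geometry. On a
pairwise surface ΔU_n reduces exactly to the coupling-scaled interaction of
the distinguished ligand with the others, which the tests exploit as an
oracle. The step factor ⟨e^{βΔU_n}⟩_n is the plain sample mean over frames
and ligand choices; its standard error comes from non-overlapping block
means over frames (10 blocks by default; samples sharing a frame share a
block), and the Gaussian-model value exp(βμ + β²σ²/2) from the sample mean
and variance is reported alongside as a diagnostic, never as the estimate.

The chain K_n = K_1·K_{n−1}/(n·⟨e^{βΔU_n}⟩_n) is anchored at a K_1 whose
provenance (quadrature oracle by default; experimental or harmonic values
accepted) is mandatory metadata. Writing the step ratio as one clustered
integral over the W_nX coordinates shows the denominator differs from the
numerator by exactly the factor e^{βΔU_n} inside the average, which fixes
the average's placement in the denominator; the flattened typography of the
relation could be misread with the average multiplying the numerator, and a
regression test keeps that reading failing against the oracle (≈ 30σ on the
Morse toy). The chosen form reduces to K_n = K_1ⁿ/n! when ΔU ≡ 0 and makes
unfavourable crowding reduce K_n. Uncertainties propagate in log space:
Var ln K_n = n² Var ln K_1 + Σ_m (SE_m/⟨e^{βΔU_m}⟩)². Everything here is
classical-limit bookkeeping; zero-point motion enters only through a
user-supplied K_1.

### Known limitation: deletion-direction convergence

⟨e^{βΔU_n}⟩_n equals Z_decoupled/Z_coupled. It is estimated from the
*coupled* stream — a deletion (reverse) free-energy average. Regions where
the decoupled measure is large but the coupled one vanishes contribute
fully to the true ratio yet are essentially never sampled: for compact
first shells the dominant such region is the ligand–ligand hard-core
overlap, which for W₂Cl⁻ at 300 K carries ≈ 14 % of the decoupled measure
while the coupled stream visits it with probability ~e^{−17}. The estimator
therefore converges from below, with a practically irreducible deficit of
order 0.1–0.5 kcal/mol per step at these conditions, growing with n. The
package does not hide this: the step-wise results overshoot the Monte Carlo
oracle by about that much on the default surrogate (see the worked example
and the oracle-equivalence test, which is allowed to fail at exactly this
gap and documents it), while on mild toys without hard cores — bounded
exponential ligand–ligand repulsion, shallow Morse wells — the chain and
the oracle agree to well within combined errors, confirming the relation
itself is exact. Practical consequence: anchor as much physics as possible
in K_1 and treat chained values at large n, or under ramified clustering,
with the quoted caution.

## Oracles

* `analytic_ideal_chain`: K_n = K_1ⁿ/n!, exact when ligand–ligand coupling
  is off.
* `k1_quadrature`: point ligands use adaptive radial quadrature of
  4π∫e^{−βu}r²dr (relative tolerance 10⁻¹⁰); rigid multi-site ligands use
  a Simpson radial grid times an SO(3) product grid (uniform α, γ;
  Gauss–Legendre in cos β), default 513 × 24³ points, with the error
  estimated by halving both grids. The default grid is converged to ~10⁻⁵
  relative for the water surrogate; the halving estimate is deliberately
  conservative.
* `kn_mc_integration` (n ≤ 3): positions of ligand reference sites in the
  criterion ball, orientations uniform on SO(3), batch-mean errors, seeded.
  Two proposals: plain `uniform` (kept for cross-checks; hopeless variance
  once β×well-depth is large) and the default `boltzmann1`, which draws
  each radius from a piecewise-constant histogram of the
  orientation-averaged single-ligand Boltzmann density — the proposal
  density is known exactly bin by bin, so the importance weights are exact
  and the estimator stays unbiased; in the ideal-ligand point-ligand limit
  the weights are constant and the estimate is exact. Results with
  relative error above 20 % are flagged low-precision. The n ≤ 3 guard
  keeps runtimes at desk scale; higher n is validated only through the
  ideal-ligand closed form.

## Structural observables

Neighborship-ordered densities ρ⁽ʲ⁾(r): per frame, selected site–ion
distances (H sites, O sites, or all) are sorted and the j-th smallest
binned (default 0.02 Å). Each rank is normalised by the discrete shell sum,
so 4π Σ ρ⁽ʲ⁾r²Δr = 1 holds exactly up to floating point — the invariant is
by construction, and the per-rank-normalised / total-as-density dual
convention is labelled explicitly. The cumulative curve n(r) is the average
selected-site count within r. Sorting implies first-order stochastic
dominance of rank j over j+1, which `stochastic_order_check` verifies (and
a corrupted-profile negative control confirms it can fail). βΔU histograms
carry the sample mean/variance, a Gaussian overlay with those moments, and
a descriptive modality count (local maxima exceeding flanking minima by
3√count, a Poisson noise floor — never an acceptance gate). Figure-style
exports convert Å → nm and Å⁻³ → nm⁻³.

## Problem sizes and determinism

Default study conditions: T = 300 K, Cl⁻ + rigid water, full coupling,
ion-cutoff 4.5 Å, 100 frames per trajectory. Validation suites scale up
where statistics demand it (up to ~20 000 frames for marginal tests,
8 000 sweeps for the oracle-equivalence runs, 2–6 × 10⁵ Monte Carlo oracle
samples) — sizes chosen so each check resolves its target at 3σ. Every
stochastic component takes an explicit integer seed; identical seeds give
bit-identical trajectories, oracle estimates and pipeline tables, and the
pipeline echoes its full configuration plus a hash into every artifact.

## What the surrogate does and does not show

Passing tests establish that the estimators, bookkeeping, and reference
integrals are mutually consistent on a classical pairwise surface with
rigid monomers. They say nothing about polarisation, charge transfer,
intramolecular flexibility, quantum zero-point motion (beyond the optional
quantum vibrational statistics in the harmonic route and whatever a
supplied K_1 carries), or the quantitative energetics of real halides — by
design, those questions are delegated to user-supplied energies fed through
the same machinery.
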
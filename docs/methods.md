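# Methods

`polyample` implements the statistical mechanics of a single statistically
neutral Markov polyampholyte: a flexible chain of `N` monomers of size `a` in
a salt-free Θ solvent, of which a fraction `f` (equidistantly spaced) carry a
quenched charge ±e.  Everything is expressed in reduced units: lengths in
`a`, energies in `k_B T`, charges in `e`.  The dimensionless Bjerrum length
`u = l_B/a` sets the Coulomb coupling.

## Sequence model

Ionic signs form a stationary two-state Markov chain with symmetric
conditional probabilities `p(+|+) = p(−|−) = (1+λ)/2`, so the ensemble is
statistically neutral for every correlation parameter `λ ∈ [−1, 1]`, and `λ`
is the second eigenvalue of the transition matrix.  Derived quantities used
throughout:

* blockiness `Λ = (1+λ)/(1−λ)`; the mean net charge of a like-charge run is
  `1 + Λ = 2/(1−λ)` (geometric run lengths), a chain holds `fN/(1+Λ)` blocks;
* exact finite-size net-charge variance, from `Cov(s_i, s_j) = λ^{|i−j|}`:

      Var(Q) = n(1+λ)/(1−λ) − 2λ(1−λ^n)/(1−λ)²,   n = fN,

  validated against exhaustive 2^n enumeration; `Var(Q)/n → Λ`;
* characteristic single-realization charge `Q = √(fNΛ)`, rising from 0
  (alternating) through `√(fN)` (random) to `fN` (block ≈ chain).

The generator draws the first ionic sign from the stationary (½, ½)
distribution and is vectorized via cumulative sign flips; neutral monomers
are interleaved deterministically at positions `⌈(k+½)/f⌉`.  `λ = 1`
(single-sign chains) is honored as a flagged degenerate case, and
`blockiness(1)` raises rather than overflowing.  Fixed-net-charge ensembles
use plain rejection sampling, which leaves the quenched measure exactly the
conditional Markov measure; no importance reweighting is attempted.  The
maximum-likelihood estimator `λ̂ = (n_same − n_diff)/n` with a binomial
standard error closes the loop (generation → estimation round trips are
property-tested).

## Scaling engine

Globule density is piecewise in Λ with all prefactors set to exactly 1:
`φ = max(u²f^{3/2}, min(ufΛ, (uf²)^{1/3}))` — dipole-dominated
(near-alternating), charged-blob melt (random), and coacervate-like (blocky)
branches meeting exactly at the crossovers `Λ_a/r = uf^{1/2}` and
`Λ_r/hb = u^{−2/3}f^{−1/3} = q_e`, the electrostatic-blob charge.  The
Rayleigh ratio of destabilizing Coulomb self-repulsion to surface energy
reduces algebraically to `I = ufΛ/φ`, giving the characteristic plateau
`I ≡ 1` across the random regime.

Regimes are assigned on left-closed intervals of Λ at the four boundaries
`Λ_a/r < Λ_r/hb < Λ_b/s = u^{−4/9}f^{1/9}N^{1/3} < Λ_PE = fN`.  `Λ_b/s`
follows from the triple equality (bead charge = block charge = ionic string
content) evaluated with the regime-III laws; `Λ_PE` is where the block
length `Λ/f` reaches `N`.  Every observable (R, N_bead, m_bead, m_str,
D_bead, l_str, L_nec, Q_bead, Q_str) is implemented with unit prefactors, so
continuity of R across II/III, III/IV and IV/V, the single-bead values at
the III and IV endpoints, and the `(N/g_e)^{1/9}` discontinuity of the bead
charge at III/IV all hold as exact identities — they are tested numerically
over a grid of (u, f, N), not asserted symbolically.  The choice of unit
prefactors is deliberate: scaling theory fixes laws only up to O(1) factors,
and unit prefactors make the internal consistency checks sharp.

In regime II the ensemble is bimodal (spheres and necklaces coexist); the
necklace branch is reported because it dominates the ensemble-average
dimensions.  Densities above 1 and boundary collapses (e.g. `u ≳ 1, f ≈ 1`
merging Λ_a/r with Λ_r/hb) are flagged with warnings rather than errors —
the dense limit is outside the theory.

### Necklace free energy and charge migration

The III/IV boundary is also derived variationally.  A necklace state is
parameterized by the bead count `n_b` (with `n_b` strings) and the fraction
`x` of the net charge `Q = √(fNΛ)` residing in strings.  With `φ` and
`ξ = 1/φ` from the globule branch, per-string charge `q_s = xQ/n_b` and
per-bead charge `q_b = (1−x)Q/n_b`, the string length minimizes
`l/ξ + u(q_b² + q_s²)/l` in closed form, the string mass follows from mass
conservation at the globule density (`m_str = φ l ξ²`), and the total energy
sums bead Coulomb self-energy `u q_b²/D`, bead surface `D²/ξ²`, string
surface and stretching `l/ξ` each, and Coulomb repulsion along the string
`u(q_b² + q_s²)/l`.  Two feasibility caps make migration physical: a string
carrying net charge is a single like-charge block, so `q_s ≤ Λ`, and `q_s`
cannot exceed the ionic content `f·m_str` (if it would, the string is
stretched to polyelectrolyte length to hold it).  Minimization is a dense
(log-spaced integer × uniform fraction) grid with one local refinement pass.
The minimizing `x` crosses ½ at Λ ≈ 8–9 for `u = f = 1, N = 10⁴`, within a
factor 3 of the closed-form `Λ_b/s ≈ 21.5`, and tends to 1 far above it —
the same crossover, recovered without assuming the closed-form algebra.

## Coarse-grained simulator

A single bead-spring chain with FENE bonds (`k = 30`, `R₀ = 1.5`), a
Lennard-Jones pair potential on all pairs (cutoff `2.5σ`, energy-shifted to
zero at the cutoff) with well depth `ε = 0.34` — a Θ-proximate choice so
that short-range two-body interactions approximately cancel and collapse is
electrostatically driven — and unscreened Coulomb `u q_i q_j/r` over all
charged pairs with open boundaries (direct O(N²) summation; appropriate for
one isolated chain).  All force-field parameters are configurable; a
harmonic bond option (`k`, rest length) exists mainly so that the ideal
discrete Gaussian chain, whose `⟨R_g²⟩ = (3/k)(N²−1)/(6N)` is exact, can
serve as an oracle.

Integration is BAOAB Langevin splitting with friction γ = 0.1 by default
(weak coupling accelerates conformational sampling; equipartition is
unaffected) and a hard timestep cap of 0.01τ.  Noise is drawn per chunk from
a seeded `numpy` Generator, making trajectories bit-reproducible; the force
loops are `numba`-compiled.  Analytic forces are verified against
central-difference energy gradients to 1e−5 relative; kinetic energy per
degree of freedom matches `k_B T/2` to well under 2% in equilibrated runs.
Initial conformations are self-avoiding random walks with a gradually
relaxing exclusion radius (hard overlaps would produce astronomically large
LJ energies); equilibration is monitored through the drift of the running
R_g mean and flagged on the returned trajectory.  Energy divergence raises
an error naming the timestep bound.

## Necklace analysis

Beads are connected components of the monomer contact graph (KD-tree pairs
within a cutoff of 1.5a, the first-neighbor shell of a dense melt; bonded
neighbors excluded so taut strings do not register as 1-D clusters) with at
least `max(4, g_e)` members — a bead must exceed one electrostatic blob.
Everything else is bookkeeping with exact integer charge conservation, and
`⟨R_g⟩`/`⟨N_bead⟩` standard errors come from block averages sized by the
integrated autocorrelation time of the R_g series, pooled across independent
trajectories.  Bead detection is rotation/translation invariant and is
validated against constructed geometries, including the scaling engine's own
idealized necklace (spheres of diameter `D_bead` packed at density φ, spaced
`l_str`).

## Fixed-charge blockiness comparison

The end-to-end pipeline conditions the Markov ensemble on an exact net
charge, simulates each quenched sequence, and compares `⟨R_g⟩` across λ at
fixed Q.  The default problem size is N = 256, Q = 20, λ ∈ {−0.5, 0, 0.5}
with 8 independent runs per λ of 6×10⁴ equilibration plus 6×10⁴ production
steps at dt = 0.01 — sizes chosen so the comparison completes on a single
desktop core in minutes while the ordering (blockier ⇒ more compact at fixed
charge) is resolved well outside its standard errors.  A full-scale mode
(N = 1024, Q = 40, longer runs) is exposed through the CLI but is not part
of the test suite; its quantitative R_g values depend on force-field details
(Θ-point calibration, Bjerrum length) that are configurable here, so only
the ordering claim is treated as a hard prediction.

## Known limitations

* All scaling predictions carry unit prefactors; they are internally exact
  but only order-of-magnitude against experiments or simulation.
* Quenched-disorder spread between sequence realizations is sampled, not
  theorized: predictions are ensemble-characteristic values.
* No salt, counterions, solvent-quality deviations from Θ, or many-chain
  phase behavior.
* The desk-scale simulator resolves trends (collapse, ordering, necklace
  fluctuations), not sharp regime boundaries; bead counts from simulation
  are sensitive to the contact cutoff and should be scanned.
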
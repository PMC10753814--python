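# Methods

## The model and the algorithm

`pchbmc` implements full configuration interaction quantum Monte Carlo
(FCIQMC) for a second-quantized molecular Hamiltonian

    H = E_nuc + Σ_PQ h_PQ a†_P a_Q + ½ Σ_PQRS g_PQRS a†_P a†_R a_S a_Q

with real, spin-restricted integrals in chemist notation `(pq|rs)` carrying
the 8-fold permutational symmetry. The stochastic wave function is a set of
signed real walker amplitudes over Slater determinants, propagated in
imaginary time by repeated application of `1 − Δτ (H − E_ref − S)`. Each
iteration has four stages: excitation generation, spawning, diagonal
death/cloning, and annihilation. Matrix elements follow the Slater–Condon
rules; the Fermionic phase of a single replacement `A ← I` is `(−1)^n` with
`n` the number of occupied spin–orbitals strictly between `A` and `I` in the
source determinant, and the composite phase of a double is accumulated by two
sequential single-style transpositions (`I → A` on the source, then `J → B`
on the intermediate). This composite-phase convention is validated by exact
Hermiticity of the assembled dense Hamiltonian and by eigenvalue agreement
with the dense full-CI oracle, not by matching any particular textbook sign
table.

Spin–orbital convention: spatial orbital `i` with spin α/β maps to index
`2i`/`2i+1` (interleaved), so spatial locality is contiguous; determinants
are little-endian integer bit masks.

## Precomputed heat-bath excitation generation

The excitation generator proposes a connected determinant with probability
`p_gen`, ideally proportional to `|⟨D_j|H|D_i⟩|`. Because the magnitude of a
double-excitation element does not depend on the starting determinant, the
weights

    W_IJ^AB = |g_AIBJ δ(σA,σI) δ(σB,σJ) − g_AJBI δ(σA,σJ) δ(σB,σI)|

can be precomputed once per active space. The sampling factorizes into four
chained draws `I → J|I → A|IJ → B|IJA` with marginals

    p(I) ∝ Σ_JAB W,   p(J|I) ∝ Σ_AB W,   p(A|IJ) ∝ Σ_B W,   p(B|IJA) ∝ W,

each stored as a normalized row plus a Vose alias table, giving O(1) draws.
Singles use the contracted weight

    S_I^A = |h_AI| + Σ_R ( |g_AIRR| + |g_ARRI| ),

with `R` running over *all* spin–orbitals (two Coulomb contributions per
spatial orbital, one same-spin exchange contribution). By the triangle
inequality `S_I^A` bounds the true single-excitation element of every
determinant, and in localized orbital bases — where the integrals decay
exponentially with inter-orbital distance — it approximates the exact
determinant-dependent law well. Both weight tensors are exactly Hermitian
(`W_IJ^AB = W_AB^IJ`, `S_I^A = S_A^I`).

Each index slot can be drawn three ways, written `sI:sA/dI-dJ:dA-dB`
(e.g. `unif:full/unif-full:full-full`):

* `unif` — uniform over the valid set (occupied for particles, empty of the
  required spin for holes), O(1);
* `fast` — from the unconstrained precomputed alias table; a draw that lands
  on an invalid orbital is discarded (the attempt is counted, not resampled);
* `full` — from the occupancy-constrained renormalized distribution.

The reported `p_gen` of a valid double sums all index orderings that produce
the same target determinant — two particle orders times two hole orders —
using each path's own conditional (`p(I|J) ≠ p(J|I)` in general) and, for
constrained slots, the renormalized value. For `fast` draws that land validly
the *unconstrained* table probability is used, which is what makes the
discard semantics unbiased. The law-of-total-probability identity
`Σ_targets p_gen + P(invalid) = 1` is enforced exhaustively in the tests by a
pure-Python path-enumeration oracle that is independent of the sampling
kernel.

### Constrained draws

Constrained (`full`) slots draw by rejection: redraw from the existing
unconstrained alias table until the occupancy constraint is met. The subset
mass needed for renormalization is obtained by summing whichever of the
subset or its complement is smaller (`mass(S) = 1 − mass(S̄)`), i.e. O(N_e)
for particles and O(N_e) rather than O(n_orb − N_e) for holes. When the
subset mass is below a threshold (default 0.2 — below this the expected ≥5
redraws typically cost more than one linear scan at desk scale) the draw
falls back to a direct scan of the renormalized restriction; a hard cap of
1000 redraw attempts guards worst-case latency. The strategy choice never
changes the sampled law, only the cost; the literature's rebuild-the-alias-
table strategy is kept as a test reference.

### GAS and spin penalty

Generalized-active-space constraints partition the spatial orbitals into
subspaces with (min, max) particle counts; an allowed particle distribution
is a supergroup. One table set is built per supergroup with every index
combination zeroed whose particle transfer leaves the allowed set, so
GAS-forbidden excitations have exactly zero generation probability. A
determinant's supergroup is found by counting particles per subspace.
Uniform slots cannot consult the weights, so in GAS dynamics any spawn whose
target leaves the allowed set is discarded like an invalid draw — equivalent
to, and as unbiased as, rejecting the attempt.

Spin purification adds `J (Ŝ² − s(s+1))` to the Hamiltonian. In the
determinant basis Ŝ² has diagonal `S_z(S_z−1) + n_α^OS` (the number of
open-shell α electrons; equivalently `S_z(S_z+1) + n_β^OS`) and unit-magnitude
off-diagonal elements only for spin-exchange doubles
`i_α j_β ← i_β j_α` between singly occupied spatial orbitals. Only those
doubles' weights change, to `|g_AIBJ − g_AJBI + J|`; an exhaustive test
verifies the tensor equals `|⟨D_j|H + JŜ²|D_i⟩|` element by element. The
penalty makes opposite-spin particle pairs more likely and concentrates the
hole selection on exchange completions, both monotonically in `J`; note the
total `p_gen` of one fixed exchange excitation need not increase, because the
penalty boosts *every* opposite-spin pair in the particle marginal.

## Walker dynamics

Each occupied determinant with amplitude `c` makes `ceil(|c|)` attempts per
iteration, each carrying weight `|c|/ceil(|c|)`. An attempt picks the
excitation class (single with probability `p1`, double with `p2 = 1 − p1`),
draws an excitation, and — if valid — spawns onto the target with magnitude
`Δτ w |H_ij| / (p_n p_gen)` and sign `−sign(H_ij) sign(c)`. Spawns below
magnitude one are stochastically rounded to 0 or ±1, and so are sub-unit
merged amplitudes after annihilation; both roundings are unbiased in
expectation and keep the population sparse. Annihilation merges all
contributions per determinant by signed summation in sorted order, so runs
are bit-reproducible for a fixed seed on a single worker. The initiator rule
discards spawns from parents with `|c| ≤ n_add` (default 3) onto unoccupied
determinants.

The per-attempt hot path (occupancy bookkeeping, alias and constrained
draws, `p_gen` ordering sums, Slater–Condon elements, spawning and death) is
compiled with numba; a readable pure-Python implementation of every matrix
element is kept alongside and the two are compared exhaustively on small
spaces in the test suite.

### Adaptation of Δτ, p1/p2 and the shift

Running maxima `M_n` of `|H_ij|/p_gen` per excitation class steer a damped
update (5% of the gap per iteration) toward the fixed point `p1 : p2 = M1 :
M2`, `Δτ = 1/max_n(M_n/p_n)`, which keeps every previously observed spawn
magnitude below one; poorly sampled classes are therefore attempted more
often. The spawn rule alone does not bound the diagonal death factor, so Δτ
is additionally capped at `0.9 / (max_i |H_ii − E_ref| + |S|)` — without this
the amplitudes of high-lying determinants can grow without bound. Adaptation
runs through the growth and settling phases and is frozen before measurement.

Population control: the run grows at fixed shift `S = 0` until the target
walker number is reached, seeds the shift with the instantaneous projected
correlation energy (so the controller only tracks fluctuations), then applies
the damped first-order rule `S ← S − ζ/(AΔτ) ln(N_now/N_prev)` plus a weak
restoring term `−r/(AΔτ) ln(N_now/N_target)` (r = 0.01) that parks the
stationary population on the target without moving the stationary shift.
Defaults ζ = 0.1, A = 2 (every iteration during settling): a faster
controller than the traditional ζ ≈ 0.05, A = 5, chosen because it shortens
the shift autocorrelation time to O(20) iterations, which is what makes
reblocked error bars on desk-scale series (a few thousand points) reliable.
The published second-order controller is deliberately replaced by this
damped first-order rule; only population control, not any estimator, depends
on it.

### Estimators and error bars

Two energy estimators are reported: the mean shift (population-control
estimator) and the projected energy
`E = H_ref,ref + Σ_j H_ref,j c_j / c_ref`. Error bars come from
Flyvbjerg–Petersen reblocking with the plateau chosen by the block-size
criterion `B³ ≥ 2N (se_B²/se_1²)²`; the projected energy uses the delta
method, reblocking the linearized fluctuation series `num − f·den`. The
projected estimator needs a reference with appreciable overlap on the ground
state; for spin-penalized or GAS runs where the aufbau determinant is poor,
pass the dominant determinant of the (oracle) ground state as `ref_det`.

## Synthetic data

Desk-scale model Hamiltonians stand in for the paper-scale molecular systems
(which need external integral generation):

* **Hubbard chains** (`gen_hubbard_chain`) — `h(i,i±1) = −t`, `(ii|ii) = U`,
  half filling by default; the dimer ground energy has the closed form
  `(U − sqrt(U² + 16t²))/2`, the U = 0 and t = 0 limits are analytic.
* **Localized random integrals** (`gen_local_integrals`) — orbitals on a 1-D
  unit-spaced lattice; base magnitudes drawn once from a seeded stream, then
  damped by `exp(−d/λ)` where `d` is the relevant inter-orbital distance (for
  `(pq|rs)`: the largest of `|p−q|`, `|r−s|` and the pair-centroid
  separation). This reproduces the exponential integral decay of localized
  molecular orbitals — the regime the weighted singles generator is designed
  for — without any quantum-chemistry dependency. λ → ∞ recovers the
  undamped draw; identical seeds give bit-identical tables. Geminal
  `(ii|ii)` integrals are shifted positive so half filling is the physical
  regime.
* **Anderson impurity** (`gen_anderson_impurity`) — one interacting impurity
  hybridized with uncoupled bath orbitals; the natural GAS example, since a
  doubly occupied impurity leaves bath particles with no allowed single
  excitation.
* **Hund-coupled pair** (`gen_hund_pair`) — two degenerate orbitals with
  direct + exchange repulsion: the minimal system whose S_z = 0 determinant
  sector has a triplet ground state, used to validate spin purification.

What these fixtures do *not* emulate: point-group symmetry blocks, realistic
integral magnitudes/cusp structure, and the 3-D decay geometry of real
localized MOs. Passing tests therefore demonstrate algorithmic correctness
(unbiased sampling laws, exact normalization, convergence to the exact
ground state) and the qualitative locality behaviour, not quantitative
efficiency ratios on molecular systems, which are hardware- and
implementation-dependent and out of scope here.

## Numerical choices and problem sizes

* Alias tables use Vose's two-stack construction with ties broken by
  ascending index — bit-reproducible tables.
* Exactly-zero weights are never floored: for doubles the weight *is* the
  element magnitude, and the singles weight upper-bounds the element, so a
  zero weight implies a zero matrix element and no excitation can starve.
  (An epsilon floor would only matter if a weight could underestimate a
  nonzero element, which the triangle-inequality construction rules out.)
* Dense conditional tables are O(n_spin⁴); building is refused beyond 40
  spin–orbitals, where pair-compressed storage (out of scope) would be
  needed.
* Duplicate FCIDUMP records must agree to 1e-10; conflicts are errors, not
  silent overwrites. Written files keep one representative per 8-fold
  symmetry class and drop entries below 1e-12.
* Dense FCI diagonalization guards the basis at 2·10⁴ determinants.
* Validation runs use target populations of 10⁴ walkers with ~1000 settling
  and 5000–10000 measurement iterations (longest for the localized fixture,
  whose population has a slow relaxation mode) on spaces of 4–100
  determinants; these sizes keep the population-control bias (∝ 1/N_w) well
  below the statistical resolution while the whole suite stays desk-scale. Criteria are
  3× the reblocked error; pairwise scheme consistency uses the combined
  error.

## Known limitations

* Single-node, single-worker only; no semistochastic propagation, no replica
  RDM sampling, no adaptive shift.
* Point-group symmetry labels are read and preserved but not used to screen
  excitations.
* The projected estimator degrades for references with small ground-state
  overlap (see above); the shift estimator does not.
* Wall-clock efficiency is reported only as a diagnostic; the package makes
  no claims about relative timings of the sampling schemes at desk scale.
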
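# Methods

This note records the models implemented in `mechelix`, the parameter
choices that matter, and what the synthetic-data generator does and does
not emulate.

## Backbone construction and helix assignment

Backbones are built from internal coordinates by natural-extension
reference-frame placement with canonical bond lengths (N–CA 1.46 Å, CA–C
1.52 Å, C–N 1.33 Å, C=O 1.23 Å, N–H 1.00 Å) and trans peptide bonds
(ω = 180°). Backbone bond angles are CA–C–N 116.6° and C–N–CA 121.7°; the
N–CA–C angle is set to 110.0°, at the low end of its canonical range, which
places the ideal α-helix (φ = −57°, ψ = −47°) at a rise of 1.52 Å per
residue, a CA radius of 2.3 Å, and a 22-residue CA–CA end-to-end distance
of 3.20 nm — the textbook α-helix dimensions. Carbonyl oxygens are placed
trans to the next amide nitrogen; amide hydrogens sit 1.00 Å from N, anti
to the bisector of the C(i−1)→N and CA→N directions. The first residue has
no amide hydrogen and cannot donate. Terminal capping groups are not
represented as residues.

Secondary structure uses the Kabsch–Sander electrostatic hydrogen-bond
model (prefactor 27.888 kcal·Å/mol, cutoff −0.5 kcal/mol) reduced to two
classes: `H` for α-helix, `C` for everything else. Only i→i+4 turns are
considered; 3₁₀/π/turn/sheet classes are collapsed into `C` because every
downstream statistic is defined on α-helicity. Under this convention a
fully folded 22-mer has exactly 20 helical residues — the termini cannot
complete two consecutive turns — which fixes the "fully folded" reference
used throughout. Assignment depends only on interatomic distances and is
rigid-motion invariant; every maximal `H` run has length ≥ 4 by
construction.

`unwind_terminal` rebuilds the last n residues at extended dihedrals
(−135°, +135°) while leaving upstream atoms bit-identical, providing
partially unfolded fixtures with known helical cores.

## Trajectory statistics

`StateTrajectory` holds frames × residues helix/coil states with
end-to-end distances. Statistics discard a burn-in specified in time
units; the default of 1000 ns reflects the convention of dropping the
initial unfolding transient of a constant-force production run started
from the folded state, and an empty post-burn-in selection is an error
rather than a silent zero. Choices fixed here:

* "helicity" at threshold L means a *contiguous* run of at least L helical
  residues (longest-run statistic);
* the conditional fraction (run ≥ L **and** e2e ≥ 3 nm) is normalised by
  *all* post-burn-in frames, so it is bounded above by both the plain
  helicity fraction and the plain extension fraction;
* the extension threshold comparison is inclusive (≥ 3 nm);
* the extension spread is the population (not sample) standard deviation.

## The surrogate chain

The generator exists to give every statistic an input with the right
structure — cooperative helicity, a force-shifted equilibrium, noisy
extension — while remaining exactly solvable. Each residue is helix or
coil; the configuration energy is

E = −k_BT·(n_H ln s + n_runs ln σ) − F·(n_H·d_h + n_C·d_c(F)),

with helical rise d_h = 0.15 nm, coil contour l_c = 0.36 nm per residue,
Kuhn length b = 0.55 nm, and d_c(F) = l_c·(coth x − 1/x), x = F·b/k_BT
(mean-field freely jointed chain; d_c depends on force magnitude only).
Nucleation factor σ = 10⁻³ gives strong cooperativity. The propagation
weight s is solved (bisection on the exact transfer matrix) so that the
zero-force mean helicity is 0.7: a free helix-forming peptide is
marginally stable — mostly helical with substantial coil fluctuation.
This default is a property of the model, not a fit to any trajectory
statistic. At 300 K the crossover d_c = d_h sits near 11 pN, so 10 pN
slightly stabilises the helix while 15 and 20 pN progressively melt it;
mean helicity is monotone decreasing in force wherever d_c > d_h.

Dynamics are Metropolis single-flip kinetic Monte Carlo (detailed balance
holds exactly; the equilibrium distribution is verified against full
enumeration by χ² on an 8-residue chain). One sweep nominally represents
1 ns; kinetics are qualitative. Frames record the state every
`frame_stride` sweeps; the reported end-to-end distance is
n_H·d_h + n_C·d_c plus uncorrelated Gaussian noise (σ = 0.05 nm), floored
at 0.01 nm so distances stay positive. Chains start fully helical, so the
burn-in convention above applies naturally.

Both kernels (spin flips and Langevin steps) consume pre-generated random
streams from `numpy.random.default_rng(seed)`, so trajectories are
bit-identical for a given seed regardless of whether the numba-compiled or
pure-Python path executes.

What the surrogate does **not** emulate: atomistic structure and solvent,
sequence effects, hairpin/autoinhibited compact states, correlated
extension fluctuations, and real kinetics. Passing tests therefore
demonstrate the correctness of the *statistics and estimators* on data
with the assumed structure, not quantitative agreement with any particular
peptide's absolute numbers (e.g. published all-atom percentages or
unfolding forces), which are outside desk scale by design.

## Langevin integrator and potentials

Overdamped Euler–Maruyama: x ← x + [−V′(x) + F_ext]·dt/γ +
√(2k_BT·dt/γ)·ξ. The step is accepted only if dt·max|V″|/γ < 0.1
(curvature estimated on a grid over the potential's domain, including any
bias spring); zero temperature is allowed and gives deterministic
gradient descent, used for work-bookkeeping checks. Named potentials:
harmonic, double well h((x−c)²/a² − 1)², and the three-state binding
surrogate

V(ξ) = −40·exp[−(ξ−0.25)²/2·0.05²] − 10·exp[−(ξ−0.55)²/2·0.05²] kJ/mol,

a deep bound basin, a shallow recognition shoulder, and a flat unbound
plateau beyond ~1 nm. Its one-dimensional equilibrium density is known in
closed form, giving quadrature oracles for every free-energy estimate.

## Pulling

Constant-velocity pulling adds U(t) = ½k(ξ − ξ₀ − v·t)² (defaults:
v = 0.01 nm/ns, k = 1000 kJ/(mol·nm²)) and records the spring force
k(ξ₀ + v·t − ξ) in pN (1 kJ/(mol·nm) = 1.661 pN). For the helix-coil
chain the pulled coordinate is the noiseless model end-to-end distance;
the coil extension per residue is slaved to the spring tension through the
self-consistent fixed point e2e = n_H·d_h + n_C·d_c(k(z − e2e)), which is
unique (both maps are monotone) and solved by bisection each frame. The
default pull stops at ~90% of the coil contour length, where the freely
jointed chain stiffens sharply and the force diverges without adding
information. The reference setup's transverse terminal restraints
(40 kJ/(mol·nm²)) have no Cartesian counterpart in a 1-D surrogate and are
carried as protocol metadata only — an emulation, not a reproduction.

Force profiles are smoothed with a centred moving average (default 1 ns)
normalised per-window at the edges; this preserves the trace mean up to
O(window/duration) edge effects. The average unfolding force is the
time-average of the smoothed force over samples with extension up to
6.4 nm (averaging over time samples, pooled across any replicas, not over
extension bins). A trace that never reaches the range is an error.

## Umbrella sampling and WHAM

Windows are planned on an arithmetic grid; both canonical protocols are
expressible exactly (17 windows × 0.04 nm at 18000 kJ/(mol·nm²) for
bound–recognition; 22 × 0.05 nm at 15000 for recognition–unbound). A
spring constant of zero denotes an unbiased window, used for plain
equilibrium reconstruction. Sampling discards an equilibration segment
(default 10% of the production length) and thins by a stride of 5 steps.

The WHAM solver iterates the standard self-consistent equations in log
space (logsumexp throughout; the 18000 kJ/(mol·nm²) biases produce factors
far outside double range otherwise) until the window free energies move by
less than 10⁻⁶ kJ/mol, with a convergence warning at 10⁵ iterations.
Binning: bin width at most half the window spacing; empty bins are masked
NaN, never interpolated. Basin free energies are computed as
−k_BT·ln ∫ exp(−A/k_BT) dξ over supported bins, matching the quadrature
oracle definition on the analytic potential; pointwise comparisons against
an analytic potential use the bin-integrated reference
−k_BT·ln ∫_bin exp(−V/k_BT), which removes mid-point discretisation bias.

Forward/reverse profiles are averaged after re-zeroing both at the
recognition anchor — the state shared by the two directions; this
alignment convention is a design choice of this package, declared rather
than inherited. Stitching shifts the second segment to agree at the
anchor and reports ΔG_total = A(unbound) − A(bound) on the joined profile.

## Problem sizes and numerical defaults

The shipped tests and examples use problem sizes chosen to make
statistical assertions decisive on a single CPU: 6000-frame chain runs
(10 sweeps/frame) for force orderings, 8000 frames for oracle comparisons
with block-averaged standard errors (50 blocks), 20 000 samples per
umbrella window, and 3×10⁶ Langevin steps for pointwise profile recovery.
Monte Carlo χ² tests thin by 20 sweeps to decorrelate configurations.
All stochastic entry points take explicit seeds, and CLI runs write JSON
manifests from which outputs replay bit-identically.

## Known limitations

* Only the α-helix class is assigned; chains shorter than 5 residues
  cannot be assigned at all.
* The transfer-matrix oracle and simulator share the Hamiltonian but not
  code paths; both assume the mean-field coil extension, so they validate
  each other's sampling/summation, not the FJC assumption itself.
* The 1-D pulling surrogate cannot express transverse restraint geometry,
  replica-specific unfolding pathways, or refolding against a bound
  partner.
* WHAM error bars are not computed; repeats and bidirectional averaging
  are the supported uncertainty handles.
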
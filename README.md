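# mechelix

Mechanics of helical peptides under force.

Short amphipathic α-helices — such as the vinculin-binding-site (VBS)
helices of the talin rod — are exposed by mechanical unfolding of their
parent bundles and then live under piconewton loads, continuously melting
and partially refolding. `mechelix` is a Python library for quantifying
that behaviour: it builds ideal and partially unwound peptide backbones,
assigns α-helicity with the Kabsch–Sander hydrogen-bond criterion, computes
force-dependent helicity and extension statistics from trajectories,
analyses steered-pulling force profiles, and reconstructs binding
free-energy profiles from umbrella sampling with WHAM. A built-in
surrogate simulator — a force-coupled Zimm–Bragg chain evolved by kinetic
Monte Carlo, plus 1-D overdamped Langevin dynamics on analytic potentials —
generates test data with the structure of the real problem, so that every
statistic in the package can be validated against an exact oracle.

It is intended for structural bioinformaticians and simulators who need the
*analysis* layer of a force-spectroscopy study — the secondary-structure
bookkeeping, run-length statistics and free-energy estimators — without the
all-atom molecular dynamics that usually produces the input.

## The models

**Helix assignment.** A backbone hydrogen bond between the amide of residue
*j* and the carbonyl of residue *i* is scored with the Kabsch–Sander
electrostatic energy

```
E = 27.888 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)   kcal/mol,  r in Å
```

and counts as a bond when E < −0.5 kcal/mol. A 4-turn exists at *i* when
NH(i+4)→CO(i) is bonded; residues i…i+3 are helical (`H`) when turns exist
at both i−1 and i. On an ideal 22-residue α-helix (φ = −57°, ψ = −47°) this
yields exactly 20 `H` residues and a CA–CA end-to-end distance of 3.2 nm.

**Surrogate chain.** Each residue is helix (rise d_h = 0.15 nm) or coil
(freely jointed extension d_c(F) = l_c·(coth x − 1/x), x = F·b/k_BT). The
configuration energy is the Zimm–Bragg form with force coupling,

```
E = −k_BT·(n_H ln s + n_runs ln σ) − F·(n_H·d_h + n_C·d_c(F)),
```

sampled by Metropolis single-flip kinetic Monte Carlo and solved exactly by
a 2×2 transfer matrix with s_eff = s·exp[F(d_h − d_c)/k_BT]. Because
stretched coil is longer than helix above ~11 pN, force melts the chain —
helicity falls and extension grows from 10 to 15 to 20 pN.

**Free energies.** Umbrella windows V(ξ) + ½k(ξ−ξ_c)² are sampled with
overdamped Langevin dynamics and combined with the standard self-consistent
WHAM equations; profiles from the binding and unbinding directions are
averaged after re-zeroing at the shared recognition state, and the
bound–recognition and recognition–unbound segments stitch into a full
three-state profile with a total ΔG.

## A worked example

```
$ python examples/force_helicity_table.py
Conditional helicity matrix (% of post-burn-in frames with run >= L and e2e >= 3 nm)
            10 pN  15 pN  20 pN
run length
>= 4         91.3   51.4    8.8
>= 8         88.9   44.0    4.7
>= 12        81.1   32.7    2.1
>= 16        62.5   20.0    0.6
>= 20        27.4    6.7    0.1

10 pN: e2e 3.26 ± 0.06 nm, >= 3 nm 100.0% of frames; helicity (run >= 4) 91.3%; helical content 70.6%
15 pN: e2e 3.94 ± 0.33 nm, >= 3 nm 100.0% of frames; helicity (run >= 4) 51.4%; helical content 32.3%
20 pN: e2e 4.95 ± 0.22 nm, >= 3 nm 100.0% of frames; helicity (run >= 4) 8.8%; helical content 4.0%
```

Each cell is the percentage of simulation time (after a 1000 ns burn-in)
that the chain holds an uninterrupted α-helical run of at least L residues
while extended to 3 nm or more. Reading down a column, long runs are rarer
than short ones; reading across, load melts the helix while stretching the
chain — the qualitative signature of a helix under increasing force.

The other examples build and assign backbones (`build_and_assign.py`),
record a constant-velocity force-extension trace with its average unfolding
force (`pulling_trace.py`), and reconstruct a binding free-energy profile
whose bound→recognition ΔG agrees with direct quadrature to a fraction of a
kJ/mol (`umbrella_pmf.py`).

A thin CLI mirrors the library:

```
mechelix build-helix --n 22 --out helix.pdb
mechelix dssp --in helix.pdb --out states.tsv
mechelix simulate-hc --force 15 --frames 5000 --seed 7 --out traj.tsv
mechelix helicity --in traj.tsv --burn-in 1000 --out table.tsv
mechelix replay --manifest traj.manifest.json   # bit-identical rerun
```

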
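"""Umbrella sampling + WHAM on the surrogate binding potential.

Plans 17 harmonic windows (0.04 nm apart, 18000 kJ/(mol·nm²)), samples
each with biased Langevin dynamics, reconstructs the free-energy profile
with WHAM, and compares the bound→recognition free-energy difference with
direct numerical quadrature of the analytic potential.  The two should
agree to well under 1 kJ/mol; the neighbour overlaps confirm the windows
tile the coordinate without gaps.
"""

import numpy as np

from mechelix import (BindingPotential, ReactionCoordinate, overlap_matrix,
                      plan_windows, sample_window, wham_solve)
from mechelix.umbrella import basin_free_energy, basin_free_energy_oracle

potential = BindingPotential()  # bound well at 0.25 nm, shoulder at 0.55 nm
coord = ReactionCoordinate()

windows = plan_windows(coord, 17, 0.04, 18000.0, start=0.20)
windows = [sample_window(w, potential, 20_000, seed=300 + i)
           for i, w in enumerate(windows)]

coeffs, warn = overlap_matrix(windows)
print(f"neighbour overlaps: min {coeffs.min():.3f}, "
      f"median {np.median(coeffs):.3f}, flagged: {int(warn.sum())}")

profile = wham_solve(windows, n_bins=160)
dg = basin_free_energy(profile, 0.40, 0.80) \
    - basin_free_energy(profile, 0.20, 0.40)
dg_exact = basin_free_energy_oracle(potential, 0.40, 0.80) \
    - basin_free_energy_oracle(potential, 0.20, 0.40)
print(f"Delta G (bound -> recognition): WHAM {dg:.2f} kJ/mol, "
      f"quadrature {dg_exact:.2f} kJ/mol")
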
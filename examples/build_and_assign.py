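"""Build an ideal 22-residue α-helix, partially unwind it, and assign
secondary structure by the hydrogen-bond criterion.

The folded helix carries 20 helical residues of 22 (the termini cannot
complete two consecutive i→i+4 turns) and spans ≈ 3.2 nm between its
terminal CA atoms; unwinding the C-terminal tail removes helicity and
extends the chain.
"""

from mechelix import (assign_secondary_structure, build_ideal_helix,
                      ca_end_to_end, unwind_terminal)

helix = build_ideal_helix(22)
states = assign_secondary_structure(helix)
print(f"folded:   {states}  ({states.count('H')} H residues, "
      f"{ca_end_to_end(helix):.2f} nm end-to-end)")

for n_unwound in (5, 10, 22):
    partial = unwind_terminal(helix, n_unwound)
    s = assign_secondary_structure(partial)
    print(f"unwind {n_unwound:2d}: {s}  ({s.count('H')} H residues, "
          f"{ca_end_to_end(partial):.2f} nm end-to-end)")
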
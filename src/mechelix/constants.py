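"""Physical constants and unit bridges.

The package mixes the unit conventions of single-molecule force spectroscopy
(pN, nm) with those of simulation force fields (kJ/mol, kcal/mol, Å).  All
conversions go through the factors defined here.
"""

#: Boltzmann constant, kJ/(mol·K).
KB_KJ_MOL_K = 0.0083145

#: kB·T at 300 K, kJ/mol.
KBT_300 = 2.494

#: kcal → kJ.
KJ_PER_KCAL = 4.184

#: 1 kJ/(mol·nm) expressed in pN.
PN_PER_KJ_MOL_NM = 1.661

#: Å per nm.
ANGSTROM_PER_NM = 10.0


def kbt(temperature: float = 300.0) -> float:
    """kB·T in kJ/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return KB_KJ_MOL_K * temperature


def kbt_pn_nm(temperature: float = 300.0) -> float:
    """kB·T in pN·nm at the given temperature (K)."""
    return kbt(temperature) * PN_PER_KJ_MOL_NM


def pn_to_kj_mol_nm(force_pn: float) -> float:
    """Convert a force in pN to kJ/(mol·nm)."""
    return force_pn / PN_PER_KJ_MOL_NM


def kj_mol_nm_to_pn(force_kj: float) -> float:
    """Convert a force in kJ/(mol·nm) to pN."""
    return force_kj * PN_PER_KJ_MOL_NM
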
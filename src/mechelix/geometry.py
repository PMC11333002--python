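"""Peptide backbone construction and α-helix assignment.

Builds ideal and partially unwound backbones from internal coordinates
(bond lengths, bond angles, φ/ψ/ω dihedrals) and assigns per-residue
secondary structure with the Kabsch–Sander hydrogen-bond criterion, reduced
to the two classes the downstream analyses use: ``H`` (α-helix) and ``C``
(everything else).

Conventions
-----------
* Coordinates are Cartesian Å; end-to-end distances are reported in nm.
* Terminal capping groups are not residues: a 22-residue construct exposes
  exactly 22 residues to the assignment, and its fully folded form carries
  20 ``H`` residues (the first and last residue can never complete two
  consecutive i→i+4 turns).
* Residue 1 carries no amide hydrogen and cannot donate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ANGSTROM_PER_NM
from .errors import InvalidArgumentError, MissingAtomError

__all__ = [
    "DihedralSpec",
    "BackboneCoordinates",
    "IDEAL_HELIX",
    "EXTENDED",
    "build_ideal_helix",
    "build_backbone",
    "unwind_terminal",
    "hbond_energy",
    "assign_secondary_structure",
    "ca_end_to_end",
    "measure_dihedrals",
]

# Canonical backbone internal geometry (Å, degrees).
BOND_N_CA = 1.46
BOND_CA_C = 1.52
BOND_C_N = 1.33
BOND_C_O = 1.23
BOND_N_H = 1.00
ANGLE_N_CA_C = 110.0
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

#: Kabsch–Sander electrostatic prefactor, kcal·Å/mol (0.084 e² × 332).
KS_PREFACTOR = 27.888
#: Hydrogen-bond energy cutoff, kcal/mol.
HBOND_CUTOFF = -0.5


@dataclass(frozen=True)
class DihedralSpec:
    """A (φ, ψ) pair in degrees, each in (−180, 180]."""

    phi: float
    psi: float

    def __post_init__(self) -> None:
        for name, val in (("phi", self.phi), ("psi", self.psi)):
            if not (-180.0 < val <= 180.0):
                raise InvalidArgumentError(
                    f"{name}={val} outside (-180, 180]"
                )


IDEAL_HELIX = DihedralSpec(phi=-57.0, psi=-47.0)
EXTENDED = DihedralSpec(phi=-135.0, psi=135.0)


@dataclass
class BackboneCoordinates:
    """Per-residue N/CA/C/O (and optional amide H) positions in Å.

    ``h`` rows are NaN where no amide hydrogen exists (residue 1, or any
    residue for which placement was not requested).
    """

    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray
    h: np.ndarray
    sequence: str = ""

    def __post_init__(self) -> None:
        m = self.residue_count
        for name in ("n", "ca", "c", "o", "h"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (m, 3):
                raise InvalidArgumentError(
                    f"{name} must have shape ({m}, 3), got {arr.shape}"
                )
            setattr(self, name, arr)
        if not self.sequence:
            self.sequence = "A" * m
        if len(self.sequence) != m:
            raise InvalidArgumentError("sequence length != residue count")

    @property
    def residue_count(self) -> int:
        return len(np.asarray(self.n))

    def has_amide_h(self, i: int) -> bool:
        return bool(np.all(np.isfinite(self.h[i])))

    def copy(self) -> "BackboneCoordinates":
        return BackboneCoordinates(
            self.n.copy(), self.ca.copy(), self.c.copy(),
            self.o.copy(), self.h.copy(), self.sequence,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "BackboneCoordinates":
        """Apply a rigid-body transform (for invariance checks)."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        out = self.copy()
        for name in ("n", "ca", "c", "o", "h"):
            setattr(out, name, getattr(self, name) @ R.T + t)
        return out


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float
                ) -> np.ndarray:
    """NeRF placement: position D with |C−D| = bond, ∠(B,C,D) = angle and
    dihedral(A,B,C,D) = dihedral."""
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(chi),
        bond * np.sin(theta) * np.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phis: np.ndarray, psis: np.ndarray,
                   sequence: str = "", place_h: bool = True,
                   seed_frame: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
                   ) -> BackboneCoordinates:
    """Build an N-residue backbone from per-residue (φ, ψ) with ω = 180°.

    φ of the first residue is undefined (no preceding carbonyl) and the
    supplied value is ignored; it is kept in the array for bookkeeping.
    ``seed_frame`` optionally fixes the positions of N1/CA1/C1 so that a
    rebuild with unchanged dihedrals reproduces the original coordinates.
    """
    phis = np.asarray(phis, float)
    psis = np.asarray(psis, float)
    m = len(phis)
    if m < 2:
        raise InvalidArgumentError("need at least 2 residues")
    if len(psis) != m:
        raise InvalidArgumentError("phi/psi length mismatch")

    n = np.empty((m, 3))
    ca = np.empty((m, 3))
    c = np.empty((m, 3))
    o = np.full((m, 3), np.nan)

    if seed_frame is None:
        n[0] = [0.0, 0.0, 0.0]
        ca[0] = [BOND_N_CA, 0.0, 0.0]
        th = np.deg2rad(ANGLE_N_CA_C)
        c[0] = ca[0] + BOND_CA_C * np.array([-np.cos(th), np.sin(th), 0.0])
    else:
        n[0], ca[0], c[0] = (np.asarray(v, float) for v in seed_frame)

    for i in range(1, m):
        n[i] = _place_atom(n[i - 1], ca[i - 1], c[i - 1],
                           BOND_C_N, ANGLE_CA_C_N, psis[i - 1])
        ca[i] = _place_atom(ca[i - 1], c[i - 1], n[i],
                            BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c[i] = _place_atom(c[i - 1], n[i], ca[i],
                           BOND_CA_C, ANGLE_N_CA_C, phis[i])

    # Carbonyl O: trans to the next amide nitrogen (dihedral ψ + 180).
    for i in range(m):
        o[i] = _place_atom(n[i], ca[i], c[i],
                           BOND_C_O, ANGLE_CA_C_O, psis[i] + 180.0)

    h = np.full((m, 3), np.nan)
    coords = BackboneCoordinates(n, ca, c, o, h, sequence)
    if place_h:
        place_amide_hydrogens(coords)
    return coords


def place_amide_hydrogens(coords: BackboneCoordinates) -> None:
    """Place amide hydrogens 1.00 Å from N, anti to the bisector of the
    C(i−1)→N and CA→N directions.  Residue 1 gets none (it cannot donate)."""
    for i in range(1, coords.residue_count):
        u = coords.n[i] - coords.c[i - 1]
        v = coords.n[i] - coords.ca[i]
        d = u / np.linalg.norm(u) + v / np.linalg.norm(v)
        d /= np.linalg.norm(d)
        coords.h[i] = coords.n[i] + BOND_N_H * d


def build_ideal_helix(n_residues: int,
                      dihedrals: DihedralSpec = IDEAL_HELIX,
                      sequence: str = "") -> BackboneCoordinates:
    """Build an ideal helix (or any uniform-dihedral chain) of ``n_residues``.

    With the default (φ, ψ) = (−57°, −47°) this is the canonical α-helix:
    rise ≈ 1.5 Å per residue, and for 22 residues a CA–CA end-to-end
    distance of ≈ 3.2 nm.
    """
    if n_residues < 2:
        raise InvalidArgumentError("n_residues must be >= 2")
    phis = np.full(n_residues, dihedrals.phi)
    psis = np.full(n_residues, dihedrals.psi)
    return build_backbone(phis, psis, sequence=sequence)


def measure_dihedrals(coords: BackboneCoordinates
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Measure (φ, ψ) in degrees.  φ[0] and ψ[−1] are NaN (undefined)."""
    m = coords.residue_count
    phis = np.full(m, np.nan)
    psis = np.full(m, np.nan)
    for i in range(m):
        if i > 0:
            phis[i] = _dihedral(coords.c[i - 1], coords.n[i],
                                coords.ca[i], coords.c[i])
        if i < m - 1:
            psis[i] = _dihedral(coords.n[i], coords.ca[i],
                                coords.c[i], coords.n[i + 1])
    return phis, psis


def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.rad2deg(np.arctan2(y, x)))


def unwind_terminal(coords: BackboneCoordinates, n_cterm: int
                    ) -> BackboneCoordinates:
    """Rebuild the last ``n_cterm`` residues with extended dihedrals
    (−135°, +135°), leaving the rest of the chain untouched.

    Models the partially unfolded states of a helix under load: the
    C-terminal tail uncoils first while the N-terminal body stays helical.
    """
    m = coords.residue_count
    if not (0 <= n_cterm <= m):
        raise InvalidArgumentError(f"n_cterm={n_cterm} outside [0, {m}]")
    if n_cterm == 0:
        return coords.copy()
    phis, psis = measure_dihedrals(coords)
    # Undefined entries only feed rebuilt positions of atoms that are
    # themselves being rewritten (or none at all); any finite value works.
    phis[0] = IDEAL_HELIX.phi if np.isnan(phis[0]) else phis[0]
    psis[-1] = psis[-2] if np.isnan(psis[-1]) else psis[-1]
    start = m - n_cterm
    phis[start:] = EXTENDED.phi
    psis[start:] = EXTENDED.psi
    # ψ of the residue preceding the tail stays helical: only tail atoms move.
    return build_backbone(phis, psis, sequence=coords.sequence,
                          seed_frame=(coords.n[0], coords.ca[0], coords.c[0]))


def hbond_energy(coords: BackboneCoordinates, donor: int, acceptor: int
                 ) -> float:
    """Kabsch–Sander electrostatic hydrogen-bond energy, kcal/mol.

    E = 27.888 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) with distances in Å,
    between the amide group (N–H) of ``donor`` and the carbonyl group
    (C=O) of ``acceptor``.  An energy below −0.5 kcal/mol counts as a bond.
    """
    m = coords.residue_count
    if not (0 <= donor < m and 0 <= acceptor < m):
        raise InvalidArgumentError("residue index out of range")
    if not coords.has_amide_h(donor):
        raise MissingAtomError(f"residue {donor} has no amide hydrogen")
    if not np.all(np.isfinite(coords.o[acceptor])):
        raise MissingAtomError(f"residue {acceptor} has no carbonyl oxygen")
    nd, hd = coords.n[donor], coords.h[donor]
    ca_, oa = coords.c[acceptor], coords.o[acceptor]
    r_on = np.linalg.norm(oa - nd)
    r_ch = np.linalg.norm(ca_ - hd)
    r_oh = np.linalg.norm(oa - hd)
    r_cn = np.linalg.norm(ca_ - nd)
    return float(KS_PREFACTOR * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn))


def is_hbonded(coords: BackboneCoordinates, donor: int, acceptor: int) -> bool:
    """True when the donor→acceptor pair satisfies the −0.5 kcal/mol cutoff."""
    try:
        return hbond_energy(coords, donor, acceptor) < HBOND_CUTOFF
    except MissingAtomError:
        return False


def assign_secondary_structure(coords: BackboneCoordinates) -> str:
    """Two-class α-helix assignment by the Kabsch–Sander criterion.

    A 4-turn exists at residue i when NH(i+4)→CO(i) is hydrogen bonded;
    residues i..i+3 are ``H`` when 4-turns exist at both i−1 and i.  Every
    other residue is ``C``.  Maximal H runs therefore have length ≥ 4.
    """
    m = coords.residue_count
    if m < 5:
        raise InvalidArgumentError("need at least 5 residues to assign helix")
    turn = np.zeros(m, dtype=bool)
    for i in range(m - 4):
        turn[i] = is_hbonded(coords, i + 4, i)
    states = np.full(m, "C", dtype="U1")
    for i in range(1, m - 4):
        if turn[i - 1] and turn[i]:
            states[i:i + 4] = "H"
    return "".join(states)


def ca_end_to_end(coords: BackboneCoordinates) -> float:
    """CA(first)–CA(last) distance in nm."""
    if coords.residue_count < 2:
        raise InvalidArgumentError("need at least 2 residues")
    return float(np.linalg.norm(coords.ca[-1] - coords.ca[0])
                 / ANGSTROM_PER_NM)
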
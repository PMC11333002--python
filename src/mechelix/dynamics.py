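"""Surrogate dynamics: a force-coupled helix-coil chain and 1-D Langevin
sampling on analytic potentials.

The chain model is a Zimm–Bragg two-state-per-residue description with an
external stretching force: helical residues contribute a short rise d_h per
residue to the end-to-end distance, coil residues the force-dependent
extension of a freely jointed chain, so force shifts the helix-coil
equilibrium toward coil whenever the stretched coil is longer than the
helical rise.  The chain is evolved by Metropolis single-flip kinetic Monte
Carlo (detailed balance holds exactly); an exact transfer-matrix solution
of the same Hamiltonian serves as the equilibrium oracle.

The Langevin side integrates overdamped Euler–Maruyama dynamics on named
analytic potentials and is the workhorse behind the pulling and
umbrella-sampling emulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .constants import kbt, kbt_pn_nm, pn_to_kj_mol_nm
from .errors import ConfigurationError, InvalidArgumentError, ParseError
from .helicity import StateTrajectory, _parse_states
from .potentials import Potential

__all__ = [
    "HelixCoilParams",
    "LangevinSpec",
    "coil_extension",
    "config_energy",
    "transfer_matrix_helicity",
    "solve_propagation_weight",
    "simulate_helix_coil",
    "simulate_langevin",
]

#: Zero-force helicity the default propagation weight is solved for.  A free
#: helix-forming peptide is marginally stable: mostly helical but with
#: substantial coil fluctuation, so ~0.7 is a realistic resting helicity.
DEFAULT_ZERO_FORCE_HELICITY = 0.7

#: Floor for reported end-to-end distances (nm); the additive Gaussian noise
#: could otherwise produce non-physical non-positive distances at zero force.
_E2E_FLOOR = 0.01


@dataclass(frozen=True)
class HelixCoilParams:
    """Parameters of the force-coupled Zimm–Bragg chain.

    ``s`` is the helix propagation weight; when None it is solved so that
    the zero-force mean helicity equals ``DEFAULT_ZERO_FORCE_HELICITY``.
    ``sigma_n`` is the nucleation factor, ``d_h`` the helical rise per
    residue (nm), ``l_c``/``b`` the coil contour length per residue and Kuhn
    length (nm) of the freely jointed coil, ``force_pn`` the applied
    constant force (pN), and ``mc_step_time_ns`` the nominal time one Monte
    Carlo sweep represents.
    """

    n_residues: int = 22
    s: float | None = None
    sigma_n: float = 1e-3
    d_h: float = 0.15
    l_c: float = 0.36
    b: float = 0.55
    force_pn: float = 0.0
    temperature: float = 300.0
    e2e_noise_sd: float = 0.05
    mc_step_time_ns: float = 1.0

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise InvalidArgumentError("n_residues must be >= 1")
        if self.s is not None and self.s <= 0:
            raise InvalidArgumentError("s must be > 0")
        if not (0 < self.sigma_n <= 1):
            raise InvalidArgumentError("sigma_n must be in (0, 1]")
        if not (0 < self.d_h < self.l_c):
            raise InvalidArgumentError("require 0 < d_h < l_c")
        if self.force_pn < 0:
            raise InvalidArgumentError("force must be >= 0")
        if self.temperature <= 0:
            raise InvalidArgumentError("temperature must be > 0")
        if self.s is None:
            object.__setattr__(
                self, "s",
                solve_propagation_weight(self, DEFAULT_ZERO_FORCE_HELICITY))

    def with_force(self, force_pn: float) -> "HelixCoilParams":
        return replace(self, force_pn=force_pn)


def coil_extension(force_pn: float, params: HelixCoilParams) -> float:
    """Mean extension per coil residue (nm) of a freely jointed chain:
    d_c = l_c · (coth x − 1/x) with x = F·b / kB·T; 0 at zero force."""
    if force_pn < 0:
        raise InvalidArgumentError("force must be >= 0")
    if force_pn == 0:
        return 0.0
    x = force_pn * params.b / kbt_pn_nm(params.temperature)
    if x < 1e-6:
        return params.l_c * x / 3.0  # Langevin function small-x limit
    return params.l_c * (1.0 / np.tanh(x) - 1.0 / x)


def _count_runs(helix: np.ndarray) -> int:
    h = np.asarray(helix, bool)
    if h.size == 0:
        return 0
    return int(h[0]) + int(np.sum(h[1:] & ~h[:-1]))


def config_energy(config: str, params: HelixCoilParams) -> float:
    """Energy (kJ/mol) of one helix/coil configuration:

    E = −kB·T [n_H ln s + n_runs ln σ] − F (n_H d_h + n_C d_c(F))

    with the force term converted from pN·nm to kJ/mol.  exp(−E/kB·T) is the
    Boltzmann weight of the configuration.
    """
    helix = _parse_states(config)
    if len(config) != params.n_residues:
        raise ParseError(
            f"config length {len(config)} != n_residues {params.n_residues}")
    n_h = int(helix.sum())
    n_c = params.n_residues - n_h
    n_runs = _count_runs(helix)
    kt = kbt(params.temperature)
    e = -kt * (n_h * np.log(params.s) + n_runs * np.log(params.sigma_n))
    d_c = coil_extension(params.force_pn, params)
    e -= pn_to_kj_mol_nm(params.force_pn) * (n_h * params.d_h + n_c * d_c)
    return float(e)


def effective_propagation_weight(params: HelixCoilParams) -> float:
    """s_eff = s · exp[F (d_h − d_c) / kB·T]: the force-dressed propagation
    weight after absorbing the configuration-independent coil term."""
    d_c = coil_extension(params.force_pn, params)
    x = params.force_pn * (params.d_h - d_c) / kbt_pn_nm(params.temperature)
    return float(params.s * np.exp(x))


def transfer_matrix_helicity(params: HelixCoilParams) -> float:
    """Exact mean helicity ⟨n_H⟩/N of the finite force-coupled chain.

    Propagates the 2-state partition vector together with its n_H-weighted
    companion, renormalising each step for numerical stability.
    """
    s_eff = effective_propagation_weight(params)
    sig = params.sigma_n
    n = params.n_residues
    # (Z, S) per terminal state; S accumulates Σ weight·n_H.
    z_h, z_c = sig * s_eff, 1.0
    s_h, s_c = sig * s_eff, 0.0
    for _ in range(n - 1):
        nz_h = s_eff * z_h + sig * s_eff * z_c
        ns_h = s_eff * (s_h + z_h) + sig * s_eff * (s_c + z_c)
        nz_c = z_h + z_c
        ns_c = s_h + s_c
        norm = nz_h + nz_c
        z_h, z_c = nz_h / norm, nz_c / norm
        s_h, s_c = ns_h / norm, ns_c / norm
    return float((s_h + s_c) / (z_h + z_c) / n)


def solve_propagation_weight(params: HelixCoilParams,
                             target_helicity: float) -> float:
    """Solve for the propagation weight s giving the requested zero-force
    mean helicity (bisection on the monotone transfer-matrix solution)."""
    if not (0 < target_helicity < 1):
        raise InvalidArgumentError("target helicity must be in (0, 1)")
    base = replace(params, s=1.0, force_pn=0.0)

    def theta(s: float) -> float:
        return transfer_matrix_helicity(replace(base, s=s))

    lo, hi = 1e-3, 1e3
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if theta(mid) < target_helicity:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def simulate_helix_coil(params: HelixCoilParams, n_frames: int,
                        frame_stride: int = 10, seed: int = 0,
                        production: bool = True) -> StateTrajectory:
    """Metropolis single-flip kinetic Monte Carlo of the helix-coil chain.

    The chain starts fully helical (a folded start, so an initial unfolding
    transient is expected and can be discarded as burn-in).  One frame is
    recorded every ``frame_stride`` sweeps; the frame time step is
    ``frame_stride · mc_step_time_ns``.  The per-frame end-to-end distance
    is n_H·d_h + n_C·d_c(F) plus Gaussian noise, floored at 0.01 nm.
    """
    if n_frames < 1:
        raise InvalidArgumentError("n_frames must be >= 1")
    if frame_stride < 1:
        raise InvalidArgumentError("frame_stride must be >= 1")
    n = params.n_residues
    rng = np.random.default_rng(seed)
    field_h = float(np.log(effective_propagation_weight(params)))
    ln_sigma = float(np.log(params.sigma_n))

    helix = np.ones(n, dtype=np.uint8)
    frames = np.empty((n_frames, n), dtype=bool)
    flips_per_frame = frame_stride * n
    for f in range(n_frames):
        sites = rng.integers(0, n, size=flips_per_frame)
        uniforms = rng.random(flips_per_frame)
        _kernels.hc_flips(helix, sites, uniforms, field_h, ln_sigma)
        frames[f] = helix.astype(bool)

    n_h = frames.sum(axis=1)
    d_c = coil_extension(params.force_pn, params)
    e2e = n_h * params.d_h + (n - n_h) * d_c
    e2e = e2e + params.e2e_noise_sd * rng.standard_normal(n_frames)
    e2e = np.maximum(e2e, _E2E_FLOOR)

    dt = frame_stride * params.mc_step_time_ns
    times = dt * np.arange(1, n_frames + 1)
    return StateTrajectory(
        times, frames, e2e, force_pn=params.force_pn,
        label=f"helix-coil F={params.force_pn:g} pN seed={seed}",
        production=production)


@dataclass(frozen=True)
class LangevinSpec:
    """Overdamped Langevin integrator configuration.

    ``friction`` γ in kJ·ns/(mol·nm²), ``dt`` in ns, ``external_force_pn``
    a constant tilt in pN, ``temperature`` in K (0 allowed: deterministic
    gradient descent), ``x0`` the starting coordinate (nm).
    """

    potential: Potential
    friction: float = 1.0
    dt: float = 1e-4
    external_force_pn: float = 0.0
    temperature: float = 300.0
    x0: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.friction <= 0:
            raise InvalidArgumentError("friction must be > 0")
        if self.dt <= 0:
            raise InvalidArgumentError("dt must be > 0")
        if self.temperature < 0:
            raise InvalidArgumentError("temperature must be >= 0")


def _check_stability(spec: LangevinSpec, extra_curvature: float = 0.0,
                     lo: float | None = None, hi: float | None = None) -> None:
    curv = spec.potential.max_curvature(lo, hi) + extra_curvature
    if spec.dt * curv / spec.friction >= 0.1:
        raise ConfigurationError(
            f"unstable integration: dt·max|V''|/γ = "
            f"{spec.dt * curv / spec.friction:.3g} >= 0.1; reduce dt")


def _run_langevin(spec: LangevinSpec, n_steps: int, record_stride: int,
                  bias_k: float = 0.0, bias_z0: float = 0.0,
                  bias_v: float = 0.0, t0: float = 0.0,
                  x0: float | None = None, seed: int | None = None,
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shared driver: returns (times_ns, positions, spring_force_kJ_mol_nm)."""
    if n_steps < 1:
        raise InvalidArgumentError("n_steps must be >= 1")
    _check_stability(spec, extra_curvature=bias_k)
    n_frames = n_steps // record_stride
    if n_frames < 1:
        raise InvalidArgumentError("n_steps smaller than record_stride")
    n_used = n_frames * record_stride
    kt = kbt(spec.temperature) if spec.temperature > 0 else 0.0
    noise = np.sqrt(2.0 * kt * spec.dt / spec.friction)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    normals = (rng.standard_normal(n_used) if noise > 0
               else np.zeros(n_used))
    pid, pp = spec.potential.encode()
    out_x = np.empty(n_frames)
    out_f = np.empty(n_frames)
    fext = pn_to_kj_mol_nm(spec.external_force_pn)
    _kernels.langevin_run(
        float(spec.x0 if x0 is None else x0), normals, spec.dt,
        spec.friction, noise, pid, pp, fext, bias_k, bias_z0, bias_v,
        t0, record_stride, out_x, out_f)
    times = t0 + spec.dt * record_stride * np.arange(1, n_frames + 1)
    return times, out_x, out_f


def simulate_langevin(spec: LangevinSpec, n_steps: int,
                      record_stride: int = 1
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Unbiased overdamped Langevin trajectory on ``spec.potential``.

    Returns (times_ns, positions_nm), recorded every ``record_stride``
    steps.  Reproducible for a given ``spec.seed``.
    """
    times, xs, _ = _run_langevin(spec, n_steps, record_stride)
    return times, xs
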
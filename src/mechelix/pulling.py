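"""Steered-pulling protocols and force-profile analysis.

Two protocols are emulated on the surrogate systems:

* **constant-velocity** pulling, where a harmonic spring whose anchor moves
  at a fixed velocity is attached to the system's extension coordinate and
  the spring force is recorded against time and extension;
* **constant-force** production runs, which delegate to the helix-coil
  simulator and feed the helicity analyses unchanged.

The headline statistic is the average unfolding force: the time-average of
the smoothed spring force over the extension range up to a stated maximum
(default 6.4 nm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .constants import kbt, kj_mol_nm_to_pn, pn_to_kj_mol_nm
from .dynamics import (HelixCoilParams, LangevinSpec, _run_langevin,
                       coil_extension, simulate_helix_coil)
from .errors import (ConfigurationError, InsufficientTraceError,
                     InvalidArgumentError)
from .helicity import StateTrajectory

__all__ = [
    "PullingProtocol",
    "ForceExtensionTrace",
    "UnfoldingForceSpec",
    "constant_velocity_pull",
    "average_unfolding_force",
    "constant_force_run",
    "smooth_trace",
]


@dataclass(frozen=True)
class PullingProtocol:
    """Pulling protocol parameters.

    Exactly one of ``velocity_nm_ns`` (constant-velocity mode) or
    ``constant_force_pn`` (constant-force mode) must be set for the chosen
    mode.  ``spring_constant`` in kJ/(mol·nm²).  The terminal restraint of
    the reference setup (40 kJ/(mol·nm²) on the termini, transverse only)
    has no Cartesian counterpart in the 1-D surrogate and is carried as
    metadata.
    """

    mode: str = "constant-velocity"
    velocity_nm_ns: float | None = 0.01
    spring_constant: float = 1000.0
    constant_force_pn: float | None = None
    terminal_restraint_k: float = 40.0
    duration_ns: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("constant-velocity", "constant-force"):
            raise InvalidArgumentError(f"unknown mode {self.mode!r}")
        if self.spring_constant <= 0:
            raise InvalidArgumentError("spring_constant must be > 0")
        if self.mode == "constant-velocity":
            if self.velocity_nm_ns is None:
                raise InvalidArgumentError(
                    "constant-velocity mode requires a velocity")
            if self.constant_force_pn is not None:
                raise InvalidArgumentError(
                    "constant-velocity mode must not set constant_force")
            if self.velocity_nm_ns < 0:
                raise InvalidArgumentError("velocity must be >= 0")
        else:
            if self.constant_force_pn is None:
                raise InvalidArgumentError(
                    "constant-force mode requires constant_force")
            if self.constant_force_pn < 0:
                raise InvalidArgumentError("constant_force must be >= 0")


@dataclass
class ForceExtensionTrace:
    """Time (ns), extension (nm) and spring force (pN) series."""

    times_ns: np.ndarray
    extension_nm: np.ndarray
    force_pn: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times_ns = np.asarray(self.times_ns, float)
        self.extension_nm = np.asarray(self.extension_nm, float)
        self.force_pn = np.asarray(self.force_pn, float)
        n = len(self.times_ns)
        if self.extension_nm.shape != (n,) or self.force_pn.shape != (n,):
            raise InvalidArgumentError("trace column lengths must match")
        if n > 1 and not np.all(np.diff(self.times_ns) > 0):
            raise InvalidArgumentError("times must be strictly increasing")
        if not np.all(np.isfinite(self.force_pn)):
            raise InvalidArgumentError("forces must be finite")

    @property
    def dt_ns(self) -> float:
        return float(np.median(np.diff(self.times_ns)))


@dataclass(frozen=True)
class UnfoldingForceSpec:
    """Extension range and smoothing for the average unfolding force."""

    extension_max_nm: float = 6.4
    smoothing_window_ns: float = 1.0

    def __post_init__(self) -> None:
        if self.extension_max_nm <= 0:
            raise InvalidArgumentError("extension_max must be > 0")
        if self.smoothing_window_ns < 0:
            raise InvalidArgumentError("smoothing window must be >= 0")


def constant_velocity_pull(system: HelixCoilParams | LangevinSpec,
                           protocol: PullingProtocol,
                           n_frames: int = 2000,
                           ) -> ForceExtensionTrace:
    """Pull the system with a moving harmonic spring.

    The bias U(t) = ½k(ξ − ξ₀ − v·t)² is added to the system energy; the
    recorded force is k(ξ₀ + v·t − ξ) in pN.  For a Langevin system ξ is
    the particle coordinate; for the helix-coil chain it is the noiseless
    model end-to-end distance, with the coil extension per residue slaved
    to the instantaneous spring force.
    """
    if protocol.mode != "constant-velocity":
        raise ConfigurationError("protocol mode must be constant-velocity")
    if isinstance(system, LangevinSpec):
        return _cv_pull_langevin(system, protocol, n_frames)
    if isinstance(system, HelixCoilParams):
        return _cv_pull_helix_coil(system, protocol, n_frames)
    raise InvalidArgumentError(f"unsupported system type {type(system)!r}")


def _cv_pull_langevin(spec: LangevinSpec, protocol: PullingProtocol,
                      n_frames: int) -> ForceExtensionTrace:
    duration = protocol.duration_ns
    if duration is None:
        raise ConfigurationError(
            "duration_ns must be set for a Langevin constant-velocity pull")
    n_steps = max(n_frames, int(round(duration / spec.dt)))
    stride = max(1, n_steps // n_frames)
    times, xs, f_kj = _run_langevin(
        spec, n_steps, record_stride=stride,
        bias_k=protocol.spring_constant, bias_z0=spec.x0,
        bias_v=protocol.velocity_nm_ns, seed=protocol.seed)
    return ForceExtensionTrace(
        times, xs, kj_mol_nm_to_pn(f_kj),
        label=f"cv-pull v={protocol.velocity_nm_ns:g} nm/ns "
              f"k={protocol.spring_constant:g}")


def _cv_pull_helix_coil(params: HelixCoilParams, protocol: PullingProtocol,
                        n_frames: int) -> ForceExtensionTrace:
    n = params.n_residues
    v = protocol.velocity_nm_ns
    k = protocol.spring_constant
    duration = protocol.duration_ns
    if duration is None:
        # extend from the folded length to ~90% of the coil contour; beyond
        # that the freely jointed coil stiffens sharply and the spring force
        # diverges without adding information
        duration = (n * (0.9 * params.l_c - params.d_h)) / v
    frame_dt = duration / n_frames
    sweeps_per_frame = max(1, int(round(frame_dt / params.mc_step_time_ns)))
    rng = np.random.default_rng(protocol.seed)
    beta = 1.0 / kbt(params.temperature)
    ln_s = float(np.log(params.s))
    ln_sigma = float(np.log(params.sigma_n))

    helix = np.ones(n, dtype=np.uint8)
    z0 = n * params.d_h
    times = np.empty(n_frames)
    exts = np.empty(n_frames)
    forces = np.empty(n_frames)

    def consistent_e2e(n_h: int, target: float) -> float:
        """Quasi-static end-to-end distance: the coil extension per residue
        is set by the spring tension, which itself depends on e2e; the
        fixed point is unique (both maps are monotone) and bracketed by the
        all-compact and all-stretched limits."""
        n_c = n - n_h
        lo = n_h * params.d_h
        hi = n_h * params.d_h + n_c * params.l_c
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            f_pn = max(kj_mol_nm_to_pn(k * (target - mid)), 0.0)
            g = n_h * params.d_h + n_c * coil_extension(f_pn, params)
            if g > mid:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    for fidx in range(n_frames):
        t = (fidx + 1) * frame_dt
        target = z0 + v * t
        n_h = int(helix.sum())
        e2e = consistent_e2e(n_h, target)
        f_pn = max(kj_mol_nm_to_pn(k * (target - e2e)), 0.0)
        d_c = coil_extension(f_pn, params)
        sites = rng.integers(0, n, size=sweeps_per_frame * n)
        uniforms = rng.random(sweeps_per_frame * n)
        _kernels.hc_pull_flips(
            helix, sites, uniforms, ln_s, ln_sigma, beta,
            k, target, params.d_h, d_c, e2e)
        e2e = consistent_e2e(int(helix.sum()), target)
        times[fidx] = t
        exts[fidx] = e2e
        forces[fidx] = kj_mol_nm_to_pn(k * (target - e2e))
    return ForceExtensionTrace(
        times, exts, forces,
        label=f"cv-pull helix-coil v={v:g} nm/ns k={k:g}")


def smooth_trace(trace: ForceExtensionTrace, window_ns: float
                 ) -> np.ndarray:
    """Centered moving average of the force with edge truncation.

    The window is converted to an odd number of samples; near the edges the
    average runs over the samples actually available, so the mean of the
    smoothed series equals the mean of the raw series.
    """
    if window_ns <= 0:
        return trace.force_pn.copy()
    half = int(round(window_ns / trace.dt_ns / 2))
    if half < 1:
        return trace.force_pn.copy()
    w = 2 * half + 1
    kern = np.ones(w)
    num = np.convolve(trace.force_pn, kern, mode="same")
    den = np.convolve(np.ones_like(trace.force_pn), kern, mode="same")
    return num / den


def average_unfolding_force(trace: ForceExtensionTrace,
                            spec: UnfoldingForceSpec = UnfoldingForceSpec(),
                            ) -> float:
    """Time-average of the smoothed spring force over all samples whose
    extension is at most ``extension_max_nm``."""
    if float(np.max(trace.extension_nm)) < spec.extension_max_nm:
        raise InsufficientTraceError(
            f"trace only reaches {np.max(trace.extension_nm):.3g} nm "
            f"< extension_max {spec.extension_max_nm:g} nm")
    smoothed = smooth_trace(trace, spec.smoothing_window_ns)
    mask = trace.extension_nm <= spec.extension_max_nm
    return float(np.mean(smoothed[mask]))


def constant_force_run(params: HelixCoilParams, protocol: PullingProtocol,
                       n_frames: int = 5000, frame_stride: int = 10,
                       ) -> StateTrajectory:
    """Constant-force production run: the helix-coil chain simulated at the
    protocol's force.  Output feeds the helicity analyses unchanged."""
    if protocol.mode != "constant-force":
        raise ConfigurationError("protocol mode must be constant-force")
    run_params = params.with_force(protocol.constant_force_pn)
    return simulate_helix_coil(run_params, n_frames, frame_stride,
                               seed=protocol.seed, production=True)
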
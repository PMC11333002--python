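"""Umbrella sampling and WHAM free-energy reconstruction.

Implements the binding free-energy workflow: planning linearly spaced
harmonic umbrella windows along a 1-D reaction coordinate, biased Langevin
sampling of each window on a surrogate binding potential, the standard
self-consistent WHAM estimator, neighbour-overlap diagnostics, averaging of
forward (binding) and reverse (unbinding) profiles, and stitching of the
bound–recognition and recognition–unbound segments into one profile with a
total binding free energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import quad
from scipy.special import logsumexp

from .constants import kbt
from .dynamics import LangevinSpec, _run_langevin
from .errors import (AlignmentError, ConfigurationError,
                     DisconnectedHistogramError, InvalidArgumentError)
from .potentials import Potential

__all__ = [
    "UmbrellaWindow",
    "ReactionCoordinate",
    "PMFProfile",
    "plan_windows",
    "sample_window",
    "wham_solve",
    "overlap_matrix",
    "bidirectional_average",
    "stitch_segments",
    "basin_free_energy",
    "basin_free_energy_oracle",
]

#: Neighbour-overlap coefficient below which a pair is flagged.
OVERLAP_WARN = 0.03


@dataclass
class UmbrellaWindow:
    """One harmonic umbrella window.

    ``spring_constant`` is in kJ/(mol·nm²); 0 denotes an unbiased window
    (plain equilibrium sampling).  ``samples`` are reaction-coordinate
    values (nm) at uniform time spacing, after discarding equilibration.
    """

    center: float
    spring_constant: float
    samples: np.ndarray = field(default_factory=lambda: np.empty(0))
    equilibration_discard_ns: float = 0.0

    def __post_init__(self) -> None:
        if self.spring_constant < 0:
            raise InvalidArgumentError("spring_constant must be >= 0")
        self.samples = np.asarray(self.samples, float)

    def bias_energy(self, xi: np.ndarray) -> np.ndarray:
        return 0.5 * self.spring_constant * (np.asarray(xi) - self.center) ** 2


@dataclass(frozen=True)
class ReactionCoordinate:
    """1-D binding coordinate with its three state anchors (nm)."""

    label: str = "binding coordinate"
    xi_min: float = 0.0
    xi_max: float = 1.3
    xi_bound: float = 0.25
    xi_recognition: float = 0.55
    xi_unbound: float = 1.0

    def __post_init__(self) -> None:
        ok = (self.xi_min <= self.xi_bound < self.xi_recognition
              < self.xi_unbound <= self.xi_max)
        if not ok:
            raise InvalidArgumentError(
                "anchors must satisfy xi_min <= bound < recognition "
                "<= unbound <= xi_max")


@dataclass
class PMFProfile:
    """Free energy (kJ/mol) on a fixed reaction-coordinate grid (nm).

    ``free_energy`` is NaN on bins without samples; on supported bins the
    minimum over the reference neighbourhood is zero.
    """

    grid: np.ndarray
    free_energy: np.ndarray
    counts: np.ndarray
    reference: float = 0.0  # coordinate value where the profile is zeroed

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, float)
        self.free_energy = np.asarray(self.free_energy, float)
        self.counts = np.asarray(self.counts)
        if not (len(self.grid) == len(self.free_energy) == len(self.counts)):
            raise InvalidArgumentError("grid/free_energy/counts length mismatch")

    @property
    def supported(self) -> np.ndarray:
        return self.counts > 0

    def value_at(self, xi: float) -> float:
        """Free energy at the supported grid point nearest to ``xi``."""
        idx = np.where(self.supported)[0]
        if idx.size == 0:
            raise InvalidArgumentError("profile has no supported bins")
        j = idx[np.argmin(np.abs(self.grid[idx] - xi))]
        return float(self.free_energy[j])

    def rezeroed(self, xi: float) -> "PMFProfile":
        shift = self.value_at(xi)
        return PMFProfile(self.grid.copy(), self.free_energy - shift,
                          self.counts.copy(), reference=xi)


def plan_windows(coord: ReactionCoordinate, n_windows: int, spacing: float,
                 spring_constant: float, start: float | None = None
                 ) -> list[UmbrellaWindow]:
    """Linearly spaced windows: centers start, start+spacing, …

    ``start`` defaults to the coordinate's lower bound anchor region
    (xi_min + spacing).  Raises when the span leaves the coordinate range.
    """
    if n_windows < 2:
        raise InvalidArgumentError("n_windows must be >= 2")
    if spacing <= 0:
        raise InvalidArgumentError("spacing must be > 0")
    if start is None:
        start = coord.xi_min + spacing
    last = start + (n_windows - 1) * spacing
    if start < coord.xi_min or last > coord.xi_max:
        raise ConfigurationError(
            f"window span [{start}, {last}] exceeds coordinate range "
            f"[{coord.xi_min}, {coord.xi_max}]")
    return [UmbrellaWindow(center=start + i * spacing,
                           spring_constant=spring_constant)
            for i in range(n_windows)]


def sample_window(window: UmbrellaWindow, potential: Potential,
                  n_samples: int, seed: int, dt: float = 2e-6,
                  friction: float = 1.0, temperature: float = 300.0,
                  equilibration_steps: int | None = None,
                  sample_stride: int = 5) -> UmbrellaWindow:
    """Langevin sampling of V(ξ) + ½k(ξ − center)².

    Integrates with time step ``dt`` (ns), discards an equilibration
    segment (default: 10% of the production length), then records
    ``n_samples`` values every ``sample_stride`` steps.
    """
    if n_samples < 1:
        raise InvalidArgumentError("n_samples must be >= 1")
    if equilibration_steps is None:
        equilibration_steps = max(1000, n_samples * sample_stride // 10)
    spec = LangevinSpec(potential, friction=friction, dt=dt,
                        temperature=temperature, x0=window.center, seed=seed)
    n_steps = equilibration_steps + n_samples * sample_stride
    _, xs, _ = _run_langevin(
        spec, n_steps, record_stride=1,
        bias_k=window.spring_constant, bias_z0=window.center)
    samples = xs[equilibration_steps:][sample_stride - 1::sample_stride]
    out = replace(window)
    out.samples = samples[:n_samples]
    out.equilibration_discard_ns = equilibration_steps * dt
    return out


def _histogram_grid(windows: list[UmbrellaWindow], n_bins: int
                    ) -> tuple[np.ndarray, np.ndarray]:
    lo = min(float(np.min(w.samples)) for w in windows)
    hi = max(float(np.max(w.samples)) for w in windows)
    pad = 1e-9 * max(1.0, abs(hi))
    edges = np.linspace(lo - pad, hi + pad, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return edges, centers


def wham_solve(windows: list[UmbrellaWindow], n_bins: int = 200,
               tolerance: float = 1e-6, max_iter: int = 100_000,
               temperature: float = 300.0, reference: float | None = None,
               residual_history: list[float] | None = None,
               ) -> PMFProfile:
    """Self-consistent WHAM estimate of the unbiased free-energy profile.

    Iterates the standard coupled equations

        P(ξ_b) ∝ Σ_i n_i(ξ_b) / Σ_i N_i exp[(f_i − U_i(ξ_b))/kB·T]
        f_i    = −kB·T ln Σ_b P(ξ_b) exp[−U_i(ξ_b)/kB·T]

    until max|Δf_i| < ``tolerance`` (kJ/mol), then A(ξ) = −kB·T ln P(ξ)
    shifted so that its minimum (or the value at ``reference``) is zero.
    Bins without samples are left NaN, never interpolated.
    """
    if not windows:
        raise InvalidArgumentError("need at least one window")
    for w in windows:
        if w.samples.size < 100:
            raise InvalidArgumentError(
                "each window must retain at least 100 samples")
    kt = kbt(temperature)
    edges, centers = _histogram_grid(windows, n_bins)
    n_w = len(windows)
    hist = np.zeros((n_w, n_bins))
    for i, w in enumerate(windows):
        hist[i], _ = np.histogram(w.samples, bins=edges)
    counts = hist.sum(axis=0)
    n_i = hist.sum(axis=1)

    _check_connected(windows, hist)

    # log bias factors: (n_w, n_bins)
    log_c = -np.array([w.bias_energy(centers) for w in windows]) / kt
    log_n_i = np.log(n_i)
    log_hist_tot = np.where(counts > 0, np.log(np.maximum(counts, 1)), -np.inf)

    f = np.zeros(n_w)  # window free energies, kJ/mol
    for _ in range(max_iter):
        # log denominator per bin
        log_den = logsumexp(log_n_i[:, None] + f[:, None] / kt + log_c,
                            axis=0)
        log_p = log_hist_tot - log_den            # unnormalized ln P
        with np.errstate(invalid="ignore"):
            log_zi = logsumexp(np.where(np.isfinite(log_p),
                                        log_p + log_c, -np.inf), axis=1)
        f_new = -kt * log_zi
        f_new -= f_new[0]
        delta = float(np.max(np.abs(f_new - f)))
        if residual_history is not None:
            residual_history.append(delta)
        f = f_new
        if delta < tolerance:
            break
    else:
        import warnings
        warnings.warn(
            f"WHAM did not converge within {max_iter} iterations; "
            f"residual {delta:.3g} kJ/mol", RuntimeWarning)

    log_den = logsumexp(log_n_i[:, None] + f[:, None] / kt + log_c, axis=0)
    log_p = log_hist_tot - log_den
    a = np.where(np.isfinite(log_p), -kt * log_p, np.nan)
    profile = PMFProfile(centers, a, counts)
    if reference is not None:
        return profile.rezeroed(reference)
    a -= np.nanmin(a)
    return PMFProfile(centers, a, counts)


def _check_connected(windows: list[UmbrellaWindow], hist: np.ndarray) -> None:
    if len(windows) < 2:
        return
    order = np.argsort([w.center for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        if not np.any((hist[a] > 0) & (hist[b] > 0)):
            raise DisconnectedHistogramError(
                f"windows at {windows[a].center:g} and {windows[b].center:g} "
                f"nm share no occupied bins")


def overlap_matrix(windows: list[UmbrellaWindow], n_bins: int = 100
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram overlap coefficient Σ_b min(p_b, q_b) for each adjacent
    window pair (ordered by center).  Returns (coefficients, warn_flags);
    a pair is flagged when its overlap falls below 0.03."""
    if len(windows) < 2:
        raise InvalidArgumentError("need at least 2 windows")
    ws = sorted(windows, key=lambda w: w.center)
    edges, _ = _histogram_grid(ws, n_bins)
    ps = []
    for w in ws:
        h, _ = np.histogram(w.samples, bins=edges)
        ps.append(h / max(1, h.sum()))
    coeffs = np.array([np.minimum(p, q).sum() for p, q in zip(ps[:-1], ps[1:])])
    return coeffs, coeffs < OVERLAP_WARN


def bidirectional_average(forward: PMFProfile, reverse: PMFProfile,
                          anchor: float) -> PMFProfile:
    """Average the binding (forward) and unbinding (reverse) profiles.

    Both are re-zeroed at the shared ``anchor`` (the recognition state, the
    boundary common to the two directions) and averaged pointwise; bins
    supported in only one input keep that input's value.
    """
    if forward.grid.shape != reverse.grid.shape or \
            not np.allclose(forward.grid, reverse.grid):
        raise AlignmentError("profiles are on different grids")
    fwd = forward.rezeroed(anchor)
    rev = reverse.rezeroed(anchor)
    a = np.nanmean(np.vstack([fwd.free_energy, rev.free_energy]), axis=0)
    counts = fwd.counts + rev.counts
    return PMFProfile(fwd.grid.copy(), a, counts, reference=anchor)


def stitch_segments(bound_recognition: PMFProfile,
                    recognition_unbound: PMFProfile,
                    anchor: float, xi_bound: float, xi_unbound: float,
                    ) -> tuple[PMFProfile, float]:
    """Join the two profile segments at the shared recognition anchor.

    The second segment is shifted so both agree at the anchor; grids are
    concatenated (the first segment wins on overlapping coordinates).
    Returns the stitched profile and ΔG_total = A(unbound) − A(bound).
    """
    try:
        a1 = bound_recognition.value_at(anchor)
        a2 = recognition_unbound.value_at(anchor)
    except InvalidArgumentError as exc:
        raise AlignmentError("segments lack support at the anchor") from exc
    for prof, name in ((bound_recognition, "bound-recognition"),
                       (recognition_unbound, "recognition-unbound")):
        g = prof.grid[prof.supported]
        if not (g.min() - 1e-9 <= anchor <= g.max() + 1e-9):
            raise AlignmentError(
                f"{name} segment does not reach the anchor {anchor:g} nm")
    shift = a1 - a2
    g2 = recognition_unbound.free_energy + shift
    keep = recognition_unbound.grid > bound_recognition.grid.max()
    grid = np.concatenate([bound_recognition.grid,
                           recognition_unbound.grid[keep]])
    a = np.concatenate([bound_recognition.free_energy, g2[keep]])
    counts = np.concatenate([bound_recognition.counts,
                             recognition_unbound.counts[keep]])
    order = np.argsort(grid)
    stitched = PMFProfile(grid[order], a[order], counts[order],
                          reference=bound_recognition.reference)
    dg_total = stitched.value_at(xi_unbound) - stitched.value_at(xi_bound)
    return stitched, float(dg_total)


def basin_free_energy(profile: PMFProfile, lo: float, hi: float,
                      temperature: float = 300.0) -> float:
    """Basin free energy −kB·T ln ∫ exp(−A/kB·T) dξ over supported bins of
    [lo, hi]."""
    kt = kbt(temperature)
    m = (profile.grid >= lo) & (profile.grid <= hi) & profile.supported
    if not np.any(m):
        raise InvalidArgumentError(f"no supported bins in [{lo}, {hi}]")
    dx = np.median(np.diff(profile.grid))
    return float(-kt * (logsumexp(-profile.free_energy[m] / kt)
                        + np.log(dx)))


def basin_free_energy_oracle(potential: Potential, lo: float, hi: float,
                             temperature: float = 300.0) -> float:
    """Quadrature oracle: −kB·T ln ∫_lo^hi exp(−V(ξ)/kB·T) dξ."""
    kt = kbt(temperature)
    val, _ = quad(lambda x: np.exp(-potential.value(x) / kt), lo, hi,
                  limit=400)
    return float(-kt * np.log(val))


def binned_potential_oracle(potential: Potential, grid: np.ndarray,
                            temperature: float = 300.0) -> np.ndarray:
    """Bin-integrated reference profile −kB·T ln ∫_bin exp(−V/kB·T) dξ on
    the same grid a histogram PMF uses (removes mid-point discretization
    bias when comparing a histogram estimate against an analytic V)."""
    kt = kbt(temperature)
    grid = np.asarray(grid, float)
    dx = np.median(np.diff(grid))
    out = np.empty_like(grid)
    for j, c in enumerate(grid):
        val, _ = quad(lambda x: np.exp(-potential.value(x) / kt),
                      c - dx / 2, c + dx / 2, limit=200)
        out[j] = -kt * np.log(val / dx)
    return out
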
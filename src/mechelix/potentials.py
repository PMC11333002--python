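"""Analytic 1-D potentials for the surrogate Langevin dynamics.

Each potential exposes its value and gradient (kJ/mol, kJ/mol/nm as a
function of a coordinate in nm), an id/parameter encoding consumed by the
integrator kernels, and a nominal domain used for curvature-based stability
checks and for quadrature oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["Potential", "Flat", "Harmonic", "DoubleWell", "BindingPotential",
           "make_potential"]

# integer ids understood by the integrator kernels
PID_FLAT = 0
PID_HARMONIC = 1
PID_DOUBLE_WELL = 2
PID_BINDING = 3


@dataclass(frozen=True)
class Potential:
    """Base class; subclasses define value/grad and a kernel encoding."""

    def value(self, x):
        raise NotImplementedError

    def grad(self, x):
        raise NotImplementedError

    def encode(self) -> tuple[int, np.ndarray]:
        raise NotImplementedError

    @property
    def domain(self) -> tuple[float, float]:
        raise NotImplementedError

    def max_curvature(self, lo: float | None = None,
                      hi: float | None = None, n: int = 2001) -> float:
        """max |V''| over [lo, hi] estimated on a fine grid."""
        d0, d1 = self.domain
        lo = d0 if lo is None else lo
        hi = d1 if hi is None else hi
        x = np.linspace(lo, hi, n)
        g = self.grad(x)
        return float(np.max(np.abs(np.gradient(g, x))))


@dataclass(frozen=True)
class Flat(Potential):
    """V = 0 everywhere."""

    def value(self, x):
        return np.zeros_like(np.asarray(x, float))

    def grad(self, x):
        return np.zeros_like(np.asarray(x, float))

    def encode(self):
        return PID_FLAT, np.zeros(1)

    @property
    def domain(self):
        return (-10.0, 10.0)


@dataclass(frozen=True)
class Harmonic(Potential):
    """V = ½ k (x − x0)², k in kJ/(mol·nm²)."""

    k: float
    x0: float = 0.0

    def __post_init__(self):
        if self.k <= 0:
            raise InvalidArgumentError("k must be > 0")

    def value(self, x):
        return 0.5 * self.k * (np.asarray(x, float) - self.x0) ** 2

    def grad(self, x):
        return self.k * (np.asarray(x, float) - self.x0)

    def encode(self):
        return PID_HARMONIC, np.array([self.k, self.x0])

    @property
    def domain(self):
        w = 5.0 * np.sqrt(1.0 / self.k) + 1.0
        return (self.x0 - w, self.x0 + w)


@dataclass(frozen=True)
class DoubleWell(Potential):
    """V = h ((x − c)²/a² − 1)²: minima at c ± a, barrier height h at c."""

    height: float = 5.0
    half_separation: float = 0.5
    center: float = 0.0

    def __post_init__(self):
        if self.height <= 0 or self.half_separation <= 0:
            raise InvalidArgumentError("height and half_separation must be > 0")

    def value(self, x):
        u = (np.asarray(x, float) - self.center) / self.half_separation
        return self.height * (u * u - 1.0) ** 2

    def grad(self, x):
        u = (np.asarray(x, float) - self.center) / self.half_separation
        return 4.0 * self.height * u * (u * u - 1.0) / self.half_separation

    def encode(self):
        return PID_DOUBLE_WELL, np.array(
            [self.height, self.half_separation, self.center])

    @property
    def domain(self):
        return (self.center - 1.6 * self.half_separation,
                self.center + 1.6 * self.half_separation)


@dataclass(frozen=True)
class BindingPotential(Potential):
    """Three-state binding surrogate along a 1-D coordinate ξ (nm).

    A deep Gaussian bound basin at ξ_b, a shallow Gaussian recognition
    shoulder at ξ_r, and a flat unbound plateau beyond ~1 nm:

        V(ξ) = −D_b exp[−(ξ−ξ_b)²/2w²] − D_r exp[−(ξ−ξ_r)²/2w²]
    """

    depth_bound: float = 40.0
    depth_recognition: float = 10.0
    xi_bound: float = 0.25
    xi_recognition: float = 0.55
    width: float = 0.05
    xi_unbound: float = 1.0

    def value(self, x):
        x = np.asarray(x, float)
        g = lambda c: np.exp(-((x - c) ** 2) / (2 * self.width ** 2))
        return -self.depth_bound * g(self.xi_bound) \
            - self.depth_recognition * g(self.xi_recognition)

    def grad(self, x):
        x = np.asarray(x, float)
        w2 = self.width ** 2
        g = lambda c: np.exp(-((x - c) ** 2) / (2 * w2))
        return (self.depth_bound * (x - self.xi_bound) / w2 * g(self.xi_bound)
                + self.depth_recognition * (x - self.xi_recognition) / w2
                * g(self.xi_recognition))

    def encode(self):
        return PID_BINDING, np.array(
            [self.depth_bound, self.depth_recognition,
             self.xi_bound, self.xi_recognition, self.width])

    @property
    def domain(self):
        return (0.0, self.xi_unbound + 0.3)


_NAMED = {
    "flat": Flat,
    "harmonic": Harmonic,
    "double-well": DoubleWell,
    "binding": BindingPotential,
    "binding-surrogate": BindingPotential,
}


def make_potential(name: str, **kwargs) -> Potential:
    """Construct a named potential (``harmonic``, ``double-well``,
    ``binding``, ``flat``) with keyword parameters."""
    try:
        cls = _NAMED[name]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown potential {name!r}; choices: {sorted(_NAMED)}") from None
    return cls(**kwargs)
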
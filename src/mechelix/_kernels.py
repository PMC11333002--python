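"""Inner simulation loops.

Plain-Python implementations, JIT-compiled with numba when available.  Both
paths consume pre-generated random-number arrays, so results are independent
of which path runs.
"""

from __future__ import annotations

import math

import numpy as np


def _hc_flips(helix, sites, uniforms, field_h, ln_sigma):
    """Metropolis single-flip sweep segment of the helix-coil chain.

    ``helix`` (uint8, modified in place) is the per-residue state, 1 = H.
    Reduced energy: βE = −n_H·field_h − n_runs·ln_sigma + const, where
    ``field_h`` folds together the propagation weight and the force coupling.
    Boundary residues see coil neighbours.
    """
    n = helix.shape[0]
    for t in range(sites.shape[0]):
        i = sites[t]
        left = helix[i - 1] if i > 0 else 0
        right = helix[i + 1] if i < n - 1 else 0
        d_runs = 1 - left - right  # for a C->H flip
        if helix[i] == 0:
            d_beta_e = -(field_h + d_runs * ln_sigma)
        else:
            d_beta_e = field_h + d_runs * ln_sigma
        if d_beta_e <= 0.0 or uniforms[t] < math.exp(-d_beta_e):
            helix[i] = 1 - helix[i]


def _hc_pull_flips(helix, sites, uniforms, ln_s, ln_sigma, beta,
                   k_spring, target, d_h, d_c, e2e):
    """Metropolis flips of the helix-coil chain under a harmonic spring on
    the (noiseless) end-to-end distance.  ``k_spring`` in kJ/(mol·nm²),
    ``beta`` in mol/kJ.  Returns the updated end-to-end distance."""
    n = helix.shape[0]
    for t in range(sites.shape[0]):
        i = sites[t]
        left = helix[i - 1] if i > 0 else 0
        right = helix[i + 1] if i < n - 1 else 0
        d_runs = 1 - left - right
        if helix[i] == 0:
            dn = 1.0
            d_runs_signed = float(d_runs)
        else:
            dn = -1.0
            d_runs_signed = -float(d_runs)
        d_e2e = dn * (d_h - d_c)
        new_e2e = e2e + d_e2e
        d_bias = 0.5 * k_spring * ((new_e2e - target) ** 2
                                   - (e2e - target) ** 2)
        d_beta_e = -(dn * ln_s + d_runs_signed * ln_sigma) + beta * d_bias
        if d_beta_e <= 0.0 or uniforms[t] < math.exp(-d_beta_e):
            helix[i] = 1 - helix[i]
            e2e = new_e2e
    return e2e


def _grad(pid, pp, x):
    if pid == 1:  # harmonic: k, x0
        return pp[0] * (x - pp[1])
    if pid == 2:  # double well: h, a, c
        u = (x - pp[2]) / pp[1]
        return 4.0 * pp[0] * u * (u * u - 1.0) / pp[1]
    if pid == 3:  # binding: Db, Dr, xb, xr, w
        w2 = pp[4] * pp[4]
        gb = math.exp(-((x - pp[2]) ** 2) / (2.0 * w2))
        gr = math.exp(-((x - pp[3]) ** 2) / (2.0 * w2))
        return pp[0] * (x - pp[2]) / w2 * gb + pp[1] * (x - pp[3]) / w2 * gr
    return 0.0


def _langevin_run(x0, normals, dt, gamma, noise_scale, pid, pp,
                  fext, bias_k, bias_z0, bias_v, t0, record_stride,
                  out_x, out_f):
    """Overdamped Euler–Maruyama with an optional (moving) harmonic bias.

    Records position and instantaneous spring force (kJ/mol/nm) every
    ``record_stride`` steps; returns the final position.
    """
    x = x0
    step = 0
    nf = out_x.shape[0]
    inv_gamma = dt / gamma
    for fidx in range(nf):
        for _ in range(record_stride):
            t = t0 + step * dt
            z = bias_z0 + bias_v * t
            force = -_grad(pid, pp, x) + fext + bias_k * (z - x)
            x = x + force * inv_gamma + noise_scale * normals[step]
            step += 1
        out_x[fidx] = x
        z = bias_z0 + bias_v * (t0 + step * dt)
        out_f[fidx] = bias_k * (z - x)
    return x


try:  # pragma: no cover - exercised implicitly
    import numba

    _grad = numba.njit(cache=True)(_grad)
    hc_flips = numba.njit(cache=True)(_hc_flips)
    hc_pull_flips = numba.njit(cache=True)(_hc_pull_flips)
    langevin_run = numba.njit(cache=True)(_langevin_run)
except Exception:  # pragma: no cover
    hc_flips = _hc_flips
    hc_pull_flips = _hc_pull_flips
    langevin_run = _langevin_run
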
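"""Surrogate helix-coil chain and Langevin integrator."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from mechelix.constants import kbt, kbt_pn_nm, pn_to_kj_mol_nm
from mechelix.dynamics import (HelixCoilParams, LangevinSpec, coil_extension,
                               config_energy, effective_propagation_weight,
                               simulate_helix_coil, simulate_langevin,
                               solve_propagation_weight,
                               transfer_matrix_helicity)
from mechelix.errors import ConfigurationError, InvalidArgumentError
from mechelix.potentials import Flat, Harmonic
from mechelix.stats import blocked_sem


def enumerate_boltzmann(params: HelixCoilParams) -> dict[str, float]:
    """Exact Boltzmann distribution over all 2^N configurations."""
    n = params.n_residues
    kt = kbt(params.temperature)
    weights = {}
    for bits in itertools.product("CH", repeat=n):
        config = "".join(bits)
        weights[config] = np.exp(-config_energy(config, params) / kt)
    z = sum(weights.values())
    return {c: w / z for c, w in weights.items()}


class TestCoilExtension:
    def test_zero_force(self):
        assert coil_extension(0.0, HelixCoilParams()) == 0.0

    def test_saturation(self):
        p = HelixCoilParams()
        assert coil_extension(1e5, p) == pytest.approx(p.l_c, rel=1e-3)

    def test_langevin_function_at_unity(self):
        """x = 1: coth(1) − 1 ≈ 0.3130."""
        p = HelixCoilParams()
        f_at_x1 = kbt_pn_nm(p.temperature) / p.b
        expected = (1 / np.tanh(1.0) - 1.0) * p.l_c
        assert coil_extension(f_at_x1, p) == pytest.approx(expected, rel=1e-9)
        assert expected / p.l_c == pytest.approx(0.313, abs=0.001)


class TestConfigEnergy:
    def test_all_coil(self):
        p = HelixCoilParams(n_residues=6, s=2.0, force_pn=12.0)
        d_c = coil_extension(12.0, p)
        expected = -pn_to_kj_mol_nm(12.0) * 6 * d_c
        assert config_energy("CCCCCC", p) == pytest.approx(expected)

    def test_uniform_ensemble(self):
        p = HelixCoilParams(n_residues=5, s=1.0, sigma_n=1.0, force_pn=0.0)
        for config in ("CCCCC", "HHHHH", "HCHCH", "CHHHC"):
            assert config_energy(config, p) == pytest.approx(0.0, abs=1e-12)

    def test_factorizes_as_transfer_matrix_weights(self):
        """exp(−E/kB·T) equals σ^runs · s_eff^{n_H} up to the
        configuration-independent coil stretching factor (N ≤ 10 by full
        enumeration)."""
        p = HelixCoilParams(n_residues=8, s=1.7, sigma_n=0.05, force_pn=14.0)
        kt = kbt(p.temperature)
        s_eff = effective_propagation_weight(p)
        d_c = coil_extension(p.force_pn, p)
        const = np.exp(pn_to_kj_mol_nm(p.force_pn) * p.n_residues * d_c / kt)
        for bits in itertools.product("CH", repeat=8):
            config = "".join(bits)
            n_h = config.count("H")
            n_runs = len([r for r in config.split("C") if r])
            w = np.exp(-config_energy(config, p) / kt)
            assert w == pytest.approx(
                const * s_eff ** n_h * p.sigma_n ** n_runs, rel=1e-9)


class TestTransferMatrix:
    def test_symmetric_independent_sites(self):
        p = HelixCoilParams(n_residues=10, s=1.0, sigma_n=1.0)
        assert transfer_matrix_helicity(p) == pytest.approx(0.5)

    def test_strong_propagation_limit(self):
        p = HelixCoilParams(n_residues=10, s=1e8, sigma_n=1e-3)
        assert transfer_matrix_helicity(p) == pytest.approx(1.0, abs=1e-4)

    def test_matches_full_enumeration(self):
        p = HelixCoilParams(n_residues=12, s=2.0, sigma_n=0.01)
        probs_p = HelixCoilParams(n_residues=12, s=2.0, sigma_n=0.01)
        # brute-force ⟨n_H⟩ over all 4096 configurations
        dist = enumerate_boltzmann(probs_p)
        mean_nh = sum(prob * c.count("H") for c, prob in dist.items())
        assert transfer_matrix_helicity(p) == \
            pytest.approx(mean_nh / 12, rel=1e-9)

    def test_force_monotone_where_coil_longer(self):
        p = HelixCoilParams()
        forces = [12.0, 14.0, 16.0, 18.0, 20.0]  # d_c > d_h throughout
        helicities = [transfer_matrix_helicity(p.with_force(f))
                      for f in forces]
        assert all(a > b for a, b in zip(helicities, helicities[1:]))

    def test_solved_weight_hits_target(self):
        p = HelixCoilParams()
        assert transfer_matrix_helicity(p) == pytest.approx(0.7, abs=1e-6)
        s = solve_propagation_weight(p, 0.4)
        p2 = HelixCoilParams(s=s)
        assert transfer_matrix_helicity(p2) == pytest.approx(0.4, abs=1e-6)


class TestSimulateHelixCoil:
    def test_seed_determinism(self):
        p = HelixCoilParams(force_pn=15.0)
        a = simulate_helix_coil(p, 200, 5, seed=11)
        b = simulate_helix_coil(p, 200, 5, seed=11)
        assert np.array_equal(a.helix, b.helix)
        assert np.array_equal(a.e2e_nm, b.e2e_nm)

    def test_dominant_helical_state(self):
        p = HelixCoilParams(s=1e6, sigma_n=0.5)
        traj = simulate_helix_coil(p, 200, 5, seed=2)
        assert traj.helix.all()
        # e2e ≈ N · d_h before noise
        assert traj.e2e_nm.mean() == pytest.approx(22 * 0.15, abs=0.05)

    @pytest.mark.parametrize("force", [0.0, 15.0])
    def test_mean_helicity_matches_oracle(self, force):
        p = HelixCoilParams(force_pn=force)
        traj = simulate_helix_coil(p, 6000, 10, seed=3)
        theta = traj.helix[500:].mean(axis=1)
        sem = blocked_sem(theta, 40)
        exact = transfer_matrix_helicity(p)
        assert abs(theta.mean() - exact) < 3 * sem + 1e-4

    def test_equilibrium_distribution_chi2(self):
        """Empirical configuration frequencies of an 8-residue chain match
        the exactly enumerated Boltzmann distribution (χ², α = 0.01)."""
        p = HelixCoilParams(n_residues=8, s=2.0, sigma_n=0.01)
        traj = simulate_helix_coil(p, 12_000, 20, seed=5)
        frames = traj.helix[500:]
        keys = ["".join("H" if b else "C" for b in row) for row in frames]
        dist = enumerate_boltzmann(p)
        observed, expected = [], []
        rare_o = rare_e = 0.0
        n = len(keys)
        from collections import Counter
        counts = Counter(keys)
        for config, prob in dist.items():
            e = prob * n
            o = counts.get(config, 0)
            if e >= 5:
                observed.append(o)
                expected.append(e)
            else:
                rare_o += o
                rare_e += e
        observed.append(rare_o)
        expected.append(rare_e)
        chi2, pval = sps.chisquare(observed, expected)
        assert pval > 0.01


class TestLangevin:
    def test_zero_temperature_relaxation(self):
        pot = Harmonic(k=20.0, x0=0.0)
        spec = LangevinSpec(pot, friction=2.0, dt=1e-4, temperature=0.0,
                            x0=1.0, seed=0)
        times, xs = simulate_langevin(spec, 20_000, record_stride=100)
        expected = np.exp(-pot.k * times / spec.friction)
        assert np.allclose(xs, expected, atol=1e-3)

    def test_flat_potential_drift(self):
        spec = LangevinSpec(Flat(), friction=1.0, dt=1e-3, temperature=0.0,
                            external_force_pn=10.0, seed=0)
        times, xs = simulate_langevin(spec, 5000, record_stride=50)
        f_kj = pn_to_kj_mol_nm(10.0)
        assert np.allclose(xs, f_kj * times / spec.friction, rtol=1e-9)

    def test_harmonic_boltzmann_statistics(self):
        """Long harmonic run: position distribution is Gaussian with
        variance kB·T/k (KS test)."""
        k = 10.0
        spec = LangevinSpec(Harmonic(k=k), dt=1e-3, seed=42)
        _, xs = simulate_langevin(spec, 400_000)
        xs = xs[4000::40]  # decorrelate: ~4 relaxation times apart
        sd = np.sqrt(kbt() / k)
        _, pval = sps.kstest(xs, "norm", args=(0.0, sd))
        assert pval > 0.01

    def test_instability_rejected(self):
        spec = LangevinSpec(Harmonic(k=1e6), dt=1e-3, seed=0)
        with pytest.raises(ConfigurationError):
            simulate_langevin(spec, 100)

    def test_seed_determinism(self):
        spec = LangevinSpec(Harmonic(k=5.0), dt=1e-3, seed=9)
        _, a = simulate_langevin(spec, 1000)
        _, b = simulate_langevin(spec, 1000)
        assert np.array_equal(a, b)


class TestValidation:
    def test_bad_params(self):
        with pytest.raises(InvalidArgumentError):
            HelixCoilParams(sigma_n=0.0)
        with pytest.raises(InvalidArgumentError):
            HelixCoilParams(d_h=0.5, l_c=0.36)
        with pytest.raises(InvalidArgumentError):
            HelixCoilParams(force_pn=-1.0)
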
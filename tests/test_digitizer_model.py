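import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from digitizer_lab import (
    CellDose, Topology, copies_from_fluorescence, nondimensional_groups,
    ptre_flux, shrna_flux, simulate_cell, simulate_population, titrate_flux,
)
from digitizer_lab.digitizer_model import _endpoint_true


def equilibrium_titration(m, s, K):
    """Independent oracle: numeric root of the two-species mass-action
    steady state (turnover delta, pairing rate k = delta**2 / K; the free
    flux is delta * M at steady state)."""
    if K == 0:
        return max(0.0, m - s)
    delta, k = 1.0, 1.0 / K  # K = delta**2 / k

    def g(M):
        S = M - (m - s) / delta
        return m - delta * M - k * M * S

    lo = max(0.0, (m - s) / delta)
    hi = m / delta
    if g(hi) >= 0:
        return m
    return delta * brentq(g, lo, hi, xtol=1e-300, rtol=1e-15)


class TestFluxes:
    def test_ptre_leak_saturation_midpoint(self, params):
        assert math.isclose(float(ptre_flux(0.0, 3, params)), 3 * params.a_f)
        assert math.isclose(float(ptre_flux(np.inf, 3, params)), 3 * params.b_f)
        mid = float(ptre_flux(params.K_dox, 2, params))
        assert math.isclose(mid, 2 * (params.a_f + params.b_f) / 2, rel_tol=1e-12)

    def test_shrna_topologies(self, params):
        assert float(shrna_flux(100.0, 5, Topology.NO_SHRNA, params)) == 0.0
        assert math.isclose(
            float(shrna_flux(0.0, 5, Topology.CONSTANT, params)),
            float(shrna_flux(225.0, 5, Topology.CONSTANT, params)))
        assert float(shrna_flux(np.inf, 5, Topology.FEEDFORWARD, params)) == 0.0
        assert math.isclose(
            float(shrna_flux(0.0, 5, Topology.FEEDFORWARD, params)),
            5 * params.b_s, rel_tol=1e-12)

    def test_titration_identities(self):
        assert math.isclose(float(titrate_flux(10.0, 0.0, 5.0)), 10.0,
                            rel_tol=1e-12)
        assert math.isclose(float(titrate_flux(10.0, 4.0, 1e-14)), 6.0,
                            abs_tol=1e-6)
        assert float(titrate_flux(4.0, 10.0, 1e-14)) < 1e-6
        assert math.isclose(float(titrate_flux(10.0, 10.0, 5.0)), 5.0,
                            rel_tol=1e-12)

    def test_titration_matches_equilibrium_root(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(1000):
            m = 10.0 ** rng.uniform(-2, 2)
            s = 10.0 ** rng.uniform(-2, 2)
            K = 10.0 ** rng.uniform(-3, 2)
            got = float(titrate_flux(m, s, K))
            want = equilibrium_titration(m, s, K)
            worst = max(worst, abs(got - want) / max(want, 1e-30))
        assert worst < 1e-8

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.floats(0.0, 1e3), st.floats(0.0, 1e3), st.floats(1e-9, 1e3))
    def test_titration_bounds(self, m, s, K):
        out = float(titrate_flux(m, s, K))
        assert 0.0 <= out <= m + 1e-9 * max(m, 1.0)
        assert out >= m - s - 1e-9 * max(m, 1.0)


class TestSimulateCell:
    def grid(self):
        return np.linspace(0.0, 96.0, 49)

    def test_no_production_stays_dark(self, params, platform):
        p = replace(params, a_f=0.0)
        dose = CellDose(10, 5, 50, 20, 4.0)
        traj = simulate_cell(dose, 0.0, Topology.CONSTANT, p, platform, self.grid())
        assert np.all(traj.F == 0) and np.all(traj.r == 0) and np.all(traj.ofp == 0)

    def test_no_recombination_when_c_zero(self, params, platform):
        p = replace(params, c=0.0)
        dose = CellDose(10, 0, 50, 20, 4.0)
        traj = simulate_cell(dose, 225.0, Topology.NO_SHRNA, p, platform, self.grid())
        assert np.all(traj.r == 0) and np.all(traj.ofp == 0)
        assert traj.F[-1] > 0

    def test_over_repression_quenches_output(self, params, platform):
        p = replace(params, b_s=100.0, K_d=1e-3)
        dose = CellDose(10, 20, 50, 20, 4.0)
        quenched = simulate_cell(dose, 225.0, Topology.CONSTANT, p, platform,
                                 self.grid())
        free = simulate_cell(replace(dose, copies_shrna=0), 225.0,
                             Topology.NO_SHRNA, p, platform, self.grid())
        assert quenched.ofp[-1] < 0.01 * free.ofp[-1]

    def test_recombined_fraction_monotone_in_unit_interval(self, params, platform):
        dose = CellDose(20, 8, 60, 20, 2.0)
        traj = simulate_cell(dose, 225.0, Topology.CONSTANT, params, platform,
                             self.grid())
        assert np.all(np.diff(traj.r) >= -1e-12)
        assert np.all((traj.r >= 0) & (traj.r <= 1))

    def test_more_shrna_never_raises_output(self, params, platform):
        base = CellDose(15, 4, 60, 20, 3.0)
        lo = simulate_cell(base, 8.0, Topology.CONSTANT, params, platform,
                           self.grid())
        hi = simulate_cell(replace(base, copies_shrna=12), 8.0,
                           Topology.CONSTANT, params, platform, self.grid())
        assert np.all(hi.ofp <= lo.ofp + 1e-9)

    def test_zero_shrna_copies_match_no_shrna_topology(self, params, platform):
        dose = CellDose(15, 0, 60, 20, 3.0)
        for topo in (Topology.CONSTANT, Topology.FEEDFORWARD):
            a = simulate_cell(dose, 8.0, topo, params, platform, self.grid())
            b = simulate_cell(dose, 8.0, Topology.NO_SHRNA, params, platform,
                              self.grid())
            np.testing.assert_allclose(a.ofp, b.ofp, rtol=1e-9, atol=1e-12)

    def test_vectorized_endpoint_matches_reference_integrator(self, params,
                                                              platform):
        rng = np.random.default_rng(0)
        for _ in range(5):
            dose = CellDose(int(rng.integers(1, 30)), int(rng.integers(0, 20)),
                            int(rng.integers(10, 80)), int(rng.integers(5, 40)),
                            float(rng.uniform(0, 12)))
            dox = float(rng.choice([0.0, 3.0, 225.0]))
            traj = simulate_cell(dose, dox, Topology.CONSTANT, params, platform,
                                 np.linspace(0, 48.0, 25))
            m0 = ptre_flux(dox, dose.copies_flp, params)
            s0 = shrna_flux(dox, dose.copies_shrna, Topology.CONSTANT, params)
            ifp, ofp, _ = _endpoint_true(
                np.atleast_1d(m0), np.atleast_1d(s0),
                np.array([float(dose.copies_reporter)]),
                np.array([float(dose.copies_cfp)]),
                np.array([dose.delay_h]), params, platform, 48.0)
            assert math.isclose(ofp[0], traj.ofp[-1],
                                rel_tol=1e-3, abs_tol=1e-6)
            assert math.isclose(ifp[0], traj.ifp[-1], rel_tol=1e-9, abs_tol=1e-9)


class TestSimulatePopulation:
    def test_deterministic_given_seed(self, params, platform, uptake):
        doses = {"flp": 35, "shrna": 5, "reporter": 100, "cfp": 50}
        a = simulate_population(500, doses, 225.0, Topology.CONSTANT, params,
                                platform, uptake, t=48.0, seed=5)
        b = simulate_population(500, doses, 225.0, Topology.CONSTANT, params,
                                platform, uptake, t=48.0, seed=5)
        assert a.data.equals(b.data)

    def test_no_circuit_reads_background(self, params, platform, uptake):
        doses = {"flp": 0, "shrna": 0, "reporter": 100, "cfp": 50}
        pop = simulate_population(400, doses, 225.0, Topology.NO_SHRNA, params,
                                  platform, uptake, t=48.0, seed=6)
        # IFP and OFP carry only the autofluorescence background
        assert np.median(pop.channel("ifp")) < 10 * uptake.autofluorescence_mu
        assert np.median(pop.channel("ofp")) < 10 * uptake.autofluorescence_mu
        assert np.median(pop.channel("cfp")) > 100 * uptake.autofluorescence_mu

    def test_induction_raises_output_geomean(self, params, platform, uptake):
        doses = {"flp": 35, "shrna": 5, "reporter": 100, "cfp": 50}
        on = simulate_population(800, doses, 225.0, Topology.CONSTANT, params,
                                 platform, uptake, t=48.0, seed=7)
        off = simulate_population(800, doses, 0.0, Topology.CONSTANT, params,
                                  platform, uptake, t=48.0, seed=8)
        gm = lambda pop: np.exp(np.mean(np.log(pop.channel("ofp"))))
        assert gm(on) > 10 * gm(off)


class TestNondimensional:
    def test_ekd_scalings(self, params):
        dose = CellDose(10, 0, 50, 20, 0.0)
        base = nondimensional_groups(params, dose).eKd
        doubled_K = nondimensional_groups(replace(params, K_d=2 * params.K_d),
                                          dose).eKd
        doubled_b = nondimensional_groups(replace(params, b_f=2 * params.b_f),
                                          dose).eKd
        assert math.isclose(doubled_K, 2 * base, rel_tol=1e-12)
        assert math.isclose(doubled_b, base / 2, rel_tol=1e-12)

    def test_zero_capacity_rejected(self, params):
        with pytest.raises(ZeroDivisionError):
            nondimensional_groups(params, CellDose(0, 0, 1, 1, 0.0))

    def test_matched_groups_give_identical_scaled_trajectories(self, params,
                                                               platform):
        # double b_f and a_f, halve c: eKd, basal fraction and the scaled
        # recombination rate are unchanged, so r(delta_F * t) must agree
        p2 = replace(params, b_f=2 * params.b_f, a_f=2 * params.a_f,
                     K_d=2 * params.K_d, c=params.c / 2)
        dose = CellDose(12, 0, 50, 20, 0.0)
        grid = np.linspace(0.0, 96.0, 33)
        r1 = simulate_cell(dose, 225.0, Topology.NO_SHRNA, params, platform,
                           grid).r
        r2 = simulate_cell(dose, 225.0, Topology.NO_SHRNA, p2, platform,
                           grid).r
        np.testing.assert_allclose(r1, r2, rtol=1e-6, atol=1e-10)


class TestCopyInversion:
    def test_exact_inversion(self, platform):
        cfp = platform.gamma * 5 * (48.0 - platform.mu_delay)
        assert copies_from_fluorescence(cfp, 48.0, platform) == 5

    def test_zero(self, platform):
        assert copies_from_fluorescence(0.0, 48.0, platform) == 0

    def test_round_trip_over_copy_range(self, platform):
        for copies in range(1, 101):
            cfp = platform.gamma * copies * (72.0 - platform.mu_delay)
            assert copies_from_fluorescence(cfp, 72.0, platform) == copies

    def test_undefined_before_onset(self, platform):
        with pytest.raises(ValueError):
            copies_from_fluorescence(100.0, platform.mu_delay, platform)
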
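import math

import numpy as np
import pytest

from ionphase import constants
from ionphase.rgrpa import (EnergyParams, SolutionState,
                            _variational_free_energy, bjerrum_length,
                            chemical_potentials_pressure, chi,
                            contact_energetics, free_energy,
                            reduced_temperature, renormalized_kuhn, stability)
from ionphase.seqcharge import ChargeSequence

NEUTRAL = ChargeSequence(sigma=(0,))


def neutral_params(**kw):
    defaults = dict(epsilon_r=80.5, eps_h=0.0, eps_s=0.0)
    defaults.update(kw)
    return EnergyParams(**defaults)


class TestBjerrumLength:
    def test_direct_constant_evaluation(self):
        # independent evaluation from CODATA constants
        e, eps0, kb = 1.602176634e-19, 8.8541878128e-12, 1.380649e-23
        expected = e**2 / (4 * math.pi * eps0 * 80.5 * kb * 300.0) * 1e10
        assert bjerrum_length(300.0, 80.5) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(6.93, abs=0.05)

    def test_inverse_temperature_scaling(self):
        assert bjerrum_length(600.0, 80.5) == pytest.approx(
            bjerrum_length(300.0, 80.5) / 2.0)

    def test_large_permittivity_limit(self):
        assert bjerrum_length(300.0, 1e12) < 1e-9

    def test_nonphysical(self):
        with pytest.raises(ValueError):
            bjerrum_length(-5.0, 80.0)


class TestReducedTemperatureChi:
    def test_ratio_convention(self):
        # T* = l/lB: engineered case where lB = 2 l
        p = EnergyParams(epsilon_r=80.5)
        t = 300.0
        lb = bjerrum_length(t, 80.5)
        assert reduced_temperature(t, p) == pytest.approx(3.8 / lb)

    def test_monotone_in_T(self):
        p = EnergyParams()
        ts = [200.0, 250.0, 300.0, 400.0]
        vals = [reduced_temperature(t, p) for t in ts]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_chi_formula(self):
        p = EnergyParams(epsilon_r=80.5)
        tstar = reduced_temperature(300.0, p)
        assert chi(300.0, 1.0, 0.0, p) == pytest.approx(1.0 / tstar)
        assert chi(300.0, 1.0, -1.5, p) == pytest.approx(1.0 / tstar - 1.5)

    def test_chi_decreasing_in_T(self):
        p = EnergyParams()
        assert chi(250.0, 1.0, 0.0, p) > chi(350.0, 1.0, 0.0, p)

    def test_chi_high_T_limit(self):
        assert chi(1e9, 1.0, -1.5) == pytest.approx(-1.5, abs=1e-3)


class TestContactEnergetics:
    def test_entropy_conversion(self):
        _, ds = contact_energetics(1.0, -1.5)
        assert ds == pytest.approx(-3.0, abs=0.02)

    def test_enthalpy_conversion(self):
        dh, _ = contact_energetics(1.0, 0.0, T_ref=300.0, epsilon_r=80.5)
        assert dh == pytest.approx(-1.1, abs=0.05)

    def test_zero_enthalpy(self):
        dh, ds = contact_energetics(0.0, 0.0)
        assert dh == 0.0 and ds == 0.0

    def test_enthalpy_temperature_independent(self):
        # lB ~ 1/T makes -eps_h kB T / T* constant in T
        dh1, _ = contact_energetics(1.0, 0.0, T_ref=280.0)
        dh2, _ = contact_energetics(1.0, 0.0, T_ref=320.0)
        assert dh1 == pytest.approx(dh2, rel=1e-12)


class TestRenormalizedKuhn:
    def test_ideal_limits(self, cs_wt):
        # uncharged sequence, v2 = 0
        cs0 = ChargeSequence(sigma=(0,) * 50)
        st = SolutionState(1e-4, 0.0, 0.0, 300.0)
        assert renormalized_kuhn(cs0, st, neutral_params()) == 1.0

    def test_lb_to_zero_continuous(self, cs_wt):
        st = SolutionState(1e-4, 13e-4, 0.0, 300.0)
        xs = [renormalized_kuhn(cs_wt, st,
                                EnergyParams(epsilon_r=er, eps_h=1.0))
              for er in (80.5, 8e3, 8e5, 8e8)]
        assert xs[0] > xs[1] > xs[2] > 1.0 - 1e-6
        assert xs[3] == pytest.approx(1.0, abs=1e-3)

    def test_polyelectrolyte_swells_polyampholyte_shrinks(self, cs_wt, cs_py):
        p = EnergyParams(epsilon_r=80.5)
        x_wt = renormalized_kuhn(cs_wt, SolutionState(1e-4, 13e-4, 0, 300), p)
        x_py = renormalized_kuhn(cs_py, SolutionState(1e-4, 1e-4, 0, 300), p)
        assert x_wt > 1.0 > x_py

    def test_brute_force_grid_minimizer_oracle(self, cs_wt):
        # low salt Caprin1: 1-D scan of the variational objective confirms
        # the returned minimizer
        p = EnergyParams(epsilon_r=80.5)
        st = SolutionState(1e-4, 13e-4, 0.0, 300.0)
        x_opt = renormalized_kuhn(cs_wt, st, p)
        lb = bjerrum_length(300.0, 80.5) / 3.8
        kappa2 = 4 * math.pi * lb * (13e-4)
        grid = np.linspace(0.2, 5.0, 2001)
        vals = [_variational_free_energy(x, cs_wt, lb, kappa2, 0.0, 1.0)
                for x in grid]
        x_grid = grid[int(np.argmin(vals))]
        assert x_opt == pytest.approx(x_grid, abs=3e-3)
        f_opt = _variational_free_energy(x_opt, cs_wt, lb, kappa2, 0.0, 1.0)
        assert f_opt <= min(vals) + 1e-9


class TestFreeEnergy:
    def test_neutral_ideal_reduces_to_mixing_entropy(self):
        cs0 = ChargeSequence(sigma=(0,) * 10)
        st = SolutionState(0.005, 0.0, 0.0, 300.0)
        br = free_energy(cs0, st, neutral_params())
        phi = 0.05
        expected = phi / 10 * math.log(phi) + (1 - phi) * math.log(1 - phi)
        assert br.f_el == 0.0
        assert br.f_fh == 0.0
        assert br.total == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("rho", [1e-3, 1e-4, 1e-5])
    def test_debye_hueckel_limiting_law(self, rho):
        st = SolutionState(0.0, rho, rho, 300.0)
        br = free_energy(NEUTRAL, st, neutral_params())
        lb = bjerrum_length(300.0, 80.5) / 3.8
        kappa = math.sqrt(4 * math.pi * lb * 2 * rho)
        dh = -kappa**3 / (12 * math.pi)
        tol = 0.01 if rho == 1e-5 else 0.02
        assert br.f_el == pytest.approx(dh, rel=tol)

    def test_breakdown_sums_to_total(self, cs_wt):
        st = SolutionState(1e-4, 13e-4 + 0.01, 0.01, 300.0)
        br = free_energy(cs_wt, st, EnergyParams(epsilon_r=80.5, eps_h=1.0))
        assert br.total == br.f_ideal + br.f_fh + br.f_el

    def test_f_el_nonpositive_various_states(self, cs_wt, cs_py):
        p = EnergyParams(epsilon_r=80.5)
        for cs in (cs_wt, cs_py):
            for rho_p in (1e-6, 1e-4, 2e-3):
                for rho_s in (0.0, 1e-3, 0.05):
                    rho_c = abs(cs.Q) * rho_p + rho_s
                    st = SolutionState(rho_p, rho_c, rho_s, 300.0)
                    assert free_energy(cs, st, p).f_el <= 0.0

    def test_overfilled_volume_raises(self, cs_wt):
        with pytest.raises(ValueError, match="volume fraction"):
            free_energy(cs_wt, SolutionState(0.009, 0.2, 0.1, 300.0),
                        EnergyParams())


class TestDerivatives:
    def test_finite_difference_oracle(self, cs_wt):
        # plain second-order central differences with an independent step
        p = EnergyParams(epsilon_r=80.5, eps_h=1.0)
        st = SolutionState(2e-4, 26e-4 + 0.01, 0.01, 300.0)
        mu = chemical_potentials_pressure(cs_wt, st, p)

        def f(rp, rc, rs):
            return free_energy(cs_wt, SolutionState(rp, rc, rs, 300.0), p).total

        for key, val, fn in (
                ("mu_p", st.rho_p, lambda v: f(v, st.rho_c, st.rho_s)),
                ("mu_c", st.rho_c, lambda v: f(st.rho_p, v, st.rho_s)),
                ("mu_s", st.rho_s, lambda v: f(st.rho_p, st.rho_c, v))):
            h = val * 3e-5
            fd = (fn(val + h) - fn(val - h)) / (2 * h)
            assert mu[key] == pytest.approx(fd, rel=1e-6)

    def test_ideal_dilute_limit(self):
        cs0 = ChargeSequence(sigma=(0,) * 5)
        p = neutral_params()
        rho = 1e-8
        mu1 = chemical_potentials_pressure(
            cs0, SolutionState(rho, 0, 0, 300.0), p)["mu_p"]
        mu2 = chemical_potentials_pressure(
            cs0, SolutionState(rho * 10, 0, 0, 300.0), p)["mu_p"]
        assert mu2 - mu1 == pytest.approx(math.log(10.0), rel=1e-3)

    def test_pure_solvent_zero_pressure(self):
        st = SolutionState(0.0, 0.0, 0.0, 300.0)
        assert chemical_potentials_pressure(NEUTRAL, st, neutral_params())[
            "Pi"] == pytest.approx(0.0, abs=1e-15)

    def test_gibbs_duhem_identity(self, cs_wt):
        p = EnergyParams(epsilon_r=80.5, eps_h=1.0)
        st = SolutionState(2e-4, 26e-4 + 0.01, 0.01, 300.0)
        mu = chemical_potentials_pressure(cs_wt, st, p)
        pi = (st.rho_p * mu["mu_p"] + st.rho_c * mu["mu_c"]
              + st.rho_s * mu["mu_s"] - mu["f"])
        assert mu["Pi"] == pytest.approx(pi, rel=1e-12)


class TestStability:
    def test_dilute_state_stable(self, cs_wt):
        p = EnergyParams(epsilon_r=80.5, eps_h=1.0)
        st = SolutionState(1e-7, 13e-7 + 1e-3, 1e-3, 300.0)
        assert stability(cs_wt, st, p) > 0.0

    def test_finite_difference_hessian_oracle(self, cs_wt):
        p = EnergyParams(epsilon_r=80.5, eps_h=1.0)
        T, q = 300.0, cs_wt.Q

        def f(ra, rb):
            rc = q * ra + rb
            return free_energy(cs_wt, SolutionState(ra, rc, rb, T), p).total

        ra, rb = 2e-4, 5e-3
        st = SolutionState(ra, q * ra + rb, rb, T)
        lam = stability(cs_wt, st, p)
        ha, hb = ra * 1e-3, rb * 1e-3
        faa = (f(ra + ha, rb) - 2 * f(ra, rb) + f(ra - ha, rb)) / ha**2
        fbb = (f(ra, rb + hb) - 2 * f(ra, rb) + f(ra, rb - hb)) / hb**2
        fab = (f(ra + ha, rb + hb) - f(ra + ha, rb - hb)
               - f(ra - ha, rb + hb) + f(ra - ha, rb - hb)) / (4 * ha * hb)
        ev = np.linalg.eigvalsh(np.array([[faa, fab], [fab, fbb]]))[0]
        assert lam == pytest.approx(ev, rel=5e-3)

    def test_no_instability_above_ucst(self, cs_py):
        # cross-check with the coexistence module at a high temperature
        from ionphase.coexist import has_instability
        p = EnergyParams(epsilon_r=80.5, eps_h=1.0, eps_s=-1.5)
        assert not has_instability(cs_py, p, 1e-3, 1000.0)


class TestFloryHugginsReduction:
    def test_symmetric_fh_binodal_closed_form(self):
        # all charges zero, no ions: the model is exactly FH. For N = 1 the
        # symmetric binodal solves ln(phi/(1-phi)) = 2 chi (2 phi - 1)/...
        # use the closed-form critical point instead: phi_c = 1/(1+sqrt(N)),
        # chi_c = (1+1/sqrt(N))^2/2, via the analytic second derivative.
        from ionphase.coexist import _Model
        n = 16
        cs0 = ChargeSequence(sigma=(0,) * n)
        chi_c = 0.5 * (1 + 1 / math.sqrt(n)) ** 2
        phi_c = 1.0 / (1 + math.sqrt(n))
        # choose eps_h to land chi slightly above/below chi_c at T = 300
        p_at = lambda eh: EnergyParams(epsilon_r=80.5, eps_h=eh, eps_s=0.0)
        tstar = reduced_temperature(300.0, EnergyParams(epsilon_r=80.5))
        eh_crit = chi_c * tstar
        for frac, expect_unstable in ((0.97, False), (1.03, True)):
            model = _Model(cs0, p_at(eh_crit * frac), 300.0)
            rho_c = phi_c / n
            h = rho_c * 1e-3
            d2 = (model.f(rho_c + h, 0.0) - 2 * model.f(rho_c, 0.0)
                  + model.f(rho_c - h, 0.0)) / h**2
            assert (d2 < 0) == expect_unstable
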
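"""PBPK system structure: synthesis modulation, mass balance, steady states."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from bxk.config import ConfigError, PBPKConfig
from bxk.exposure import InputError
from bxk.pbpk import AB42_COMPARTMENTS, PBPKSystem, app_synthesis_rate


class TestSynthesisRate:
    @pytest.mark.parametrize(
        "k0, x, rb, expected",
        [
            (7.0, 1.5, 0.0, 7.0),  # baseline
            (10.0, 1.5, 1.0, 25.0),  # calibrated amplification
            (3.0, 0.0, 99.0, 3.0),  # decoupled limit
        ],
    )
    def test_affine_modulation(self, k0, x, rb, expected):
        assert app_synthesis_rate(k0, x, rb) == pytest.approx(expected)

    def test_strictly_increasing_in_response(self):
        rates = [app_synthesis_rate(10.0, 1.5, rb) for rb in (0.0, 0.5, 1.0, 2.0)]
        assert np.all(np.diff(rates) > 0)

    def test_negative_response_rejected(self):
        with pytest.raises(InputError):
            app_synthesis_rate(10.0, 1.5, -0.1)


def transport_only_config() -> PBPKConfig:
    """Synthesis, degradation and upstream reactions switched off."""
    return PBPKConfig(
        k_app0=0.0,
        k_bace1=0.0,
        k_gs=0.0,
        **{f"k_deg_{c}": 0.0 for c in AB42_COMPARTMENTS},
    )


class TestMassBalance:
    def test_transport_columns_conserve_mass_exactly(self):
        """Volume-weighted column sums of transport terms vanish."""
        sys = PBPKSystem(transport_only_config())
        cols = [sys.index[f"ab42_{c}"] for c in AB42_COMPARTMENTS]
        weighted = sys.volumes @ sys.A
        assert np.allclose(weighted[cols], 0.0, atol=1e-10)

    def test_total_mass_constant_over_100_h(self, rng):
        sys = PBPKSystem(transport_only_config())
        c0 = np.zeros(sys.n)
        for c in AB42_COMPARTMENTS:
            c0[sys.index[f"ab42_{c}"]] = rng.uniform(1.0, 50.0)
        sol = solve_ivp(
            lambda t, c: sys.rhs(c, 0.0), (0, 100), c0, rtol=1e-10, atol=1e-12,
            t_eval=np.linspace(0, 100, 21),
        )
        mass = sys.volumes @ sol.y
        assert np.max(np.abs(mass - mass[0])) < 1e-8 * mass[0]

    def test_decoupled_compartments_stay_put(self):
        cfg = transport_only_config().model_copy(
            update=dict(q_br=0.0, q_per=0.0, l_br=0.0, l_per=0.0, f_bbb=0.0,
                        f_gly=0.0, k_rage=0.0, k_lrp1=0.0, k_pgp=0.0)
        )
        sys = PBPKSystem(cfg)
        c0 = np.zeros(sys.n)
        c0[sys.index["ab42_pla"]] = 12.0
        sol = solve_ivp(lambda t, c: sys.rhs(c, 0.0), (0, 50), c0, rtol=1e-10, atol=1e-12)
        assert sol.y[sys.index["ab42_pla"], -1] == pytest.approx(12.0, rel=1e-9)


class TestSteadyState:
    def test_baseline_plasma_hits_autoscaler_target(self, config):
        sys = PBPKSystem(config.pbpk)
        ss = sys.steady_state()
        assert ss[sys.plasma_index] == pytest.approx(
            config.pbpk.baseline_plasma_pg_ml, rel=1e-10
        )
        # the state is a genuine fixed point: residual RHS ~ 0
        resid = sys.rhs(ss, 0.0)
        assert np.max(np.abs(resid)) < 1e-10 * sys.k_app0

    def test_zero_synthesis_gives_zero_state(self, config):
        sys = PBPKSystem(config.pbpk.model_copy(update={"k_app0": 0.0}))
        assert np.allclose(sys.steady_state(), 0.0)

    def test_long_integration_converges_to_direct_solve(self, config):
        """Independent oracle: integrating from empty compartments reaches
        the same fixed point the linear solver returns."""
        sys = PBPKSystem(config.pbpk)
        ss = sys.steady_state()
        sol = solve_ivp(
            lambda t, c: sys.rhs(c, 0.0), (0, 3000.0), np.zeros(sys.n),
            rtol=1e-10, atol=1e-13, method="LSODA",
        )
        assert np.allclose(sol.y[:, -1], ss, rtol=1e-6, atol=1e-9 * ss.max())

    def test_doubling_synthesis_doubles_all_concentrations(self, config):
        sys1 = PBPKSystem(config.pbpk)
        k0 = sys1.k_app0
        sys2 = PBPKSystem(config.pbpk.model_copy(update={"k_app0": 2 * k0}))
        assert np.allclose(sys2.steady_state(), 2 * sys1.steady_state(), rtol=1e-6)

    def test_dead_end_compartment_named_in_error(self, config):
        bad = config.pbpk.model_copy(
            update=dict(k_bace1=0.0, k_app0=5.0)  # APP has inflow, no outflow
        )
        with pytest.raises(ConfigError, match="app_br"):
            PBPKSystem(bad).steady_state()


class TestDoseResponseAndTransporters:
    def test_sustained_response_raises_plasma_monotonically(self, config):
        sys = PBPKSystem(config.pbpk)
        levels = []
        for rb in (0.0, 0.5, 1.0, 2.0):
            b = sys.forcing(app_synthesis_rate(sys.k_app0, config.pbpk.x, rb))
            ss = np.linalg.solve(sys.A, -b)
            levels.append(ss[sys.plasma_index])
        assert np.all(np.diff(levels) > 0)

    def test_efflux_influx_asymmetry(self, config):
        base = PBPKSystem(config.pbpk.model_copy(update={"k_app0": 10.0}))
        more_efflux = PBPKSystem(
            config.pbpk.model_copy(update={"k_app0": 10.0, "k_lrp1": 2 * config.pbpk.k_lrp1})
        )
        more_influx = PBPKSystem(
            config.pbpk.model_copy(update={"k_app0": 10.0, "k_rage": 5 * config.pbpk.k_rage})
        )
        i_isf = base.index["ab42_isf"]
        ss0, ss_eff, ss_inf = (s.steady_state() for s in (base, more_efflux, more_influx))
        assert ss_eff[i_isf] < ss0[i_isf]  # stronger LRP1 drains the ISF
        assert ss_inf[i_isf] > ss0[i_isf]  # stronger RAGE loads the ISF
        # transient: extra efflux briefly raises vascular content
        i_vas = base.index["ab42_vas"]
        d0 = base.rhs(ss0, 0.0)[i_vas]
        d_eff = more_efflux.rhs(ss0, 0.0)[i_vas]
        assert d_eff > d0


class TestOptionalSpecies:
    def test_ab40_shares_c99_flux(self, config):
        cfg = config.pbpk.model_copy(update={"include_ab40": True})
        sys = PBPKSystem(cfg)
        ss = sys.steady_state()
        ab42 = ss[sys.index["ab42_isf"]]
        ab40 = ss[sys.index["ab40_isf"]]
        # same transport and clearance rates: ratio equals f_42/(1-f_42)
        assert ab42 / ab40 == pytest.approx(cfg.f_42 / (1 - cfg.f_42), rel=1e-8)

    def test_byproducts_are_inert_bookkeeping(self, config):
        cfg = config.pbpk.model_copy(update={"include_byproducts": True})
        sys = PBPKSystem(cfg)
        base = PBPKSystem(config.pbpk)
        ss = sys.steady_state()
        ss_base = base.steady_state()
        assert ss[sys.plasma_index] == pytest.approx(ss_base[base.plasma_index], rel=1e-9)
        assert ss[sys.index["sappb_br"]] > 0

    def test_saturable_transport_reduces_efflux_at_high_load(self, config):
        cfg = config.pbpk.model_copy(
            update={"saturable_transport": True, "km_transport": 10.0, "k_app0": 10.0}
        )
        sat = PBPKSystem(cfg)
        lin = PBPKSystem(config.pbpk.model_copy(update={"k_app0": 10.0}))
        ss_sat = sat.steady_state()
        ss_lin = lin.steady_state()
        # saturation throttles ISF->vascular efflux, backing Abeta up in the ISF
        assert ss_sat[sat.index["ab42_isf"]] > ss_lin[lin.index["ab42_isf"]]
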
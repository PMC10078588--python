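"""Transport, conservation, analytic limits, determinism of the simulator."""

import numpy as np
import pytest

from conftest import closed_params, make_quiet_forcing, single_box_geometry

from deltacarbon.carbon_kinetics import STATE_VARS, KineticParams
from deltacarbon.column_chain import (ChainGeometry, ChainModel, VAR_INDEX,
                                      advect_step)
from deltacarbon.forcing_synth import default_forcing


class TestGeometry:
    def test_default_chain(self):
        geo = ChainGeometry.default()
        assert geo.n_boxes == 5
        assert geo.n_layers == 10
        assert geo.interfaces == ("inflow", "pilot->delta", "delta->mouth",
                                  "mouth->plume", "plume->ocean", "export")

    def test_four_mouth_branch_weights_sum_to_one(self):
        geo = ChainGeometry.four_mouth_preset()
        assert sum(geo.branch_weights["delta->mouth"].values()) == \
            pytest.approx(1.0)

    def test_bad_branch_interface_rejected(self):
        with pytest.raises(ValueError):
            ChainGeometry(names=("a", "b"), areas=np.array([1e9, 1e9]),
                          depths=np.array([10.0, 10.0]),
                          branch_weights={"nope": {"x": 1.0}})


class TestAdvection:
    def _conc(self, geo, value=0.0):
        return np.full((len(STATE_VARS), geo.n_boxes, geo.n_layers), value)

    def test_no_flow_no_transport(self):
        geo = ChainGeometry.default()
        conc = self._conc(geo, 3.0)
        new, iface, _ = advect_step(conc, geo, 0.0, np.zeros(len(STATE_VARS)),
                                    0.01)
        np.testing.assert_array_equal(new, conc)
        assert np.all(iface == 0.0)

    def test_uniform_steady_state_fluxes_equal_qc(self):
        geo = ChainGeometry.default()
        conc = self._conc(geo, 2.0)
        q, dt = 5000.0, 0.01
        bc = np.full(len(STATE_VARS), 2.0)
        new, iface, _ = advect_step(conc, geo, q, bc, dt)
        np.testing.assert_allclose(new, conc, rtol=1e-12)
        np.testing.assert_allclose(iface, q * dt * 86400.0 * 2.0, rtol=1e-12)

    def test_pulse_mass_conserved_along_chain(self):
        """Injected pulse mass = water-column mass + cumulative export."""
        geo = ChainGeometry.default()
        conc = self._conc(geo)
        i = VAR_INDEX["cdoc_w"]
        conc[i, 0, :] = 10.0
        injected = 10.0 * geo.volumes[0]
        exported = 0.0
        bc = np.zeros(len(STATE_VARS))
        for _ in range(2000):
            conc, iface, _ = advect_step(conc, geo, 15000.0, bc, 0.05)
            exported += iface[-1, i]
        in_column = (conc[i] * geo.layer_volumes[:, None]).sum()
        assert in_column + exported == pytest.approx(injected, rel=1e-10)

    def test_cfl_violation_names_the_limiting_box(self):
        geo = ChainGeometry(names=("tiny", "big"), areas=np.array([1e4, 1e9]),
                            depths=np.array([5.0, 10.0]))
        with pytest.raises(RuntimeError, match="tiny"):
            advect_step(self._conc(geo), geo, 5000.0,
                        np.zeros(len(STATE_VARS)), 0.5)


class TestStep:
    def test_null_dynamics_leaves_state_unchanged(self, quiet_model):
        quiet_model.conc[:] = 1.5
        before = quiet_model.conc.copy()
        quiet_model.step(0)
        np.testing.assert_array_equal(quiet_model.conc, before)

    def test_closed_system_conserves_carbon_over_1000_steps(self):
        """Q = 0, dark, no settling/resuspension, all rates off except
        hydrolysis (an internal transfer): total carbon drifts < 1e-10."""
        f = make_quiet_forcing(n_days=10)
        params = closed_params(kappa_p=(0.03, 0.006))  # internal transfer on
        m = ChainModel(ChainGeometry.default(), params, f, dt=0.01,
                       spinup_days=0)
        m.conc[:] = 2.0
        c0 = m.total_carbon()
        for k in range(1000):
            m.step(min(k // 100, 9))
        assert abs(m.total_carbon() - c0) / c0 < 1e-10

    def test_labile_decay_matches_analytic_half_life(self):
        """Single box, microbial decay only: after ln2/0.025 = 27.73 days the
        labile pool is half its initial value (tolerance 1%at dt = 0.01 d)."""
        f = make_quiet_forcing(n_days=30, n_boxes=1, temperature=20.0)
        params = closed_params(kappa_c=(0.025, 0.0, 0.0))
        m = ChainModel(single_box_geometry(), params, f, dt=0.01,
                       spinup_days=0)
        i = VAR_INDEX["ncdoc1"]
        m.conc[:] = 0.0
        m.conc[i] = 1.0
        half_life = np.log(2.0) / 0.025
        n_steps = int(round(half_life / 0.01))
        for k in range(n_steps):
            m.step(int(k * 0.01))
        assert m.conc[i].mean() == pytest.approx(0.5, rel=0.01)

    def test_iss_settling_builds_benthic_pool(self, params):
        f = make_quiet_forcing(n_days=5, n_boxes=1)
        m = ChainModel(single_box_geometry(), closed_params(w_max=2.0), f,
                       dt=0.01, spinup_days=0)
        m.conc[VAR_INDEX["iss"]] = 100.0
        bed0 = m.benthic[0, 0]
        water0 = m.conc[VAR_INDEX["iss"]].sum()
        for _ in range(100):
            m.step(0)
        assert m.benthic[0, 0] > bed0
        assert m.conc[VAR_INDEX["iss"]].sum() < water0

    def test_resuspension_limited_by_benthic_pool(self):
        f = make_quiet_forcing(n_days=5, n_boxes=1, current=3.0)  # tau >> crit
        p = closed_params(benthic_init=1.0e-3)
        m = ChainModel(single_box_geometry(), p, f, dt=0.5, spinup_days=0)
        m.conc[:] = 0.0
        m.step(0)
        m.step(0)
        assert np.all(m.benthic >= -1e-15)
        lifted = sum(m.ledger.resuspension.values())
        assert lifted <= 1.0e-3 * m.geometry.areas[0] * (1.0 + 1e-12)


class TestRun:
    def test_identical_config_and_seed_is_bit_identical(self):
        outs = []
        for _ in range(2):
            f = default_forcing(seed=3, n_days=5)
            m = ChainModel(ChainGeometry.default(), KineticParams(), f,
                           dt=0.02, spinup_days=0)
            outs.append(m.run())
        a, b = outs
        for var in ("cdoc_ss", "iss", "b1", "kd_par"):
            np.testing.assert_array_equal(a.dataset[var].values,
                                          b.dataset[var].values)
        np.testing.assert_array_equal(a.fluxes.values, b.fluxes.values)

    def test_full_run_ledger_closes(self):
        f = default_forcing(seed=2, n_days=20)
        m = ChainModel(ChainGeometry.default(), KineticParams(), f, dt=0.01,
                       spinup_days=0)
        out = m.run()
        assert abs(out.closure) < 1e-6

    def test_halving_dt_changes_day90_doc_stock_below_half_percent(self):
        stocks = []
        for dt in (0.02, 0.01):
            f = default_forcing(seed=1, n_days=90)
            m = ChainModel(ChainGeometry.default(), KineticParams(), f, dt=dt,
                           spinup_days=0)
            out = m.run()
            doc_vars = ("cdoc_m", "cdoc_w", "cdoc_ss", "ncdoc1", "ncdoc2",
                        "ncdoc3")
            geo = m.geometry
            last = out.dataset.isel(time=-1)
            stock = sum((last[v].values * geo.layer_volumes[:, None]).sum()
                        for v in doc_vars)
            stocks.append(stock)
        assert abs(stocks[1] - stocks[0]) / stocks[1] < 0.005

    def test_monotone_dilution_of_conservative_tracer(self):
        """With transport only and a constant boundary, the steady profile is
        nonincreasing along the chain."""
        f = make_quiet_forcing(n_days=30, discharge=15000.0,
                               boundary={"cdoc_w": 10.0})
        m = ChainModel(ChainGeometry.default(), closed_params(), f, dt=0.05,
                       spinup_days=0)
        m.conc[:] = 0.0
        for k in range(600):
            m.step(k // 20)
        profile = m.conc[VAR_INDEX["cdoc_w"]].mean(axis=1)
        assert np.all(np.diff(profile) <= 1e-12)

    def test_nan_state_aborts_with_dump(self):
        f = make_quiet_forcing(n_days=2)
        m = ChainModel(ChainGeometry.default(), closed_params(), f, dt=0.01,
                       spinup_days=0)
        m.conc[0, 0, 0] = np.nan
        with pytest.raises(RuntimeError, match="invalid"):
            m.step(0)

    def test_output_contains_light_diagnostics(self):
        f = default_forcing(seed=0, n_days=3)
        m = ChainModel(ChainGeometry.default(), KineticParams(), f, dt=0.02,
                       spinup_days=1)
        out = m.run()
        assert set(STATE_VARS) <= set(out.dataset.data_vars)
        assert {"kd_par", "par"} <= set(out.dataset.data_vars)
        assert out.dataset.sizes == {"time": 3, "box": 5, "layer": 10}
        assert np.all(out.dataset["kd_par"].values >= 0.0)
        assert out.post_spinup.sizes["time"] == 2
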
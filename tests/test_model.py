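"""Reaction network model: geometry, equilibrium initialization, unit
conversions, deterministic/stochastic/spatial simulators and observables."""

import math

import numpy as np
import pandas as pd
import pytest

from nanotrap import model
from nanotrap.model import (DYN1BB, Geometry, ModelState, RateParams,
                            apply_stimulation, build_geometry, convert_units,
                            dyn1bb_states, equilibrium_kb, membrane_grid,
                            observables, simulate_membrane_pde, simulate_ode,
                            simulate_ssa, ssa_dyn_copies, NA_UM)


class TestGeometry:
    def test_measured_density_gives_printed_patch(self):
        g = build_geometry(0.54)
        assert g.area == pytest.approx(1.85, abs=0.005)
        assert g.side == pytest.approx(1.36, abs=0.005)

    def test_post_stimulation_density_gives_printed_side(self):
        g = build_geometry(3.1, r_clus=0.096)
        assert g.side == pytest.approx(0.568, abs=0.0005)

    def test_unit_density_identity(self):
        g = build_geometry(1.0)
        assert g.side == 1.0
        assert g.df == pytest.approx(190.0)
        assert g.df == pytest.approx(g.volume / (g.area * g.h))

    def test_cluster_cannot_exceed_patch(self):
        with pytest.raises(ValueError, match="disk"):
            build_geometry(3.1, r_clus=0.4)


class TestEquilibrium:
    def test_printed_off_rate(self):
        kb = equilibrium_kb(10.0, 4.85, 30.0, 0.09)
        assert kb == pytest.approx(0.1455)
        assert round(kb, 2) == 0.15

    def test_equal_densities_reduce_to_kfrev_times_conc(self):
        assert equilibrium_kb(1.0, 25.0, 25.0, 0.09) == pytest.approx(0.09)

    def test_stationary_without_activator(self):
        # with k_b from the equilibrium condition and no cluster, every
        # species is constant over 400 s
        st = ModelState(a_clus=0.0)
        g = build_geometry(0.54)
        rates = RateParams(k_frev=0.09,
                           k_b=equilibrium_kb(st.d_sol, st.r_mem, st.d_mem, 0.09),
                           k_mem=0.017, k_dyn=0.035)
        s = simulate_ode(st, rates, g, 400.0)
        drift = np.abs(s.conc.iloc[-1] - s.conc.iloc[0])
        assert (drift / s.conc.iloc[0].max()).max() < 1e-6


class TestUnits:
    def test_micromolar_to_copy_density(self):
        assert convert_units(1.0, "uM", "copies/um3") == pytest.approx(602.214)

    def test_surface_density_to_copies(self):
        g = build_geometry(0.54)
        assert convert_units(10.0, "copies/um2@A", "copies", g) == \
            pytest.approx(18.5, abs=0.02)

    def test_round_trip_is_identity(self):
        g = build_geometry(0.54)
        for units in ("uM", "copies/um3", "copies/um2@A", "copies/um2@Aclus"):
            v = convert_units(convert_units(3.7, units, "copies", g),
                              "copies", units, g)
            assert v == pytest.approx(3.7, abs=1e-12)

    def test_unknown_units_rejected(self):
        with pytest.raises(ValueError, match="unknown unit"):
            convert_units(1.0, "furlongs", "uM")


class TestODE:
    def test_reversible_binding_relaxation_rate(self):
        # k_mem = k_dyn = 0 with a perturbed membrane pool relaxes at the
        # linearized rate k_b + k_frev([D]_sol + [R]_mem) (closed form for
        # A + B <-> C near equilibrium)
        g = build_geometry(0.54)
        st_eq = ModelState(a_clus=0.0)
        kb = equilibrium_kb(st_eq.d_sol, st_eq.r_mem, st_eq.d_mem, 0.09)
        rates = RateParams(k_frev=0.09, k_b=kb, k_mem=0.0, k_dyn=0.0)
        st = ModelState(d_mem=st_eq.d_mem * 1.01, a_clus=0.0)
        t = np.linspace(0.0, 60.0, 1201)
        s = simulate_ode(st, rates, g, 60.0, t_eval=t, rtol=1e-10, atol=1e-12)
        y = s.conc["d_mem"].to_numpy()
        dev = y - y[-1]            # relaxation toward the new equilibrium
        fit_win = t <= 2.0
        lam_fit = -np.polyfit(t[fit_win], np.log(np.abs(dev[fit_win])), 1)[0]
        a_eq = s.conc["d_sol"].iloc[-1]
        b_eq = s.conc["r_mem"].iloc[-1]
        lam_true = kb + 0.09 * (a_eq + b_eq)
        assert lam_fit == pytest.approx(lam_true, rel=0.02)

    def test_dynamin_conservation(self):
        state, geom, rates = dyn1bb_states(True)
        s = simulate_ode(state, rates, geom, 4.0)
        tot = s.total_dynamin_copies()
        assert np.abs(tot / tot[0] - 1).max() < 1e-7

    def test_recruiter_pool_non_increasing(self):
        # free R + membrane dynamin copies can only shrink once cluster
        # species sequester them
        state, geom, rates = dyn1bb_states(True)
        s = simulate_ode(state, rates, geom, 4.0)
        pool = (s.conc["r_mem"] + s.conc["d_mem"]).to_numpy()
        assert (np.diff(pool) <= 1e-12).all()

    def test_peak_copies_in_reported_envelope(self):
        state, geom, rates = dyn1bb_states(True)
        obs = observables(simulate_ode(state, rates, geom, 4.0))
        assert obs.peak_copies <= 80.0
        assert obs.peak_copies > obs.dyn_copies[0]


class TestStimulation:
    def test_identity_when_nothing_changes(self):
        state, geom, rates = dyn1bb_states(False)
        st2, g2, r2 = apply_stimulation(state, geom, rates, 1.0,
                                        geom.cluster_density, rates.k_mem)
        assert st2 == state
        assert g2.side == pytest.approx(geom.side)
        assert r2.k_mem == rates.k_mem

    def test_copy_conservation_arithmetic(self):
        # tripling 10 copies/µm² pulls 20/(1.9·602.214) µM from solution
        state = ModelState(d_sol=10.0, d_mem=10.0)
        geom = build_geometry(0.54)
        rates = RateParams(k_frev=0.09, k_b=0.15, k_mem=0.017, k_dyn=0.035)
        st2, _, _ = apply_stimulation(state, geom, rates, 3.0, 3.1, 0.0024,
                                      post_r_clus=0.096)
        assert state.d_sol - st2.d_sol == pytest.approx(20 / (1.9 * NA_UM))

    def test_total_copies_per_area_preserved(self):
        state, geom, rates = dyn1bb_states(False)
        st2, g2, _ = apply_stimulation(state, geom, rates, 2.0, 3.1, 0.0024,
                                       post_r_clus=0.096)
        pre = state.d_sol * NA_UM * geom.v_over_a + state.d_mem
        post = st2.d_sol * NA_UM * g2.v_over_a + st2.d_mem
        assert post == pytest.approx(pre, rel=1e-12)

    def test_overdraw_rejected(self):
        state = ModelState(d_sol=0.001, d_mem=80.0)
        geom = build_geometry(0.54)
        rates = RateParams(k_frev=0.09, k_b=0.15, k_mem=0.017, k_dyn=0.035)
        with pytest.raises(ValueError, match="negative"):
            apply_stimulation(state, geom, rates, 10.0, 3.1, 0.0024)


class TestSSA:
    def test_zero_rates_freeze_state(self):
        state, geom, _ = dyn1bb_states(True)
        zero = RateParams(k_frev=0, k_b=0, k_mem=0, k_dyn=0)
        run = simulate_ssa(state, zero, geom, 1.0, seed=1)
        assert run[model.SPECIES].nunique().max() == 1

    def test_reproducible_by_seed(self):
        state, geom, rates = dyn1bb_states(True)
        a = simulate_ssa(state, rates, geom, 2.0, seed=5)
        b = simulate_ssa(state, rates, geom, 2.0, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_exact_conservation_without_titration(self):
        state, geom, rates = dyn1bb_states(True)
        run = simulate_ssa(state, rates, geom, 4.0, seed=2)
        tot = (run["d_sol"] + run["d_mem"] + run["d_clus"]
               + run["d_2dclus"]).to_numpy()
        assert (tot == tot[0]).all()

    def test_no_cluster_zero_drift(self):
        # reaction 1 at detailed balance: 48 runs stay within 3 SE
        state, geom, rates = dyn1bb_states(False)
        state = ModelState(d_sol=state.d_sol, r_mem=state.r_mem,
                           d_mem=state.d_mem, a_clus=0.0)
        finals = []
        for k in range(48):
            run = simulate_ssa(state, rates, geom, 2.0, seed=100 + k)
            finals.append(run["d_mem"].iloc[-1])
        finals = np.array(finals, float)
        n0 = round(state.d_mem * geom.area)
        se = finals.std(ddof=1) / math.sqrt(len(finals))
        assert abs(finals.mean() - n0) <= 3 * max(se, 1e-9)

    def test_ensemble_mean_matches_ode(self):
        # 48 stochastic trajectories vs deterministic cluster copies
        state, geom, rates = dyn1bb_states(True)
        t_eval = np.arange(0.0, 4.0 + 1e-9, 0.05)
        ser = simulate_ode(state, rates, geom, 4.0, t_eval=t_eval)
        ode_copies = observables(ser).dyn_copies
        runs = np.stack([
            ssa_dyn_copies(simulate_ssa(state, rates, geom, 4.0, seed=s),
                           geom)
            for s in range(48)])
        mean = runs.mean(axis=0)
        se = runs.std(axis=0, ddof=1) / math.sqrt(len(runs))
        dev = np.abs(mean - ode_copies)
        assert (dev <= 3 * np.maximum(se, 0.05)).mean() > 0.99

    def test_mean_converges_at_scaled_up_geometry(self):
        # 10× larger patch (same densities, 10× the copies) tightens the
        # relative agreement with the ODE
        state, geom, rates = dyn1bb_states(True)
        big = Geometry(cluster_density=geom.cluster_density / 10.0,
                       r_clus=geom.r_clus * math.sqrt(10.0),
                       v_over_a=geom.v_over_a, h=geom.h)
        t_eval = np.arange(0.0, 4.0 + 1e-9, 0.1)
        for g in (big,):
            ser = simulate_ode(state, rates, g, 4.0, t_eval=t_eval)
            ode_copies = observables(ser).dyn_copies
            runs = np.stack([
                ssa_dyn_copies(simulate_ssa(state, rates, g, 4.0, seed=s),
                               g)
                for s in range(24)])
            rel = np.abs(runs.mean(axis=0)[-1] - ode_copies[-1]) / ode_copies[-1]
            assert rel < 0.1

    def test_titration_pins_solution_pool(self):
        state, geom, rates = dyn1bb_states(True)
        run = simulate_ssa(state, rates, geom, 0.3, seed=3,
                           titration=(100.0, 10.0))
        conc = run["d_sol"].to_numpy() / (NA_UM * geom.volume)
        assert abs(conc[-1] - 10.0) < 1.0


class TestPDE:
    def test_well_mixed_limit_matches_ode(self):
        state, geom, rates = dyn1bb_states(True)
        pde = simulate_membrane_pde(state, rates, geom, d_mem=50.0, t_end=4.0)
        ser = simulate_ode(state, rates, geom, 4.0, t_eval=pde.times)
        P, O = pde.totals.to_numpy(), ser.conc.to_numpy()
        scale = np.maximum(np.abs(O).max(axis=0), 1e-30)
        assert (np.abs(P - O) / scale).max() < 0.02

    def test_gaussian_bump_decays_like_heat_kernel(self):
        # zero rates: peak of a 2D Gaussian of variance σ² decays as
        # σ²/(σ² + 2Dt)
        g = build_geometry(0.54)
        zero = RateParams(k_frev=0, k_b=0, k_mem=0, k_dyn=0)
        st = ModelState(d_sol=0.0, r_mem=0.0, d_mem=1.0, a_clus=0.0)
        X, Y = membrane_grid(g)
        sigma = 0.08
        bump = 100.0 * np.exp(-(X ** 2 + Y ** 2) / (2 * sigma ** 2))
        d = 0.045
        t_end = 0.4
        pde = simulate_membrane_pde(st, zero, g, d_mem=d, t_end=t_end,
                                    initial_fields={"d_mem": bump})
        peak0 = bump.max()
        peak1 = pde.fields["d_mem"].max()
        expected = peak0 * sigma ** 2 / (sigma ** 2 + 2 * d * t_end)
        assert peak1 == pytest.approx(expected, rel=0.02)

    def test_depletion_halo_inside_cluster(self):
        # at the measured membrane diffusion the local membrane pool
        # inside the cluster footprint drops below the far field
        state, geom, rates = dyn1bb_states(True)
        pde = simulate_membrane_pde(state, rates, geom, d_mem=0.02,
                                    t_end=4.0)
        inside = pde.radial_d_mem[0]
        far = pde.radial_d_mem[-2]
        assert inside < far


class TestObservables:
    def test_initial_relative_density_is_one(self):
        state, geom, rates = dyn1bb_states(True)
        obs = observables(simulate_ode(state, rates, geom, 1.0))
        assert obs.rel_density[0] == pytest.approx(1.0)
        assert np.all((obs.fraction_2d >= 0) & (obs.fraction_2d <= 1))

    def test_solution_only_recruitment_has_zero_lateral_fraction(self):
        # suppressing the 2D channels (no membrane pool to draw from)
        # leaves every clustered dynamin arriving from solution
        state, geom, rates = dyn1bb_states(True)
        tiny = ModelState(d_sol=state.d_sol, r_mem=0.0, d_mem=1e-12,
                          a_clus=state.a_clus)
        zero2d = RateParams(k_frev=0.0, k_b=0.0, k_mem=rates.k_mem,
                            k_dyn=rates.k_dyn)
        s = simulate_ode(tiny, zero2d, geom, 4.0)
        obs = observables(s)
        assert obs.fraction_2d.max() < 1e-6

    def test_lateral_fraction_monotone_in_membrane_pool(self):
        # more membrane-bound dynamin → larger share of 2D recruitment
        _, geom, rates = dyn1bb_states(True)
        peaks = []
        for d_mem in (10.0, 30.0, 60.0):
            st = ModelState(d_sol=10.0, r_mem=4.85, d_mem=d_mem, a_clus=207.0)
            kb = equilibrium_kb(st.d_sol, st.r_mem, st.d_mem, rates.k_frev)
            r = RateParams(k_frev=rates.k_frev, k_b=kb, k_mem=rates.k_mem,
                           k_dyn=rates.k_dyn)
            obs = observables(simulate_ode(st, r, geom, 4.0))
            peaks.append(obs.fraction_2d.max())
        assert peaks[0] < peaks[1] < peaks[2]

    def test_stimulation_raises_lateral_fraction(self):
        # short-tail preset: the 2D share of recruitment grows after the
        # stimulation transform
        pre_state, pre_geom, pre_rates = dyn1bb_states(False)
        post_state, post_geom, post_rates = dyn1bb_states(True)
        pre = observables(simulate_ode(pre_state, pre_rates, pre_geom, 4.0))
        post = observables(simulate_ode(post_state, post_rates, post_geom, 4.0))
        assert post.fraction_2d.max() >= pre.fraction_2d.max()
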
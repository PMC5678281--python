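"""Integration correctness: steady states, events, analytic oracles."""

import numpy as np
import pytest

from pipnet.model import (
    DEFAULT_PARAMS,
    Enzyme,
    Genotype,
    InhibitorEvent,
    Species,
    apply_genotype,
    build_reference_network,
)
from pipnet.fitting import build_variant
from pipnet.simulate import (
    Protocol,
    observe,
    simulate,
    steady_state,
)


class TestSteadyState:
    def test_derivatives_vanish(self, reference_model, steady_states):
        from pipnet.model import rhs

        ss = steady_states["WT"]
        d = rhs(reference_model, ss)
        for sp, v in d.items():
            assert abs(v) < 1e-8

    def test_zero_basal_drive_means_zero_pip3(self):
        model = build_reference_network({"k_pi3k_basal_activation": 0.0})
        ss = steady_state(model)
        assert ss[Species.PIP3] == pytest.approx(0.0, abs=1e-9)
        assert ss[Species.PI3K_ACTIVE] == pytest.approx(0.0, abs=1e-9)

    def test_pten_ko_basal_differs_from_wt(self, steady_states):
        """With nonzero basal PI3K drive, removing PTEN shifts the starved
        equilibrium (higher basal PIP3)."""
        assert steady_states["PTEN-KO"][Species.PIP3] > \
            steady_states["WT"][Species.PIP3]

    def test_conserved_totals_preserved(self, reference_model, steady_states):
        ss = steady_states["WT"]
        init = reference_model.initial_state
        assert ss[Species.EGFR_INACTIVE] + ss[Species.EGFR_ACTIVE] == pytest.approx(
            init[Species.EGFR_INACTIVE] + init[Species.EGFR_ACTIVE], rel=1e-9)
        assert ss[Species.PI3K_INACTIVE] + ss[Species.PI3K_ACTIVE] == pytest.approx(
            init[Species.PI3K_INACTIVE] + init[Species.PI3K_ACTIVE], rel=1e-9)


class TestSimulate:
    def test_no_stimulus_stays_flat(self, reference_model):
        proto = Protocol(egf_dose=0.0, t_end=900.0)
        traj = simulate(reference_model, proto)
        for sp in (Species.PIP3, Species.PI34P2, Species.PI45P2):
            y = traj.concentration(sp)
            assert np.allclose(y, y[0], rtol=1e-6, atol=1e-8)

    def test_trajectory_contains_output_times_exactly(self, vehicle_trajectories):
        t = vehicle_trajectories["WT"].times
        for want in (0.0, 60.0, 300.0, 900.0):
            assert np.any(t == want)

    def test_conservation_along_trajectory(self, vehicle_trajectories):
        traj = vehicle_trajectories["WT"]
        r = traj.concentration(Species.EGFR_INACTIVE) + \
            traj.concentration(Species.EGFR_ACTIVE)
        p = traj.concentration(Species.PI3K_INACTIVE) + \
            traj.concentration(Species.PI3K_ACTIVE)
        assert np.abs(r - r[0]).max() < 1e-8 * r[0]
        assert np.abs(p - p[0]).max() < 1e-8 * p[0]

    def test_nonnegativity(self, vehicle_trajectories, chase_trajectories):
        for trajs in (vehicle_trajectories, chase_trajectories):
            for traj in trajs.values():
                assert traj.states.min() > -1e-9

    def test_event_split_equals_one_shot(self, genotype_models, steady_states):
        """Integrating through the event equals stopping at 60 s and
        restarting from the stored state with the inhibitor in force."""
        model = genotype_models["WT"]
        ss = steady_states["WT"]
        full = simulate(model, Protocol(inhibitor=InhibitorEvent(60.0, 0.0)),
                        initial_state=ss)
        first = simulate(model, Protocol(t_end=60.0, output_times=(0.0, 60.0)),
                         initial_state=ss)
        mid = {sp: first.concentration(sp)[-1] for sp in Species}
        second = simulate(
            model,
            Protocol(egf_dose=0.0, t_end=840.0,
                     inhibitor=InhibitorEvent(0.0, 0.0),
                     output_times=(0.0, 240.0, 840.0)),
            initial_state=mid,
        )
        for t_offset in (240.0, 840.0):
            a = observe(full, Species.PIP3, [60.0 + t_offset])[0]
            b = observe(second, Species.PIP3, [t_offset])[0]
            assert a == pytest.approx(b, rel=1e-6, abs=1e-9)

    def test_grid_refinement_stable_peak(self, genotype_models, steady_states):
        model = genotype_models["WT"]
        pk = {}
        for dt in (1.0, 2.0):
            traj = simulate(model, Protocol(dense_grid_dt=dt),
                            initial_state=steady_states["WT"])
            pk[dt] = traj.concentration(Species.PIP3).max()
        assert abs(pk[2.0] - pk[1.0]) / pk[1.0] < 0.005


class TestAnalyticOracles:
    def test_post_inhibition_pip3_is_single_exponential(
            self, genotype_models, steady_states):
        """With full inhibition, synthesis stops and PI(3,4,5)P3 decays as
        PIP3(t0) * exp(-lambda (t - t0)) with lambda the summed first-order
        dephosphorylation constants; agreement within 0.1%."""
        traj = simulate(genotype_models["WT"],
                        Protocol(inhibitor=InhibitorEvent(60.0, 0.0)),
                        initial_state=steady_states["WT"])
        lam = (DEFAULT_PARAMS["k_pten_pip3"] + DEFAULT_PARAMS["k_ship2_pip3"]
               + DEFAULT_PARAMS["k_x_pip3"])
        t0 = 60.0
        p0 = observe(traj, Species.PIP3, [t0])[0]
        for tau in (1.0, 2.0, 5.0, 10.0, 20.0):
            expected = p0 * np.exp(-lam * tau)
            got = observe(traj, Species.PIP3, [t0 + tau])[0]
            assert got == pytest.approx(expected, rel=1e-3)

    def test_half_life_matches_ln2_over_lambda(self):
        lam = 0.2
        model = build_variant("linear", {
            "k_pten_pip3": lam / 2.4, "k_ship2_pip3": lam * 1.4 / 2.4 * 2.65 / 3.65,
            "k_x_pip3": lam * 1.4 / 2.4 / 3.65,
        })
        model = apply_genotype(model, Genotype("WT"))
        traj = simulate(model, Protocol(inhibitor=InhibitorEvent(60.0, 0.0)),
                        initial_state=steady_state(model))
        p0 = observe(traj, Species.PIP3, [60.0])[0]
        basal = observe(traj, Species.PIP3, [900.0])[0]
        half_expected = np.log(2) / lam  # 3.466 s
        got = observe(traj, Species.PIP3, [60.0 + half_expected])[0]
        assert got - basal == pytest.approx((p0 - basal) / 2, rel=0.02)

    def test_two_exponential_chain_oracle(self, steady_states):
        """Post-inhibition PI(3,4)P2 in the fully linear variant follows the
        closed-form two-exponential solution of the PIP3 -> PI(3,4)P2 chain
        within 0.1%."""
        model = build_variant("linear")
        ss = steady_state(model)
        traj = simulate(model, Protocol(inhibitor=InhibitorEvent(60.0, 0.0)),
                        initial_state=ss)
        lam_p = (DEFAULT_PARAMS["k_pten_pip3"] + DEFAULT_PARAMS["k_ship2_pip3"]
                 + DEFAULT_PARAMS["k_x_pip3"])
        lam_m = (DEFAULT_PARAMS["k_inpp4b"] + DEFAULT_PARAMS["k_pten_pi34p2"]
                 + DEFAULT_PARAMS["k_y_linear"])
        k_in = DEFAULT_PARAMS["k_ship2_pip3"] + DEFAULT_PARAMS["k_x_pip3"]
        t0 = 60.0
        p0 = observe(traj, Species.PIP3, [t0])[0]
        m0 = traj.concentration(Species.PI34P2)[traj.times == t0][0]
        for tau in (2.0, 5.0, 15.0, 40.0):
            expected = (m0 * np.exp(-lam_m * tau)
                        + k_in * p0 * (np.exp(-lam_p * tau) - np.exp(-lam_m * tau))
                        / (lam_m - lam_p))
            got = traj.concentration(Species.PI34P2)[traj.times == t0 + tau][0]
            assert got == pytest.approx(expected, rel=1e-3)


class TestLinearRangeEquivalence:
    def test_saturable_collapses_onto_mass_action(self, steady_states):
        """With every phosphatase Km set far above the substrate excursion
        and k = Vmax/Km, the saturable and mass-action variants agree within
        1% sup-norm."""
        linear = build_variant("linear")
        saturable = build_variant("saturable", {"saturable_km": 1e5})
        proto = Protocol()
        t_lin = simulate(linear, proto, initial_state=steady_state(linear))
        t_sat = simulate(saturable, proto, initial_state=steady_state(saturable))
        for sp in (Species.PIP3, Species.PI34P2, Species.PI45P2):
            a, b = t_lin.concentration(sp), t_sat.concentration(sp)
            scale = np.abs(a).max()
            assert np.abs(a - b).max() / scale < 0.01


class TestObserve:
    def test_background_pool_added_to_pi34p2(self, vehicle_trajectories,
                                             reference_model):
        traj = vehicle_trajectories["WT"]
        raw = traj.concentration(Species.PI34P2)[0]
        obs = observe(traj, Species.PI34P2, [0.0])[0]
        assert obs == pytest.approx(raw + reference_model.pi34p2_background)

    def test_pi45p2_passes_through(self, vehicle_trajectories):
        traj = vehicle_trajectories["WT"]
        assert observe(traj, Species.PI45P2, [0.0])[0] == pytest.approx(
            traj.concentration(Species.PI45P2)[0])

    def test_basal_pi34p2_observable_positive(self, vehicle_trajectories):
        """The EGF-insensitive background pool keeps the basal PI(3,4)P2
        observable well above the near-zero model concentration."""
        traj = vehicle_trajectories["WT"]
        assert traj.concentration(Species.PI34P2)[0] < 0.1
        assert observe(traj, Species.PI34P2, [0.0])[0] > 4.0

    def test_time_outside_span_rejected(self, vehicle_trajectories):
        with pytest.raises(ValueError, match="outside"):
            observe(vehicle_trajectories["WT"], Species.PIP3, [1000.0])
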
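"""Network structure, rate laws, genotype semantics and the rhs oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pipnet.model import (
    DEFAULT_PARAMS,
    Enzyme,
    Genotype,
    InhibitorEvent,
    ModelSpec,
    RateLaw,
    ReactionSpec,
    Species,
    apply_genotype,
    build_reference_network,
    reaction_rate,
    rhs,
)


class TestNetworkStructure:
    def test_pip3_consuming_routes(self, reference_model):
        """Two 5-phosphatase routes (SHIP2, X) and one 3-phosphatase route
        (PTEN) consume PI(3,4,5)P3."""
        consumers = [r for r in reference_model.reactions
                     if r.substrate is Species.PIP3]
        to_pi34p2 = [r for r in consumers if r.product is Species.PI34P2]
        to_pi45p2 = [r for r in consumers if r.product is Species.PI45P2]
        assert sorted(r.enzyme for r in to_pi34p2) == [Enzyme.SHIP2, Enzyme.X]
        assert [r.enzyme for r in to_pi45p2] == [Enzyme.PTEN]
        assert len(consumers) == 3

    def test_pi34p2_consuming_routes(self, reference_model):
        consumers = [r for r in reference_model.reactions
                     if r.substrate is Species.PI34P2]
        assert sorted(r.enzyme for r in consumers) == [
            Enzyme.PTEN, Enzyme.INPP4B, Enzyme.Y
        ] or {r.enzyme for r in consumers} == {Enzyme.INPP4B, Enzyme.PTEN, Enzyme.Y}
        assert len(consumers) == 3

    def test_background_pool_has_no_reactions(self, reference_model):
        for rx in reference_model.reactions:
            assert rx.substrate is not Species.PI34P2_BG
            assert rx.product is not Species.PI34P2_BG

    def test_no_egf_no_activator_drive(self):
        """With EGF dose zero, every EGF-activated reaction is silent at the
        initial state."""
        model = build_reference_network(egf_dose=0.0)
        state = dict(model.initial_state)
        state[Species.EGF] = 0.0
        for rx in model.reactions:
            if rx.activator is Species.EGF:
                assert reaction_rate(rx, state, 1.0) == 0.0

    def test_direct_pi4p_route_off_by_default(self, reference_model):
        assert all(rx.id != "pi3k_pi4p_direct" for rx in reference_model.reactions)
        with_route = build_reference_network(include_direct_pi4p_route=True)
        assert any(rx.id == "pi3k_pi4p_direct" for rx in with_route.reactions)

    def test_y_product_configurable(self):
        m = build_reference_network(y_product=Species.PI3P)
        assert m.reaction("y_pi34p2").product is Species.PI3P
        with pytest.raises(ValueError):
            build_reference_network(y_product=Species.PIP3)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(KeyError):
            build_reference_network({"k_bogus": 1.0})


class TestRateLaw:
    def test_mass_action_arithmetic(self):
        law = RateLaw("mass_action", k=0.1)
        rx = ReactionSpec("r", Species.PIP3, Species.PI45P2, Enzyme.PTEN, law)
        assert reaction_rate(rx, {Species.PIP3: 10.0}, 1.0) == pytest.approx(1.0)

    def test_michaelis_menten_linear_limit(self):
        """Km >> S: the saturable law collapses onto mass action k=Vmax/Km."""
        mm = ReactionSpec("r", Species.PIP3, Species.PI45P2, Enzyme.PTEN,
                          RateLaw("michaelis_menten", vmax=100.0, km=1000.0))
        v = reaction_rate(mm, {Species.PIP3: 10.0}, 1.0)
        assert v == pytest.approx(100.0 * 10.0 / 1010.0)
        assert v == pytest.approx(0.990, abs=5e-4)
        linear = reaction_rate(
            ReactionSpec("r", Species.PIP3, Species.PI45P2, Enzyme.PTEN,
                         RateLaw("mass_action", k=0.1)),
            {Species.PIP3: 10.0}, 1.0)
        assert abs(v - linear) / linear < 0.01

    @pytest.mark.parametrize("law", [
        RateLaw("mass_action", k=0.3),
        RateLaw("michaelis_menten", vmax=2.0, km=0.5),
        RateLaw("zeroth_order", v=0.7),
    ])
    def test_zero_activity_silences_any_law(self, law):
        rx = ReactionSpec("r", Species.PI34P2, Species.PI4P, Enzyme.Y, law)
        assert reaction_rate(rx, {Species.PI34P2: 3.0}, 0.0) == 0.0

    def test_negative_concentration_rejected(self):
        rx = ReactionSpec("r", Species.PIP3, None, Enzyme.PTEN,
                          RateLaw("mass_action", k=1.0))
        with pytest.raises(ValueError, match="negative"):
            reaction_rate(rx, {Species.PIP3: -0.1}, 1.0)

    @pytest.mark.parametrize("kwargs", [
        {"kind": "bogus"},
        {"kind": "mass_action", "k": -1.0},
        {"kind": "michaelis_menten", "vmax": 1.0, "km": 0.0},
    ])
    def test_invalid_rate_law_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RateLaw(**kwargs)


class TestGenotype:
    def test_knockout_zeroes_all_enzyme_fluxes(self, reference_model):
        ko = apply_genotype(reference_model, Genotype("PTEN-KO", {Enzyme.PTEN: 0.0}))
        state = {sp: 1.0 for sp in Species}
        for rx in ko.reactions:
            if rx.enzyme is Enzyme.PTEN:
                assert reaction_rate(rx, state, ko.activity(rx.enzyme)) == 0.0

    def test_knockdown_scales_flux_linearly(self, reference_model):
        kd = apply_genotype(reference_model, Genotype("SHIP2-KD", {Enzyme.SHIP2: 0.1}))
        state = {sp: 2.0 for sp in Species}
        rx = reference_model.reaction("ship2_pip3")
        wt_flux = reaction_rate(rx, state, reference_model.activity(Enzyme.SHIP2))
        kd_flux = reaction_rate(rx, state, kd.activity(Enzyme.SHIP2))
        assert kd_flux == pytest.approx(0.1 * wt_flux)

    def test_applying_knockout_twice_is_idempotent(self, reference_model):
        g = Genotype("PTEN-KO", {Enzyme.PTEN: 0.0})
        once = apply_genotype(reference_model, g)
        twice = apply_genotype(once, g)
        assert once.enzyme_activities == twice.enzyme_activities

    def test_input_model_unchanged(self, reference_model):
        before = dict(reference_model.enzyme_activities)
        apply_genotype(reference_model, Genotype("KO", {Enzyme.X: 0.0}))
        assert dict(reference_model.enzyme_activities) == before

    def test_unknown_enzyme_label_rejected(self, reference_model):
        with pytest.raises(KeyError, match="AKT"):
            apply_genotype(reference_model, Genotype("bad", {"AKT": 0.0}))

    @pytest.mark.parametrize("mult", [-0.1, 1.5])
    def test_multiplier_out_of_range_rejected(self, mult):
        with pytest.raises(ValueError):
            Genotype("bad", {Enzyme.PTEN: mult})


class TestRhs:
    def test_receptor_and_pi3k_conservation(self, reference_model):
        state = {sp: 0.5 for sp in Species}
        d = rhs(reference_model, state)
        assert d[Species.EGFR_INACTIVE] + d[Species.EGFR_ACTIVE] == pytest.approx(0.0, abs=1e-15)
        assert d[Species.PI3K_INACTIVE] + d[Species.PI3K_ACTIVE] == pytest.approx(0.0, abs=1e-15)

    def test_no_pip3_no_pi34p2_production_from_5phosphatases(self, reference_model):
        state = {sp: 1.0 for sp in Species}
        state[Species.PIP3] = 0.0
        d = rhs(reference_model, state)
        # only the PI(3,4)P2 consuming routes act: derivative strictly negative
        consumption = sum(
            reaction_rate(rx, state, reference_model.activity(rx.enzyme))
            for rx in reference_model.reactions if rx.substrate is Species.PI34P2
        )
        assert d[Species.PI34P2] == pytest.approx(-consumption)

    def test_inhibitor_event_scales_pi3k_drive(self, reference_model):
        state = {sp: 1.0 for sp in Species}
        ev = InhibitorEvent(time=60.0, residual_pi3k_fraction=0.25)
        before = rhs(reference_model, state, time=30.0, events=[ev])
        after = rhs(reference_model, state, time=90.0, events=[ev])
        rx = reference_model.reaction("pi3k_pip3_synthesis")
        full = reaction_rate(rx, state, 1.0, 1.0)
        assert before[Species.PIP3] - after[Species.PIP3] == pytest.approx(0.75 * full)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 50.0), min_size=len(Species),
                    max_size=len(Species)),
           st.booleans())
    def test_rhs_matches_stoichiometry_oracle(self, concs, inhibited):
        """d[S]/dt equals the signed flux sum over an independently built
        stoichiometry table, exactly (to 1e-12)."""
        model = build_reference_network(y_saturable=True)
        state = dict(zip(Species, concs))
        events = [InhibitorEvent(0.0, 0.3)] if inhibited else []
        phi = 0.3 if inhibited else 1.0
        d = rhs(model, state, time=10.0, events=events)
        oracle = {sp: 0.0 for sp in Species}
        for rx in model.reactions:
            f = reaction_rate(rx, state, model.activity(rx.enzyme), phi)
            if rx.substrate is not None:
                oracle[rx.substrate] -= f
            if rx.product is not None:
                oracle[rx.product] += f
        oracle[Species.PI34P2_BG] = 0.0
        for sp in Species:
            assert d[sp] == pytest.approx(oracle[sp], abs=1e-12)


def test_default_activities_are_identity(reference_model):
    state = {sp: 1.3 for sp in Species}
    for rx in reference_model.reactions:
        assert reference_model.activity(rx.enzyme) == 1.0
        raw = rx.rate_law.evaluate(state[rx.substrate] if rx.substrate else 1.0)
        scaled = reaction_rate(rx, state, reference_model.activity(rx.enzyme))
        if rx.activator is not None:
            raw *= state[rx.activator]
        assert scaled == pytest.approx(raw)


def test_model_rejects_negative_initial_state():
    m = build_reference_network()
    bad = dict(m.initial_state)
    bad[Species.PI45P2] = -1.0
    with pytest.raises(ValueError):
        ModelSpec(reactions=m.reactions, initial_state=bad)
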
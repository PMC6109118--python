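"""Box-model kinetics: closed forms, conservation, ordering, and a
time-stepping oracle for the continuous-kinetics survival solution."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sulfoc.boxmodel import (
    BoxModelError,
    BoxSpec,
    FluxState,
    Kinetics,
    ModelParams,
    ReactivitySpectrum,
    box_transit,
    preserved_sc,
    run_chain,
)

SINGLE = ReactivitySpectrum(g=(1.0, 1e-2, 1e-4), f=(1.0, 0.0, 0.0))


def euler_box_oracle(h, q, tau, n_steps=100_000):
    """Explicit time integration of dC/dt = -(h+q) C with loss partitioning.

    Independent of the closed-form survival used by box_transit.
    """
    dt = tau / n_steps
    c = 1.0
    sulfurized = 0.0
    remineralized = 0.0
    for _ in range(n_steps):
        loss = (h + q) * c * dt
        c -= loss
        if h + q > 0:
            sulfurized += loss * q / (h + q)
            remineralized += loss * h / (h + q)
    return c, sulfurized, remineralized


class TestBoxTransit:
    def test_zero_exposure_time_is_identity(self):
        state = FluxState.initial(SINGLE, r_bio=0.005)
        box = BoxSpec("A", 0.0, True, 0.045)
        out, ledger = box_transit(state, box, ModelParams(10.0, 5.0, SINGLE))
        assert out == state
        assert ledger.remineralized_c == 0.0 and ledger.newly_sulfurized_c == 0.0

    def test_mixed_half_survival_closed_form(self):
        # single class, no sulfurization, h*tau = 1 -> phi = 1/2
        params = ModelParams(k_het=2.0, k_sulf=0.0, spectrum=SINGLE)
        out, ledger = box_transit(
            FluxState.initial(SINGLE), BoxSpec("A", 0.5, True, 0.045), params
        )
        assert out.biomass_c[0] == pytest.approx(0.5, abs=1e-15)
        assert ledger.remineralized_c == pytest.approx(0.5, abs=1e-15)
        assert ledger.newly_sulfurized_c == 0.0

    def test_continuous_equal_rates_ln4(self):
        # h = q, (h+q)*tau = ln 4 -> phi = 1/4, losses split evenly
        k = math.log(4.0) / 2.0
        params = ModelParams(k_het=k, k_sulf=k, spectrum=SINGLE)
        box = BoxSpec("A", 1.0, True, 0.045, Kinetics.CONTINUOUS)
        out, ledger = box_transit(FluxState.initial(SINGLE), box, params)
        assert out.biomass_c[0] == pytest.approx(0.25, rel=1e-12)
        assert out.sulfurized_c == pytest.approx(0.375, rel=1e-12)
        assert ledger.remineralized_c == pytest.approx(0.375, rel=1e-12)

    def test_negative_tau_rejected(self):
        with pytest.raises(BoxModelError):
            BoxSpec("A", -1.0, True, 0.045)

    def test_zero_rates_pass_through(self):
        params = ModelParams(k_het=1e-300, k_sulf=0.0, spectrum=SINGLE)
        out, _ = box_transit(
            FluxState.initial(SINGLE), BoxSpec("A", 1.0, False, 0.0), params
        )
        assert out.biomass_c[0] == pytest.approx(1.0)

    @given(
        k_het=st.floats(1e-3, 1e3),
        ratio=st.floats(1e-3, 1e2),
        tau=st.floats(1e-4, 1e3),
        on=st.booleans(),
        f2=st.floats(0, 0.6),
        f3=st.floats(0, 0.4),
    )
    @settings(max_examples=150, derandomize=True)
    def test_carbon_conserved_to_1e12(self, k_het, ratio, tau, on, f2, f3):
        spectrum = ReactivitySpectrum(f=(1 - f2 - f3, f2, f3))
        params = ModelParams(k_het, k_het * ratio, spectrum)
        state = FluxState.initial(spectrum, r_bio=0.005)
        for kin in Kinetics:
            out, ledger = box_transit(
                state, BoxSpec("A", tau, on, 0.045, kin), params
            )
            residual = (
                state.total_c
                - out.total_c
                - ledger.remineralized_c
            )
            assert abs(residual) < 1e-12

    @given(
        k=st.floats(1e-3, 1e2),
        tau=st.floats(1e-3, 1e2),
    )
    @settings(max_examples=100, derandomize=True)
    def test_continuous_survival_below_mixed(self, k, tau):
        # exp(-x) <= 1/(1+x) for x > 0
        params = ModelParams(k, 0.0, SINGLE)
        state = FluxState.initial(SINGLE)
        mixed, _ = box_transit(state, BoxSpec("A", tau, False, 0.0), params)
        cont, _ = box_transit(
            state, BoxSpec("A", tau, False, 0.0, Kinetics.CONTINUOUS), params
        )
        assert cont.biomass_c[0] <= mixed.biomass_c[0] + 1e-15

    def test_continuous_matches_euler_oracle(self, rng):
        # small instances: (h+q)*tau <= 3 keeps the first-order Euler
        # discretization error at 1e5 steps well below the 1e-4 tolerance
        for _ in range(5):
            h = 10 ** rng.uniform(-2, 1)
            q = 10 ** rng.uniform(-2, 1)
            tau = rng.uniform(0.1, 3.0) / (h + q)
            params = ModelParams(h, q, SINGLE)
            box = BoxSpec("A", tau, True, 0.045, Kinetics.CONTINUOUS)
            out, ledger = box_transit(FluxState.initial(SINGLE), box, params)
            c_ref, s_ref, r_ref = euler_box_oracle(h, q, tau)
            assert out.biomass_c[0] == pytest.approx(c_ref, rel=1e-4)
            assert out.sulfurized_c == pytest.approx(s_ref, rel=1e-4)
            assert ledger.remineralized_c == pytest.approx(r_ref, rel=1e-4)


def _boxes(taus, flags, sc=(0.045, 0.045, 0.02), kin=Kinetics.MIXED):
    return [
        BoxSpec(n, t, on, s, kin)
        for n, t, on, s in zip("ABC", taus, flags, sc)
    ]


class TestRunChain:
    def test_pure_decay_continuous(self):
        params = ModelParams(k_het=0.7, k_sulf=0.0, spectrum=SINGLE)
        taus = (0.5, 1.0, 2.0)
        res = run_chain(params, _boxes(taus, (True,) * 3, kin=Kinetics.CONTINUOUS))
        assert res.preserved_total_c == pytest.approx(
            math.exp(-0.7 * sum(taus)), rel=1e-12
        )

    def test_pure_decay_mixed_three_halvings(self):
        params = ModelParams(k_het=1.0, k_sulf=0.0, spectrum=SINGLE)
        res = run_chain(params, _boxes((1.0, 1.0, 1.0), (True,) * 3))
        assert res.preserved_total_c == pytest.approx(0.125, rel=1e-12)

    def test_no_heterotrophy_preserves_everything(self):
        # k_het ~ 0: carbon either survives or is sulfurized, none remineralized
        params = ModelParams(k_het=1e-300, k_sulf=3.0, spectrum=SINGLE)
        res = run_chain(params, _boxes((0.5, 10.0, 1000.0), (True,) * 3))
        assert res.preserved_total_c == pytest.approx(1.0, abs=1e-9)

    def test_flux_checkpoints_are_totals(self):
        params = ModelParams(2.0, 1.0, SINGLE)
        res = run_chain(params, _boxes((0.2, 5.0, 100.0), (True,) * 3), r_bio=0.005)
        for state, flux in zip(
            res.states[1:], (res.flux_after_a, res.flux_after_b, res.flux_after_c)
        ):
            assert flux == state.total_biomass_c + state.sulfurized_c

    def test_preservation_monotone_in_sulfurization_extent(self, rng):
        for _ in range(20):
            params = ModelParams(
                10 ** rng.uniform(-1, 2), 10 ** rng.uniform(-2, 2), SINGLE
            )
            taus = tuple(10 ** rng.uniform(-2, 2) for _ in range(3))
            configs = [(False,) * 3, (False, False, True), (False, True, True),
                       (True, True, True)]
            vals = [
                run_chain(params, _boxes(taus, flags)).preserved_total_c
                for flags in configs
            ]
            assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_preservation_nonincreasing_in_tau_and_k_het(self):
        base = dict(taus=(0.3, 5.0, 500.0))
        params = ModelParams(5.0, 1.0, SINGLE)
        v0 = run_chain(params, _boxes(base["taus"], (True,) * 3)).preserved_total_c
        v_tau = run_chain(
            params, _boxes((0.3, 50.0, 500.0), (True,) * 3)
        ).preserved_total_c
        v_k = run_chain(
            ModelParams(10.0, 1.0, SINGLE), _boxes(base["taus"], (True,) * 3)
        ).preserved_total_c
        assert v_tau <= v0 and v_k <= v0


class TestPreservedSC:
    def test_no_sulfurization_returns_r_bio(self):
        params = ModelParams(1.0, 0.0, SINGLE)
        res = run_chain(params, _boxes((1.0, 1.0, 1.0), (False,) * 3), r_bio=0.008)
        assert preserved_sc(res) == pytest.approx(0.008, rel=1e-12)

    def test_fully_sulfurized_returns_product_ratio(self):
        # overwhelming sulfurization in box A captures essentially all carbon
        params = ModelParams(1e-12, 1e12, SINGLE)
        res = run_chain(params, _boxes((1.0, 0.0, 0.0), (True, False, False)),
                        r_bio=0.005)
        assert preserved_sc(res) == pytest.approx(0.045, rel=1e-6)

    def test_weighted_mean_of_endmembers(self):
        state = FluxState(
            biomass_c=(0.5, 0.0, 0.0),
            sulfurized_c=0.5,
            sulfurized_s=0.5 * 0.04,
            sc_biomass=0.01,
        )
        assert state.sc_total == pytest.approx(0.025, rel=1e-12)

    def test_bounded_by_endmember_hull(self, rng):
        for _ in range(20):
            params = ModelParams(
                10 ** rng.uniform(-1, 2), 10 ** rng.uniform(-2, 2), SINGLE
            )
            r_bio = rng.uniform(0, 0.01)
            res = run_chain(
                params,
                _boxes(tuple(10 ** rng.uniform(-2, 2) for _ in range(3)),
                       (True,) * 3),
                r_bio=r_bio,
            )
            lo = min(r_bio, 0.02, 0.045)
            hi = max(r_bio, 0.02, 0.045)
            assert lo - 1e-12 <= preserved_sc(res) <= hi + 1e-12

    def test_zero_preserved_carbon_rejected(self):
        state = FluxState(biomass_c=(0.0, 0.0, 0.0))
        with pytest.raises(BoxModelError):
            _ = state.sc_total
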
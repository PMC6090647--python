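"""Rate laws, derivative assembly and integration of the kinetic model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from propiokin import (
    SPECIES,
    FeedProfile,
    FermentationState,
    KineticParameters,
    batch_derivatives,
    fedbatch_derivatives,
    growth_rate,
    pyruvate_drain_term,
    simulate,
    substrate_uptake_rate,
)
from propiokin.synthetic_data import reference_parameters

from oracles import rk4_batch, scalar_batch_rhs, scalar_fedbatch_rhs


def random_params(rng) -> KineticParameters:
    return KineticParameters(
        rs_max=rng.uniform(0.2, 5.0), Ks=rng.uniform(0.1, 50.0),
        kipa=rng.uniform(1.0, 80.0), kiaa=rng.uniform(1.0, 80.0),
        Yxs=rng.uniform(0.02, 0.5), ms=rng.uniform(0.0, 1.0),
        K1=rng.uniform(0, 15), K2=rng.uniform(0, 2), K3=rng.uniform(0, 1),
        K4=rng.uniform(0, 3), K5=rng.uniform(0, 0.5), K6=rng.uniform(0, 3),
        K7=rng.uniform(0, 0.5), K_pyr=rng.uniform(0.05, 2.0),
        beta_pa=rng.uniform(-0.2, 0.4), beta_pyr=rng.uniform(-0.05, 0.05),
        beta_aa=rng.uniform(-0.1, 0.2), beta_sa=rng.uniform(-0.1, 0.2),
    )


def random_state(rng, with_volume=False) -> FermentationState:
    return FermentationState(
        X=rng.uniform(0, 5), S=rng.uniform(0, 150), PA=rng.uniform(0, 60),
        PYR=rng.uniform(0, 3), AA=rng.uniform(0, 15), SA=rng.uniform(0, 15),
        V=rng.uniform(0.3, 2.0) if with_volume else 1.0,
    )


class TestRateLaws:
    def test_uptake_zero_at_zero_substrate(self, simple_params):
        assert substrate_uptake_rate(0.0, 12.0, 3.0, simple_params) == 0.0

    def test_uptake_half_saturation(self, simple_params):
        qs = substrate_uptake_rate(simple_params.Ks, 0.0, 0.0, simple_params)
        assert qs == pytest.approx(simple_params.rs_max / 2)

    def test_uptake_hand_value(self, simple_params):
        # rs_max=0.8, Ks=0.1, kipa=20, kiaa=40 at S=40, PA=20, AA=10
        qs = substrate_uptake_rate(40.0, 20.0, 10.0, simple_params)
        assert qs == pytest.approx(0.8 * (40 / 40.1) * (20 / 40) * (40 / 50))
        assert qs == pytest.approx(0.3192, abs=5e-5)

    def test_uptake_rejects_negative_concentration(self, simple_params):
        with pytest.raises(ValueError):
            substrate_uptake_rate(-1.0, 0.0, 0.0, simple_params)

    def test_growth_rate_maintenance_balance(self, simple_params):
        assert growth_rate(simple_params.ms, simple_params) == pytest.approx(0.0)

    def test_growth_rate_hand_value(self, simple_params):
        p = simple_params.updated(Yxs=0.3, ms=0.05)
        assert growth_rate(0.4, p) == pytest.approx(0.105)

    def test_growth_rate_negative_below_maintenance(self, simple_params):
        assert growth_rate(0.0, simple_params) < 0

    def test_drain_term_limits(self, simple_params):
        assert pyruvate_drain_term(0.0, simple_params) == 0.0
        assert pyruvate_drain_term(simple_params.K_pyr, simple_params) == 0.5
        p = simple_params.updated(K_pyr=1.0)
        assert pyruvate_drain_term(3.0, p) == pytest.approx(0.75)
        with pytest.raises(ValueError):
            pyruvate_drain_term(-0.1, simple_params)

    @given(S=st.floats(0, 200), PA=st.floats(0, 100), AA=st.floats(0, 100))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_uptake_bounded(self, S, PA, AA):
        p = reference_parameters("wgs7-like")
        qs = substrate_uptake_rate(S, PA, AA, p)
        assert 0.0 <= qs <= p.rs_max

    def test_uptake_monotonicity_on_grids(self):
        p = reference_parameters("wgs7-like")
        S = np.linspace(0, 120, 25)
        qs_S = [substrate_uptake_rate(s, 10, 5, p) for s in S]
        assert np.all(np.diff(qs_S) >= 0)
        PA = np.linspace(0, 80, 25)
        qs_PA = [substrate_uptake_rate(40, pa, 5, p) for pa in PA]
        assert np.all(np.diff(qs_PA) <= 0)
        AA = np.linspace(0, 40, 25)
        qs_AA = [substrate_uptake_rate(40, 10, aa, p) for aa in AA]
        assert np.all(np.diff(qs_AA) <= 0)


class TestDerivatives:
    def test_zero_biomass_freezes_everything(self, simple_params):
        state = FermentationState(X=0.0, S=50.0, PA=5.0, PYR=1.0, AA=2.0, SA=1.0)
        assert np.all(batch_derivatives(state, simple_params) == 0.0)

    def test_no_pyruvate_no_drain(self, simple_params):
        state = FermentationState(X=1.0, S=50.0, PA=5.0, PYR=0.0, AA=2.0, SA=1.0)
        d = batch_derivatives(state, simple_params)
        qs = substrate_uptake_rate(50.0, 5.0, 2.0, simple_params)
        u = growth_rate(qs, simple_params)
        expected = (simple_params.K2 * u + simple_params.beta_pyr) * 1.0
        assert d[SPECIES.index("PYR")] == pytest.approx(expected, rel=1e-12)

    def test_batch_matches_scalar_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = random_params(rng)
            state = random_state(rng)
            d = batch_derivatives(state, p)
            expect = scalar_batch_rhs(
                {k: getattr(state, k) for k in SPECIES}, p.as_dict())
            for i, name in enumerate(SPECIES):
                assert d[i] == pytest.approx(expect[name], rel=1e-12, abs=1e-14)

    def test_fedbatch_matches_scalar_oracle(self):
        rng = np.random.default_rng(11)
        feed = FeedProfile.constant(0.01, 0.0, 100.0, 300.0)
        for _ in range(50):
            p = random_params(rng)
            state = random_state(rng, with_volume=True)
            d = fedbatch_derivatives(state, p, feed, t=50.0)
            sd = {k: getattr(state, k) for k in SPECIES} | {"V": state.V}
            expect = scalar_fedbatch_rhs(sd, p.as_dict(), 0.01, 300.0)
            for i, name in enumerate(SPECIES + ("V",)):
                assert d[i] == pytest.approx(expect[name], rel=1e-12, abs=1e-14)

    def test_zero_feed_reduces_to_batch(self):
        rng = np.random.default_rng(3)
        feed = FeedProfile.none()
        for _ in range(200):
            p = random_params(rng)
            state = random_state(rng, with_volume=True)
            db = batch_derivatives(state, p)
            dfb = fedbatch_derivatives(state, p, feed, t=rng.uniform(0, 100))
            assert np.allclose(dfb[:6], db, atol=1e-12)
            assert dfb[6] == 0.0

    def test_hand_dilution_rate(self):
        # D = F/V at the bundled feed rate and working volume
        p = reference_parameters("wgs7-like")
        feed = FeedProfile.constant(0.0066, 40.0, 64.0, 350.0)
        state = FermentationState(X=1.0, S=10.0, V=0.7)
        d = fedbatch_derivatives(state, p, feed, t=50.0)
        D = 0.0066 / 0.7
        assert D == pytest.approx(0.0094286, abs=1e-6)
        # dPA/dt picks up exactly -D*PA relative to batch
        db = batch_derivatives(state, p)
        assert d[2] - db[2] == pytest.approx(-D * state.PA, rel=1e-12)


class TestSimulate:
    def test_zero_inoculum_stays_flat(self, simple_params):
        init = FermentationState(X=0.0, S=50.0, PA=1.0)
        ts = simulate(init, simple_params, np.linspace(0, 50, 11))
        for name in SPECIES:
            assert np.allclose(ts.frame[name], getattr(init, name), atol=1e-9)

    def test_batch_monotone_sucrose_and_product(self, wgs7_batch):
        ts, _, _ = wgs7_batch
        assert np.all(np.diff(ts.frame["S"]) <= 1e-9)
        assert np.all(np.diff(ts.frame["PA"]) >= -1e-9)

    def test_nonnegative_trajectories(self, wgs7_batch, wgs7_fedbatch):
        for ts in (wgs7_batch[0], wgs7_fedbatch[0]):
            for name in SPECIES:
                assert ts.frame[name].min() >= -1e-7

    def test_volume_closed_form(self, wgs7_fedbatch):
        ts, _, init, feed = wgs7_fedbatch
        expect = init.V + np.array([feed.fed_volume(t) for t in ts.times])
        assert np.allclose(ts.frame["V"], expect, rtol=1e-9)

    def test_fedbatch_sucrose_mass_closure(self, wgs7_fedbatch):
        ts, _, init, feed = wgs7_fedbatch
        f = ts.frame
        residual = (f.V * f.S - init.V * init.S + f.consumed_g - f.fed_g)
        scale = init.V * init.S + feed.fed_sucrose(np.inf)
        assert np.abs(residual).max() / scale < 1e-5

    def test_adaptive_matches_rk4_oracle(self):
        # tiny fixed-step RK4 agrees with the adaptive solver
        for scenario in ("wgs7-like", "wildtype-like"):
            p = reference_parameters(scenario)
            init = FermentationState(X=0.08, S=80.0)
            ts = simulate(init, p, [0.0, 50.0])
            oracle = rk4_batch({k: getattr(init, k) for k in SPECIES},
                               p.as_dict(), t_end=50.0, dt=1e-2)
            for name in SPECIES:
                got = ts.frame[name].iloc[-1]
                ref = oracle[name]
                # absolute floor covers species pinned at exhaustion:
                # the coarse fixed step overshoots the non-negativity
                # ramp by ~1e-5 g/L, far below the detection limit
                assert got == pytest.approx(ref, rel=1e-5, abs=1e-4)

    def test_determinism(self, wgs7_batch):
        ts, p, init = wgs7_batch
        again = simulate(init, p, ts.times)
        assert np.array_equal(ts.frame.to_numpy(), again.frame.to_numpy())

    def test_feed_boundary_restart_consistency(self):
        # volume kink at the segment edges is resolved exactly
        p = reference_parameters("wgs7-like")
        feed = FeedProfile.constant(0.0066, 40.0, 64.0, 350.0)
        init = FermentationState(X=0.075, S=80.0, V=0.7)
        grid = np.array([0.0, 39.5, 40.0, 41.0, 63.0, 64.0, 65.0, 100.0])
        ts = simulate(init, p, grid, mode="fedbatch", feed=feed)
        V = ts.frame["V"]
        assert V.loc[40.0] == pytest.approx(0.7, rel=1e-10)
        assert V.loc[64.0] == pytest.approx(0.7 + 0.0066 * 24, rel=1e-9)
        assert V.loc[100.0] == pytest.approx(V.loc[64.0], rel=1e-12)

    def test_requires_increasing_grid_and_feed(self, simple_params):
        init = FermentationState(X=0.1, S=10.0)
        with pytest.raises(ValueError):
            simulate(init, simple_params, [0.0, 2.0, 1.0])
        with pytest.raises(ValueError):
            simulate(init, simple_params, [0.0, 1.0], mode="fedbatch")


class TestDomainTypes:
    @pytest.mark.parametrize("field,value", [
        ("rs_max", 0.0), ("Ks", -1.0), ("kipa", 0.0), ("Yxs", 1.6),
        ("Yxs", 0.0), ("ms", -0.1), ("K3", -0.5), ("beta_pa", -2.0),
    ])
    def test_parameter_invariants(self, simple_params, field, value):
        with pytest.raises(ValueError):
            simple_params.updated(**{field: value})

    def test_parameter_roundtrip(self, simple_params):
        arr = simple_params.to_array()
        assert KineticParameters.from_array(arr) == simple_params
        assert KineticParameters.from_dict(simple_params.as_dict()) == simple_params

    def test_parameter_dict_rejects_unknown_keys(self, simple_params):
        d = simple_params.as_dict() | {"mystery": 1.0}
        with pytest.raises(ValueError, match="unknown"):
            KineticParameters.from_dict(d)

    def test_state_invariants(self):
        with pytest.raises(ValueError):
            FermentationState(X=-0.1, S=1.0)
        with pytest.raises(ValueError):
            FermentationState(X=0.1, S=1.0, V=0.0)

    def test_feed_profile_invariants(self):
        with pytest.raises(ValueError):
            FeedProfile(segments=((10.0, 5.0, 0.01),), So=100.0)
        with pytest.raises(ValueError):
            FeedProfile(segments=((0.0, 10.0, 0.01), (5.0, 15.0, 0.02)),
                        So=100.0)
        with pytest.raises(ValueError):
            FeedProfile(segments=((0.0, 10.0, -0.01),), So=100.0)

    def test_feed_profile_rate_and_cumulative(self):
        feed = FeedProfile(segments=((10.0, 20.0, 0.01), (30.0, 40.0, 0.02)),
                           So=200.0)
        assert feed.rate(5.0) == 0.0
        assert feed.rate(15.0) == 0.01
        assert feed.rate(25.0) == 0.0
        assert feed.rate(35.0) == 0.02
        assert feed.fed_volume(50.0) == pytest.approx(0.1 + 0.2)
        assert feed.fed_sucrose(35.0) == pytest.approx((0.1 + 0.05 * 2) * 200)
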
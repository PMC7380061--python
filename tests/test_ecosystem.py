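"""Box model: process terms, coupled tendencies, integration behaviour."""

import numpy as np
import pytest

import sizebef as sb
from sizebef.ecosystem import _pack_params, _rhs
from sizebef.moments import P_FLOOR, V_FLOOR, growth_profile
from sizebef._core import _rhs_box


@pytest.fixture(scope="module")
def closed_eco():
    """No exchange with the outside: mixing, export and scavenging off."""
    return sb.EcosystemParams(mixing=0.0, export=0.0, scavenging=0.0)


@pytest.fixture(scope="module")
def fixture_state():
    ts = sb.TraitState(P=0.8, mean_l=2.5, var_v=0.08)
    return sb.BoxState.from_moments(ts, N=1.5, Z=0.4, D=0.3, fer=0.5, DETFe=0.02)


class TestGrazing:
    def test_zero_prey_or_predator(self, eco):
        assert sb.grazing_total(0.0, 1.0, eco) == 0.0
        assert sb.grazing_total(1.0, 0.0, eco) == 0.0

    def test_half_saturation(self, eco):
        assert sb.grazing_total(eco.K_p, 2.0, eco) == pytest.approx(eco.g_max * 2.0 / 2.0)

    def test_saturation(self, eco):
        assert sb.grazing_total(1e6, 3.0, eco) == pytest.approx(eco.g_max * 3.0, rel=1e-9)


class TestKillTheWinner:
    def test_unbiased_grazing_leaves_moments(self):
        ts = sb.TraitState(P=1.0, mean_l=2.0, var_v=0.5)
        dP, dl, dv = sb.ktw_moment_effects(ts, G=0.2, a_g=0.0)
        assert (dP, dl, dv) == (-0.2, 0.0, 0.0)

    def test_variance_source_arithmetic(self):
        # (G/P) v a_g / (1 + a_g) with G/P = 0.2, v = 0.5, a_g = 0.1
        ts = sb.TraitState(P=1.0, mean_l=0.0, var_v=0.5)
        _, _, dv = sb.ktw_moment_effects(ts, G=0.2, a_g=0.1)
        assert dv == pytest.approx(0.2 * 0.5 * 0.1 / 1.1, rel=1e-12)

    def test_vanishing_biomass_no_contributions(self):
        ts = sb.TraitState(P=P_FLOOR / 10.0, mean_l=1.0, var_v=0.3)
        assert sb.ktw_moment_effects(ts, G=0.1, a_g=0.1) == (0.0, 0.0, 0.0)

    def test_against_binned_distribution_oracle(self):
        """One small KTW step on a 2000-bin Gaussian matches the closed form."""
        mean, v, P, a_g = 2.0, 0.5, 1.0, 0.1
        ls = np.linspace(mean - 6 * np.sqrt(v), mean + 6 * np.sqrt(v), 2000)
        pdf = np.exp(-((ls - mean) ** 2) / (2 * v))
        b = P * pdf / pdf.sum()
        G_over_P, dt = 0.2, 0.01  # small step so the rate comparison is clean
        w = b ** (1.0 + a_g)
        graze = G_over_P * P * dt * w / w.sum()
        b2 = b - graze
        P2 = b2.sum()
        m2 = (b2 * ls).sum() / P2
        v2 = (b2 * (ls - m2) ** 2).sum() / P2
        dv_oracle = (v2 - v) / dt
        ts = sb.TraitState(P=P, mean_l=mean, var_v=v)
        _, dl, dv = sb.ktw_moment_effects(ts, G=G_over_P * P, a_g=a_g)
        assert dl == 0.0
        assert dv == pytest.approx(dv_oracle, rel=0.05)


class TestTraitDiffusion:
    def test_zero_coefficient(self, params, env_mid):
        ts = sb.TraitState(P=1.0, mean_l=2.0, var_v=0.1)
        assert sb.trait_diffusion_effects(ts, env_mid, params, u=0.0) == 0.0

    def test_no_growth_no_mutation(self, params):
        dark = sb.Environment(N=1.0, fer=0.6, I=0.0)
        ts = sb.TraitState(P=1.0, mean_l=2.0, var_v=0.1)
        assert sb.trait_diffusion_effects(ts, dark, params, u=0.1) == 0.0

    def test_proportional_to_growth(self, params, env_mid):
        ts = sb.TraitState(P=1.0, mean_l=2.0, var_v=0.1)
        mu = growth_profile(2.0, env_mid, params).mu
        dv = sb.trait_diffusion_effects(ts, env_mid, params, u=0.1)
        assert dv == pytest.approx(2.0 * 0.1 * float(mu), rel=1e-12)
        assert dv > 0.0


class TestTendencies:
    def test_closed_box_nitrogen_is_conserved(self, params, closed_eco, fixture_state):
        env = sb.Environment(N=1.5, fer=0.5, I=90.0)
        d = sb.tendencies(fixture_state, env, params, closed_eco, sb.DiversityControls())
        assert d.N + d.P + d.Z + d.D == pytest.approx(0.0, abs=1e-12)

    def test_closed_box_iron_is_conserved(self, params, closed_eco, fixture_state):
        env = sb.Environment(N=1.5, fer=0.5, I=90.0)
        d = sb.tendencies(fixture_state, env, params, closed_eco, sb.DiversityControls())
        R = closed_eco.fe_n_ratio
        assert d.fer + d.DETFe + R * (d.P + d.Z) == pytest.approx(0.0, abs=1e-12)

    def test_variance_reduces_to_selection_without_grazers_or_mutation(
        self, params, eco, fixture_state
    ):
        state = sb.BoxState(**{**fixture_state.__dict__, "Z": 0.0})
        env = sb.Environment(N=state.N, fer=state.fer, I=90.0)
        d = sb.tendencies(state, env, params, eco, sb.DiversityControls(u=0.0, a_g=0.0))
        ts = state.trait_state()
        # recover dv from the raw-moment tendencies via the product rule
        dl = sb.mean_trait_tendency(ts, env, params)
        dv = (
            d.PM2 - d.P * (ts.mean_l**2 + ts.var_v) - ts.P * 2.0 * ts.mean_l * dl
        ) / ts.P
        assert dv == pytest.approx(
            float(sb.variance_tendency_selection(ts, env, params)), rel=1e-9
        )

    def test_process_sum_oracle(self, params, eco, fixture_state):
        """Full tendencies equal the sum of the individually tested processes."""
        state = fixture_state
        env = sb.Environment(N=state.N, fer=state.fer, I=90.0)
        dc = sb.DiversityControls(u=0.05, a_g=0.08)
        d = sb.tendencies(state, env, params, eco, dc)

        ts = state.trait_state()
        g = growth_profile(ts.mean_l, env, params)
        mu_com = float(sb.community_growth(ts, env, params))
        uptake = ts.P * mu_com
        G = float(sb.grazing_total(state.P, state.Z, eco))
        zmort = eco.mort_z * state.Z**2
        pmort = eco.mort_p * state.P

        assert d.P == pytest.approx(uptake - G - pmort, rel=1e-12)
        assert d.Z == pytest.approx(eco.gge * G - zmort, rel=1e-12)
        assert d.D == pytest.approx(
            eco.unassim * G + pmort + zmort - (eco.remin + eco.export) * state.D, rel=1e-12
        )
        assert d.N == pytest.approx(
            eco.remin * state.D + eco.excretion * G
            + eco.mixing * (eco.N_deep - state.N) - uptake,
            rel=1e-12,
        )
        # trait tendencies assembled from the tested process terms
        dl = float(sb.mean_trait_tendency(ts, env, params))
        _, _, dv_ktw = sb.ktw_moment_effects(ts, G, dc.a_g)
        dv = (
            float(sb.variance_tendency_selection(ts, env, params))
            + dv_ktw
            + float(sb.trait_diffusion_effects(ts, env, params, dc.u))
        )
        assert d.PM1 == pytest.approx(d.P * ts.mean_l + ts.P * dl, rel=1e-9)
        assert d.PM2 == pytest.approx(
            d.P * (ts.mean_l**2 + ts.var_v) + ts.P * (2 * ts.mean_l * dl + dv), rel=1e-9
        )

    def test_compiled_kernel_matches_reference_tendencies(self, params, eco, fixture_state):
        """The numba right-hand side agrees with the numpy contract path."""
        y = fixture_state.to_array()
        dc = sb.DiversityControls(u=0.03, a_g=0.05)
        ref = _rhs(y, 8.0, 0.9, 110.0, 15.0, params, eco, dc, False)
        ap, ev, _ = _pack_params(params, eco, sb.Forcing())
        dy = np.empty_like(y)
        _rhs_box(y, dy, 8.0, 0.9, 110.0, 1.0, ap, ev, dc.u, dc.a_g, False)
        np.testing.assert_allclose(dy, ref, rtol=1e-12)


class TestIntegrate:
    def test_exponential_growth_in_replete_unlosing_limit(self, params):
        """No grazing/mortality/mixing: P grows at the community rate."""
        ep = sb.EcosystemParams(
            g_max=0.0, mort_p=0.0, mort_z=0.0, mixing=0.0, export=0.0, scavenging=0.0
        )
        ts = sb.TraitState(P=0.01, mean_l=2.0, var_v=V_FLOOR)
        state = sb.BoxState.from_moments(ts, N=5000.0, Z=0.0, D=0.0, fer=500.0)
        f = sb.Forcing.constant(supply=5000.0, light=2000.0, fer=500.0)
        run = sb.integrate(state, f, params, ep, years=1)
        env = sb.Environment(N=5000.0, fer=500.0, I=2000.0)
        mu = float(sb.growth_rate(2.0, env, params))
        # daily-mean biomass on day 5, while resources are still replete:
        # integral of P0 e^(mu t) over [4, 5]
        expected = 0.01 * (np.exp(mu * 5.0) - np.exp(mu * 4.0)) / mu
        assert run.data["P"][4] == pytest.approx(expected, rel=0.02)

    def test_closed_box_conservation_one_year(self, params, closed_eco):
        state = sb.BoxState.from_moments(
            sb.TraitState(P=0.5, mean_l=2.0, var_v=0.05), N=3.0
        )
        run = sb.integrate(state, sb.Forcing.constant(), params, closed_eco, years=1)
        tot = run.data["N"] + run.data["P"] + run.data["Z"] + run.data["D"]
        assert np.max(np.abs(tot - tot[0])) / tot[0] < 1e-10

    def test_fixed_variance_holds_initial_value(self, params, eco):
        state = sb.BoxState.from_moments(sb.TraitState(P=0.25, mean_l=4.0, var_v=0.07))
        run = sb.integrate(state, sb.Forcing(), params, eco, years=1, fixed_variance=True)
        assert np.allclose(run.data["var_v"], 0.07, rtol=1e-9)

    def test_mean_size_tracks_nutrient_pulse_and_depletion(self, params, eco):
        """A nutrient pulse selects larger opportunists; depletion selects
        smaller gleaners (transient response of the mean trait)."""
        ts = sb.TraitState(P=0.25, mean_l=1.5, var_v=0.3)
        pulsed = sb.BoxState.from_moments(ts, N=25.0)
        starved = sb.BoxState.from_moments(ts, N=0.02)
        lean_supply = sb.Forcing.constant(supply=0.02)
        up = sb.integrate(pulsed, lean_supply, params, eco, years=1)
        down = sb.integrate(starved, lean_supply, params, eco, years=1)
        assert up.data["mean_l"][20] > 1.5
        assert down.data["mean_l"][20] < 1.5

    def test_variance_floor_under_competitive_exclusion(self, params, eco):
        run = sb.integrate(
            sb.BoxState.from_moments(sb.TraitState(P=0.25, mean_l=3.0, var_v=0.05)),
            sb.Forcing.constant(),
            params,
            eco,
            dc=sb.DiversityControls(u=0.0, a_g=0.0),
            years=10,
        )
        v = run.data["var_v"]
        assert np.all(np.diff(v) <= 1e-12)  # selection only ever erodes variance
        assert v[-1] < 0.3 * v[0]  # hyperbolic decay toward the floor
        assert v[-1] >= V_FLOOR

    def test_replicate_batch_matches_single_runs(self, params, eco):
        # The adaptive step sequence is shared across batch columns, so a
        # batch and a stand-alone run are the same model at slightly
        # different discretisations; trajectories must agree closely.
        means = np.array([1.0, 6.0])
        ts = sb.TraitState(P=np.full(2, 0.25), mean_l=means, var_v=np.full(2, 0.05))
        batch = sb.integrate(sb.BoxState.from_moments(ts), sb.Forcing(), params, eco, years=1)
        for j, ml in enumerate(means):
            single = sb.integrate(
                sb.BoxState.from_moments(sb.TraitState(P=0.25, mean_l=ml, var_v=0.05)),
                sb.Forcing(),
                params,
                eco,
                years=1,
            )
            np.testing.assert_allclose(
                batch.data["NPP"][:, j], single.data["NPP"], rtol=0.02, atol=0.5
            )

    def test_mask_records_failed_replicate(self, params, eco):
        ts = sb.TraitState(P=np.array([0.25, 1e300]), mean_l=np.array([2.0, 2.0]),
                           var_v=np.array([0.05, 0.05]))
        run = sb.integrate(
            sb.BoxState.from_moments(ts), sb.Forcing(), params, eco, years=1, on_nan="mask"
        )
        assert run.metadata["failed_replicates"] == [1]
        assert np.isfinite(run.data["P"][:, 0]).all()
        assert np.isnan(run.data["P"][-1, 1])

    def test_rejects_bad_arguments(self, params, eco):
        state = sb.BoxState.from_moments(sb.TraitState(P=0.25, mean_l=2.0, var_v=0.05))
        with pytest.raises(ValueError):
            sb.integrate(state, sb.Forcing(), params, eco, years=0)
        with pytest.raises(ValueError):
            sb.integrate(state, sb.Forcing(), params, eco, dt=0.5)
        with pytest.raises(ValueError):
            sb.integrate(state, sb.Forcing(), params, eco, on_nan="explode")


class TestParamValidation:
    def test_ecosystem_invariants(self):
        with pytest.raises(ValueError):
            sb.EcosystemParams(gge=0.0)
        with pytest.raises(ValueError):
            sb.EcosystemParams(gge=0.8, unassim=0.5)
        with pytest.raises(ValueError):
            sb.EcosystemParams(mixing=-0.1)

    def test_controls_nonnegative(self):
        with pytest.raises(ValueError):
            sb.DiversityControls(u=-0.01)
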
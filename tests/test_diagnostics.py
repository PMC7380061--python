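"""Attribution diagnostics and size-distribution observables."""

import numpy as np
import pytest
from scipy.stats import norm

import sizebef as sb
from sizebef.runio import RunOutput


def make_run(n=365, **series):
    """Minimal single-replicate RunOutput from explicit daily series."""
    time = np.arange(1.0, n + 1.0)
    base = {
        "P": np.full(n, 1.0),
        "mu": np.full(n, 0.8),
        "QN": np.full(n, 0.1),
        "var_v": np.full(n, 0.05),
        "d2muQ": np.full(n, -0.3),
        "N": np.full(n, 1.0),
        "I": np.full(n, 100.0),
        "fer": np.full(n, 1e6),
        "mean_l": np.full(n, 2.0),
    }
    base.update({k: np.asarray(v, dtype=float) for k, v in series.items()})
    base["NPP"] = 12.0 * base["P"] * (
        base["mu"] / base["QN"] + 0.5 * base["var_v"] * base["d2muQ"]
    )
    return RunOutput(time, base, {})


class TestChainDecomposition:
    def test_identical_runs_give_zero_everything(self):
        run = make_run()
        res = sb.chain_decomposition(run, run, delta_u=0.1)
        assert res.total == 0.0
        assert res.terms_sum == 0.0
        assert res.residual == 0.0

    def test_single_factor_biomass_perturbation(self):
        """Only P differs (v = 0): the whole difference flows through term_P."""
        a = make_run(var_v=np.zeros(365))
        b = make_run(var_v=np.zeros(365), P=np.full(365, 1.3))
        res = sb.chain_decomposition(a, b, delta_u=0.1)
        assert res.term_P != 0.0
        for name in ("term_mu", "term_QN", "term_curv", "term_v"):
            assert getattr(res, name) == 0.0
        assert res.term_P_curv == 0.0  # v = 0 kills the curvature cross-term
        assert res.residual == pytest.approx(0.0, abs=1e-9 * abs(res.total))
        assert res.total == pytest.approx(res.term_P, rel=1e-12)

    def test_midpoint_split_is_exact_for_two_factor_products(self):
        """Differences in mu and P together leave only the triple-product
        residual, which is second-order small."""
        a = make_run(var_v=np.zeros(365))
        b = make_run(
            var_v=np.zeros(365),
            P=np.full(365, 1.1),
            mu=np.full(365, 0.88),
        )
        res = sb.chain_decomposition(a, b, delta_u=0.05)
        assert abs(res.residual) < 0.02 * abs(res.total)

    def test_box_model_pair_self_consistency(self, params, eco):
        """Paired low/high trait-diffusion runs: terms sum to the exact
        normalised NPP difference within a small residual."""
        state = sb.BoxState.from_moments(sb.TraitState(P=0.25, mean_l=2.0, var_v=0.05))
        runs = {}
        for u in (0.0, 0.1):
            runs[u] = sb.integrate(
                state, sb.Forcing(), params, eco, sb.DiversityControls(u=u), years=3
            )
        res = sb.chain_decomposition(runs[0.0], runs[0.1], delta_u=0.1)
        assert res.total != 0.0
        assert abs(res.residual) <= 0.05 * abs(res.total)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            sb.chain_decomposition(make_run(100), make_run(200), delta_u=0.1)
        with pytest.raises(ValueError):
            sb.chain_decomposition(make_run(), make_run(), delta_u=0.0)

    def test_weights_scale_terms(self):
        a = make_run(var_v=np.zeros(365))
        b = make_run(var_v=np.zeros(365), P=np.full(365, 1.2))
        r1 = sb.chain_decomposition(a, b, delta_u=0.1)
        r2 = sb.chain_decomposition(a, b, delta_u=0.1, weights=np.full(365, 2.0))
        assert r2.term_P == pytest.approx(2.0 * r1.term_P, rel=1e-12)


class TestTaylorDecomposition:
    def test_constant_series_has_no_second_order_terms(self, params):
        run = make_run()
        res = sb.taylor_decomposition(run, params)
        for name in ("var_l", "var_N", "var_I", "cov_lN", "cov_lI", "cov_IN"):
            assert getattr(res, name) == pytest.approx(0.0, abs=1e-12)
        assert res.base == pytest.approx(res.mu_bar, rel=1e-12)
        assert not res.limiter_switched

    def test_quadrature_phase_kills_covariance(self, params):
        """mean_l and N varying 90 degrees out of phase have ~zero covariance."""
        t = np.arange(365.0)
        run = make_run(
            mean_l=2.0 + 0.3 * np.sin(2 * np.pi * t / 365),
            N=1.0 + 0.4 * np.cos(2 * np.pi * t / 365),
        )
        res = sb.taylor_decomposition(run, params)
        assert abs(res.cov_lN) < 1e-3 * max(abs(res.var_l), abs(res.var_N))

    def test_exact_for_quadratic_fitness(self):
        """A fitness quadratic in (l, N, I) jointly is reconstructed exactly."""
        def mu_func(l, n, i):
            return (
                0.5 + 0.1 * l - 0.04 * l**2 + 0.02 * n - 0.001 * n**2
                + 0.0005 * i - 1e-6 * i**2 + 0.003 * l * n - 0.0002 * l * i
                + 1e-5 * n * i
            )

        t = np.arange(365.0)
        run = make_run(
            mean_l=2.0 + 0.5 * np.sin(2 * np.pi * t / 365),
            N=1.0 + 0.5 * np.sin(2 * np.pi * t / 365 + 0.7),
            I=100.0 + 30.0 * np.sin(2 * np.pi * t / 365 + 1.9),
        )
        res = sb.taylor_decomposition(run, mu_func=mu_func)
        assert res.reconstruction_error == pytest.approx(0.0, abs=1e-10 * abs(res.mu_bar))

    def test_small_amplitude_reconstruction(self, params):
        """For the real growth function the second-order expansion reproduces
        the time mean up to the cubic remainder."""
        t = np.arange(365.0)
        eps = 0.05
        run = make_run(
            mean_l=2.0 + eps * np.sin(2 * np.pi * t / 365),
            N=1.0 * (1.0 + eps * np.sin(2 * np.pi * t / 365 + 0.5)),
            I=100.0 * (1.0 + eps * np.sin(2 * np.pi * t / 365 + 2.1)),
        )
        res = sb.taylor_decomposition(run, params)
        assert abs(res.reconstruction_error) < 1e-3 * abs(res.mu_bar)

    def test_limiter_switch_flagged(self, params):
        t = np.arange(365.0)
        fer = np.where(t < 180, 1e6, 1e-4)  # iron crashes mid-window
        run = make_run(fer=fer)
        res = sb.taylor_decomposition(run, params)
        assert res.limiter_switched

    def test_window_validation(self, params):
        with pytest.raises(ValueError):
            sb.taylor_decomposition(make_run(), params, window=1)


class TestPicoFraction:
    def test_mean_at_threshold_gives_half(self):
        lc = sb.esd_to_logvolume(2.0)
        for v in (0.01, 0.5, 3.0):
            ts = sb.TraitState(P=1.0, mean_l=lc, var_v=v)
            assert sb.pico_fraction(ts) == pytest.approx(0.5)

    def test_variance_free_step_function(self):
        lc = sb.esd_to_logvolume(2.0)
        below = sb.TraitState(P=1.0, mean_l=lc - 1.0, var_v=0.0)
        above = sb.TraitState(P=1.0, mean_l=lc + 1.0, var_v=0.0)
        assert sb.pico_fraction(below) == 1.0
        assert sb.pico_fraction(above) == 0.0

    def test_normal_cdf_oracle(self):
        ts = sb.TraitState(P=1.0, mean_l=3.0, var_v=1.0)
        lc = sb.esd_to_logvolume(2.0)
        assert sb.pico_fraction(ts) == pytest.approx(norm.cdf(lc - 3.0), rel=1e-9)

    def test_monotone_decreasing_in_mean_size(self):
        means = np.linspace(-2.0, 10.0, 40)
        fracs = [
            sb.pico_fraction(sb.TraitState(P=1.0, mean_l=m, var_v=0.5)) for m in means
        ]
        assert np.all(np.diff(fracs) < 0)

    def test_alternative_threshold(self):
        ts = sb.TraitState(P=1.0, mean_l=sb.esd_to_logvolume(3.0), var_v=0.2)
        assert sb.pico_fraction(ts, threshold_diameter=3.0) == pytest.approx(0.5)


class TestSizeDiversity:
    def test_identity_and_scale_invariance(self):
        ts = sb.TraitState(P=2.0, mean_l=1.0, var_v=0.7)
        assert sb.size_diversity(ts) == 0.7
        scaled = sb.TraitState(P=20.0, mean_l=1.0, var_v=0.7)
        assert sb.size_diversity(scaled) == sb.size_diversity(ts)

    def test_matches_discrete_community(self):
        c = sb.SpeciesCommunity(sizes=[0.0, 2.0], biomasses=[0.5, 0.5])
        assert sb.size_diversity(sb.community_moments(c)) == pytest.approx(1.0)
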
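"""Moment-closure dynamics of the community size distribution.

The phytoplankton community is summarised by three statistics of a
(log-normal) size distribution: nitrogen biomass ``P``, mean log cell
volume ``l_bar`` and trait variance ``v``.  Closing the growth terms at
second order in the trait gives

* community growth      mu_com = mu(l_bar) + (v/2) mu''(l_bar)
* mean-trait tendency   dl_bar/dt = v mu'(l_bar)
* variance tendency     dv/dt = v^2 mu''(l_bar)          (selection only)

The mean-trait equation is a Fisher-type selection law: the community mean
moves up the local fitness gradient at a speed proportional to diversity
(the insurance effect).  Near a fitness peak the curvature is negative,
so selection erodes variance (competitive exclusion).

Carbon-based net primary production applies the same closure to the
carbon-specific growth rate mu / Q_N, which is where a flexible quota can
turn a nitrogen-based gain into a carbon-based loss.

Trait derivatives are central finite differences with a fixed step; at a
Liebig crossover the derivatives follow the limiter that is active exactly
at the community mean (ties resolve to nitrogen).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np

from .allometry import (
    AllometricParams,
    Environment,
    eppley_factor,
    half_saturation_fer,
    half_saturation_N,
)

__all__ = [
    "TraitState",
    "TraitDerivatives",
    "GrowthProfile",
    "DERIV_STEP",
    "V_FLOOR",
    "P_FLOOR",
    "trait_derivatives",
    "growth_profile",
    "community_growth",
    "mean_trait_tendency",
    "variance_tendency_selection",
    "community_npp",
    "moments_to_raw",
    "raw_to_moments",
]

#: Trait-derivative step, ln um^3.  O(h^2) central-difference error is far
#: below the closure's own truncation error for the exponential forms used.
DERIV_STEP = 1.0e-3

#: Variance floor, (ln um^3)^2 — keeps the distribution non-degenerate.
V_FLOOR = 1.0e-4

#: Biomass floor, mmol N m^-3 — keeps moment ratios and divisions defined.
P_FLOOR = 1.0e-6

#: mg C per mmol C, converting molar carbon production to mass units.
CARBON_MG_PER_MMOL = 12.0


@dataclass
class TraitState:
    """Biomass P (mmol N m^-3), mean log-volume l_bar, trait variance v."""

    P: float | np.ndarray
    mean_l: float | np.ndarray
    var_v: float | np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.P) < 0):
            raise ValueError("TraitState.P must be >= 0")
        if np.any(np.asarray(self.var_v) < 0):
            raise ValueError("TraitState.var_v must be >= 0")


@dataclass
class TraitDerivatives:
    """Value, first and second trait derivative of a function at l_bar."""

    f0: float | np.ndarray
    f1: float | np.ndarray
    f2: float | np.ndarray


class GrowthProfile(NamedTuple):
    """Growth and carbon-growth derivatives at the community mean trait.

    mu, mu1, mu2: realised growth rate and its first/second trait
    derivatives; cg, cg1, cg2: same for the carbon-specific rate mu/Q_N;
    Q: quota at the mean; nitrogen_limited: active Liebig branch there.
    """

    mu: np.ndarray
    mu1: np.ndarray
    mu2: np.ndarray
    cg: np.ndarray
    cg1: np.ndarray
    cg2: np.ndarray
    Q: np.ndarray
    nitrogen_limited: np.ndarray


def trait_derivatives(f: Callable, at, h: float = DERIV_STEP) -> TraitDerivatives:
    """Central-difference value/slope/curvature of a scalar trait function.

    Exact for polynomials up to cubic (first derivative) and quadratic
    (second derivative).  Non-finite evaluations raise, naming the trait
    value responsible.
    """
    if not h > 0:
        raise ValueError("step h must be > 0")
    at = np.asarray(at, dtype=float)
    fm, f0, fp = f(at - h), f(at), f(at + h)
    for val, where in ((fm, at - h), (f0, at), (fp, at + h)):
        if not np.all(np.isfinite(val)):
            raise FloatingPointError(f"non-finite function value at l = {where}")
    return TraitDerivatives(f0, (fp - fm) / (2.0 * h), (fp - 2.0 * f0 + fm) / (h * h))


def _phys(l, N, fer, I, p: AllometricParams, n_limited, temp_factor):
    """Growth rate and quota at trait l with the Liebig branch fixed."""
    mu_m = p.mu0 * np.exp(p.alpha_mu * l + p.beta_mu * l * l) * temp_factor
    lim_N = N / (N + p.K0_N * np.exp(p.alpha_K * l))
    lim_F = fer / (fer + p.K0_fer * np.exp(p.alpha_fer * l))
    lim = np.where(n_limited, lim_N, lim_F)
    light = -np.expm1(-p.alpha0_c * np.exp(p.alpha_I * l) * I / mu_m)
    mu = mu_m * lim * light
    Q = p.Q_min / (1.0 - (1.0 - p.Q_min / p.Q_max) * lim)
    return mu, Q


def growth_profile(
    mean_l,
    env: Environment,
    p: AllometricParams,
    h: float = DERIV_STEP,
    temperature_effect: bool = False,
) -> GrowthProfile:
    """Evaluate mu and mu/Q_N with their trait derivatives at the mean size.

    The Liebig branch is selected once, at ``mean_l`` exactly, and held
    fixed for the stencil points — the documented tie-break when the two
    limitation terms cross within the stencil.
    """
    l0 = np.asarray(mean_l, dtype=float)
    N, fer, I = env.N, env.fer, env.I
    n_limited = N / (N + half_saturation_N(l0, p)) <= fer / (fer + half_saturation_fer(l0, p))
    tf = eppley_factor(env.T) if temperature_effect else 1.0
    mu_m_, Q_m = _phys(l0 - h, N, fer, I, p, n_limited, tf)
    mu_0, Q_0 = _phys(l0, N, fer, I, p, n_limited, tf)
    mu_p, Q_p = _phys(l0 + h, N, fer, I, p, n_limited, tf)
    cg_m, cg_0, cg_p = mu_m_ / Q_m, mu_0 / Q_0, mu_p / Q_p
    inv2h, invh2 = 0.5 / h, 1.0 / (h * h)
    return GrowthProfile(
        mu=mu_0,
        mu1=(mu_p - mu_m_) * inv2h,
        mu2=(mu_p - 2.0 * mu_0 + mu_m_) * invh2,
        cg=cg_0,
        cg1=(cg_p - cg_m) * inv2h,
        cg2=(cg_p - 2.0 * cg_0 + cg_m) * invh2,
        Q=Q_0,
        nitrogen_limited=n_limited,
    )


def community_growth(ts: TraitState, env: Environment, p: AllometricParams, h: float = DERIV_STEP):
    """Community per-capita growth rate mu(l_bar) + (v/2) mu''(l_bar), d^-1."""
    g = growth_profile(ts.mean_l, env, p, h)
    return g.mu + 0.5 * ts.var_v * g.mu2


def mean_trait_tendency(ts: TraitState, env: Environment, p: AllometricParams, h: float = DERIV_STEP):
    """Selection drift of the mean trait, v mu'(l_bar), ln um^3 d^-1."""
    g = growth_profile(ts.mean_l, env, p, h)
    return ts.var_v * g.mu1


def variance_tendency_selection(
    ts: TraitState, env: Environment, p: AllometricParams, h: float = DERIV_STEP
):
    """Selection tendency of the trait variance, v^2 mu''(l_bar), (ln um^3)^2 d^-1."""
    g = growth_profile(ts.mean_l, env, p, h)
    return ts.var_v**2 * g.mu2


def community_npp(ts: TraitState, env: Environment, p: AllometricParams, h: float = DERIV_STEP):
    """Carbon-based net primary production, mg C m^-3 d^-1.

    ``12 P [ (mu/Q_N)(l_bar) + (v/2) (mu/Q_N)''(l_bar) ]``.  The curvature
    of the carbon-specific growth rate is usually negative at the dominant
    size, so diversity carries a cost of unproductive edge classes.
    """
    g = growth_profile(ts.mean_l, env, p, h)
    if np.any(np.asarray(g.Q) <= 0):  # quota is bounded below by Q_min; guard anyway
        raise FloatingPointError("non-positive quota encountered")
    return CARBON_MG_PER_MMOL * ts.P * (g.cg + 0.5 * ts.var_v * g.cg2)


def moments_to_raw(ts: TraitState):
    """Raw moment tracers (P, P l_bar, P (l_bar^2 + v)) from a trait state."""
    return ts.P, ts.P * ts.mean_l, ts.P * (ts.mean_l**2 + ts.var_v)


def raw_to_moments(P, M1, M2, v_floor: float = V_FLOOR, p_floor: float = P_FLOOR) -> TraitState:
    """Trait state from raw moment tracers, with floors.

    The implied variance ``M2/P - (M1/P)^2`` is clamped from below at the
    variance floor (raw moments violating the Cauchy-Schwarz bound can
    arise from independent transport of the tracers).  A biomass at or
    below the floor yields a flagged default state.
    """
    P = np.asarray(P, dtype=float)
    scalar = P.ndim == 0
    if scalar and P <= p_floor:
        return TraitState(P=p_floor, mean_l=0.0, var_v=v_floor, degenerate=True)
    Ps = np.maximum(P, p_floor)
    mean_l = np.asarray(M1, dtype=float) / Ps
    var_v = np.maximum(np.asarray(M2, dtype=float) / Ps - mean_l**2, v_floor)
    if scalar:
        return TraitState(P=float(P), mean_l=float(mean_l), var_v=float(var_v))
    return TraitState(P=P, mean_l=mean_l, var_v=var_v, degenerate=bool(np.any(P <= p_floor)))
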
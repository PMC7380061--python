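"""Discrete n-species counterpart of the continuous size model.

Each species is a fixed point on the log-volume trait axis with its own
biomass; all species share the same physiology (:mod:`sizebef.allometry`),
the same dissolved nutrient and iron pools, one zooplankton grazer and
one detritus pool.  This is the classic phytoplankton-nutrient
competition setup used for species-coexistence studies, and doubles as
the brute-force oracle for the moment closure: a fine grid of species
initialised from a lognormal biomass profile should track the
(P, l_bar, v) trajectory of the moment model.

Kill-the-winner grazing allocates the total grazing flux across species
proportionally to ``P_i^(1 + a_g)``, so abundant species are removed
disproportionately when ``a_g > 0``, delaying competitive exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .allometry import AllometricParams
from .forcing import Forcing
from .moments import CARBON_MG_PER_MMOL, P_FLOOR, TraitState
from .ecosystem import EcosystemParams, IntegrationError
from .runio import RunOutput

__all__ = [
    "SpeciesCommunity",
    "discrete_tendencies",
    "community_moments",
    "discrete_npp",
    "integrate_discrete",
]


@dataclass
class SpeciesCommunity:
    """Species trait positions and biomasses plus the shared pools.

    ``sizes`` and ``biomasses`` have shape (n_species,) for a single
    community or (n_replicates, n_species) for a batch; the pools are
    scalars or (n_replicates,) arrays.
    """

    sizes: np.ndarray
    biomasses: np.ndarray
    N: float | np.ndarray = 2.0
    Z: float | np.ndarray = 0.1
    D: float | np.ndarray = 0.1
    fer: float | np.ndarray = 0.6
    DETFe: float | np.ndarray = 0.01

    def __post_init__(self) -> None:
        self.sizes = np.atleast_1d(np.asarray(self.sizes, dtype=float))
        self.biomasses = np.atleast_1d(np.asarray(self.biomasses, dtype=float))
        if self.sizes.shape != self.biomasses.shape:
            raise ValueError("sizes and biomasses must have the same shape")
        if self.sizes.shape[-1] < 1:
            raise ValueError("community must contain at least one species")
        if np.any(self.biomasses < 0):
            raise ValueError("biomasses must be >= 0")


def _mu_Q(sizes, N, fer, I, p: AllometricParams):
    """Per-species growth rate and quota (sizes (..., n); pools (...,) or scalar)."""
    if np.ndim(N):
        N = np.asarray(N)[..., None]
        fer = np.asarray(fer)[..., None]
    mu_m = p.mu0 * np.exp(p.alpha_mu * sizes + p.beta_mu * sizes * sizes)
    lim_N = N / (N + p.K0_N * np.exp(p.alpha_K * sizes))
    lim_F = fer / (fer + p.K0_fer * np.exp(p.alpha_fer * sizes))
    lim = np.minimum(lim_N, lim_F)
    light = -np.expm1(-p.alpha0_c * np.exp(p.alpha_I * sizes) * I / mu_m)
    mu = mu_m * lim * light
    Q = p.Q_min / (1.0 - (1.0 - p.Q_min / p.Q_max) * lim)
    return mu, Q


def _ktw_allocation(biomasses, a_g):
    """Share of the total grazing flux taken from each species."""
    w = biomasses ** (1.0 + a_g)
    tot = w.sum(axis=-1, keepdims=True)
    return np.where(tot > 0.0, w / np.where(tot > 0.0, tot, 1.0), 0.0)


def discrete_tendencies(
    c: SpeciesCommunity,
    env,
    p: AllometricParams,
    ep: EcosystemParams,
    a_g: float = 0.0,
    N_supply: float | None = None,
    fer_supply: float | None = None,
):
    """Per-species biomass tendencies and shared-pool tendencies.

    Returns ``(dP_i, pools)`` with ``pools`` a dict of dN, dZ, dD, dfer,
    dDETFe.  Light and temperature come from ``env``; ambient N and fer
    are the community's own pools.
    """
    P_i = c.biomasses
    mu, _ = _mu_Q(c.sizes, c.N, c.fer, env.I, p)
    uptake_i = P_i * mu
    uptake = uptake_i.sum(axis=-1)
    P_tot = P_i.sum(axis=-1)
    G = ep.g_max * c.Z * P_tot * P_tot / (ep.K_p**2 + P_tot * P_tot)
    g_i = np.asarray(G)[..., None] * _ktw_allocation(P_i, a_g)
    pmort_i = ep.mort_p * P_i
    dP_i = uptake_i - g_i - pmort_i

    zmort = ep.mort_z * c.Z**2
    pmort = pmort_i.sum(axis=-1)
    N_sup = ep.N_deep if N_supply is None else N_supply
    fer_sup = ep.fer_deep if fer_supply is None else fer_supply
    R = ep.fe_n_ratio
    pools = {
        "dN": ep.remin * c.D + ep.excretion * G + ep.mixing * (N_sup - c.N) - uptake,
        "dZ": ep.gge * G - zmort,
        "dD": ep.unassim * G + pmort + zmort - (ep.remin + ep.export) * c.D,
        "dfer": ep.remin * c.DETFe + ep.excretion * G * R
        + ep.mixing * (fer_sup - c.fer) - uptake * R - ep.scavenging * c.fer,
        "dDETFe": (ep.unassim * G + pmort + zmort) * R - (ep.remin + ep.export) * c.DETFe,
    }
    return dP_i, pools


def community_moments(c: SpeciesCommunity) -> TraitState:
    """Biomass-weighted trait mean and variance of a discrete community.

    A community with (effectively) zero biomass yields a flagged empty
    state rather than dividing by zero.
    """
    P = c.biomasses.sum(axis=-1)
    if np.ndim(P) == 0 and P <= P_FLOOR:
        return TraitState(P=0.0, mean_l=0.0, var_v=0.0, degenerate=True)
    Ps = np.maximum(P, P_FLOOR)
    mean_l = (c.biomasses * c.sizes).sum(axis=-1) / Ps
    dev = c.sizes - np.expand_dims(np.asarray(mean_l), -1)
    var_v = (c.biomasses * dev * dev).sum(axis=-1) / Ps
    return TraitState(
        P=P, mean_l=mean_l, var_v=var_v, degenerate=bool(np.any(P <= P_FLOOR))
    )


def discrete_npp(c: SpeciesCommunity, env, p: AllometricParams):
    """Species-summed carbon production, mg C m^-3 d^-1: 12 sum P_i mu_i / Q_i."""
    mu, Q = _mu_Q(c.sizes, c.N, c.fer, env.I, p)
    return CARBON_MG_PER_MMOL * (c.biomasses * mu / Q).sum(axis=-1)


def integrate_discrete(
    initial: SpeciesCommunity,
    forcing: Forcing,
    p: AllometricParams | None = None,
    ep: EcosystemParams | None = None,
    a_g: float = 0.0,
    *,
    years: int = 10,
    dt: float = 0.05,
    on_nan: str = "raise",
    record_species: bool = False,
    metadata: dict | None = None,
) -> RunOutput:
    """Integrate the discrete-species model; mirrors the box integrator.

    Same RK4 scheme with the stability-bounded step as the box model.
    Daily output carries the shared pools plus the moment summary of the
    assemblage (mean_l, var_v), biomass-weighted growth rate and quota,
    and species-summed NPP.  Species positions are fixed for the whole
    run (no mutation in discrete mode); species whose biomass reaches
    zero stay extinct.
    """
    from .ecosystem import _pack_params
    from ._core import integrate_discrete_core

    p = p or AllometricParams()
    ep = ep or EcosystemParams()
    if a_g < 0:
        raise ValueError("a_g must be >= 0")
    if years < 1:
        raise ValueError("years must be >= 1")
    if not 0 < dt <= 0.1:
        raise ValueError("dt must be in (0, 0.1] days")
    if on_nan not in ("raise", "mask"):
        raise ValueError("on_nan must be 'raise' or 'mask'")

    sizes = np.atleast_2d(np.asarray(initial.sizes, dtype=float)).copy()
    m, n = sizes.shape
    B = np.broadcast_to(np.atleast_2d(initial.biomasses), (m, n)).astype(float).copy()
    pools = np.vstack([
        np.broadcast_to(np.atleast_1d(np.asarray(x, dtype=float)), (m,)).copy()
        for x in (initial.N, initial.Z, initial.D, initial.fer, initial.DETFe)
    ])  # rows: N, Z, D, fer, DETFe

    ndays = int(years * 365)
    channels = ("N", "P", "Z", "D", "fer", "DETFe", "mean_l", "var_v", "mu", "QN", "NPP", "I")
    ap, ev, fc = _pack_params(p, ep, forcing)
    out = np.empty((ndays, len(channels), m))
    species_out = np.empty((ndays, m, n)) if record_species else np.empty((1, 1, 1))
    failed = np.zeros(m, dtype=np.bool_)

    clamps, code, err_t = integrate_discrete_core(
        B, pools, sizes, ndays, float(dt), on_nan == "mask",
        ap, ev, float(a_g), fc, out, species_out, bool(record_species), failed,
    )
    if code == 1:
        raise IntegrationError(f"non-finite state at t={err_t:.2f} d in discrete model")
    if code == 2:
        raise IntegrationError(
            f"tracer below -1e-3 at t={err_t:.2f} d in discrete model; dt={dt} too large"
        )

    data = {
        name: (out[:, i, 0] if m == 1 else out[:, i, :].copy())
        for i, name in enumerate(channels)
    }
    if record_species:
        data["species_P"] = species_out[:, 0, :] if m == 1 else species_out
    meta = {
        "model": "discrete",
        "years": years,
        "dt": dt,
        "a_g": a_g,
        "n_species": n,
        "clamp_events": int(clamps),
        "failed_replicates": np.flatnonzero(failed).tolist(),
        "allometry": {f.name: getattr(p, f.name) for f in fields(p)},
        "ecosystem": {f.name: getattr(ep, f.name) for f in fields(ep)},
        "forcing": {f.name: getattr(forcing, f.name) for f in fields(forcing)},
    }
    if metadata:
        meta.update(metadata)
    return RunOutput(np.arange(1.0, ndays + 1.0), data, meta)
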
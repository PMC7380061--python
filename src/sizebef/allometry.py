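"""Size-scaling physiology of phytoplankton.

Cell size is the master trait, expressed as ``l = ln(V)`` with the cell
volume ``V`` in cubic micrometres.  Maximal growth rate is a unimodal
(log-quadratic) function of ``l``; half-saturation constants for nitrogen
and iron and the initial slope of the photosynthesis-irradiance curve scale
exponentially with ``l``.  Together these encode the gleaner/opportunist
trade-off: small cells with low half-saturation constants win under
scarcity, fast-growing intermediate cells win when resources are plentiful.

Realised growth follows Liebig's law of the minimum over Monod terms for
nitrogen and dissolved iron, multiplied by a saturating light response.
The cellular nitrogen-to-carbon quota is flexible between ``Q_min`` and
``Q_max`` and rises with nutrient availability, which is what converts
nitrogen-based growth into carbon-based production.

All functions accept scalars or numpy arrays for the trait and the
environmental fields and broadcast in the usual numpy way.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "AllometricParams",
    "Environment",
    "esd_to_logvolume",
    "logvolume_to_esd",
    "max_growth",
    "half_saturation_N",
    "half_saturation_fer",
    "photo_slope",
    "nutrient_limitation",
    "growth_rate",
    "quota",
    "carbon_growth",
    "eppley_factor",
]

#: V = (pi/6) * d^3 for an equivalent spherical diameter d.
_VOLUME_FACTOR = np.pi / 6.0


@dataclass(frozen=True)
class AllometricParams:
    """Size-scaling and stoichiometric constants.

    Parameters
    ----------
    mu0 : float
        Maximal growth rate at unit log-volume (``l = 0``), d^-1.
    alpha_mu, beta_mu : float
        Linear and quadratic coefficients of log maximal growth in ``l``
        ((ln um^3)^-1 and (ln um^3)^-2).  ``beta_mu < 0`` makes maximal
        growth unimodal with an optimum at ``-alpha_mu / (2 beta_mu)``.
    K0_N, alpha_K : float
        Nitrogen half-saturation at ``l = 0`` (mmol N m^-3) and its
        exponential size-scaling.
    K0_fer, alpha_fer : float
        Iron half-saturation at ``l = 0`` (umol Fe m^-3) and its scaling.
    alpha0_c, alpha_I : float
        Initial slope of the photosynthesis-irradiance curve at ``l = 0``
        ((W m^-2)^-1 d^-1) and its size-scaling.  Light scaling is weaker
        than nutrient scaling (``alpha_I < alpha_K``).
    Q_min, Q_max : float
        Minimal and maximal nitrogen-to-carbon quota, mol N (mol C)^-1.
    """

    mu0: float = 1.2
    alpha_mu: float = 0.2
    beta_mu: float = -0.02
    K0_N: float = 0.1
    alpha_K: float = 0.27
    K0_fer: float = 0.08
    alpha_fer: float = 0.27
    alpha0_c: float = 0.05
    alpha_I: float = 0.1
    Q_min: float = 0.06
    Q_max: float = 0.2

    def __post_init__(self) -> None:
        for name in ("mu0", "K0_N", "K0_fer", "alpha0_c"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not self.beta_mu < 0:
            raise ValueError(
                f"beta_mu must be < 0 (unimodal maximal growth), got {self.beta_mu}"
            )
        if not (self.alpha_K > self.alpha_I >= 0):
            raise ValueError(
                "require alpha_K > alpha_I >= 0 (light scaling weaker than "
                f"nutrient scaling), got alpha_K={self.alpha_K}, alpha_I={self.alpha_I}"
            )
        if not (0 < self.Q_min < self.Q_max < 1):
            raise ValueError(
                f"require 0 < Q_min < Q_max < 1, got Q_min={self.Q_min}, Q_max={self.Q_max}"
            )

    @property
    def optimal_logvolume(self) -> float:
        """Trait value maximising the maximal growth rate, ``-alpha_mu/(2 beta_mu)``."""
        return -self.alpha_mu / (2.0 * self.beta_mu)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))


@dataclass
class Environment:
    """Ambient conditions seen by the phytoplankton community.

    N in mmol N m^-3, fer in umol Fe m^-3, I in W m^-2, T in degrees C.
    The temperature field is carried for the optional Eppley-type modifier
    and is otherwise inert.
    """

    N: float | np.ndarray
    fer: float | np.ndarray
    I: float | np.ndarray
    T: float | np.ndarray = 15.0

    def __post_init__(self) -> None:
        for name in ("N", "fer", "I"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"Environment.{name} must be >= 0")


def esd_to_logvolume(diameter):
    """Log cell volume ``ln((pi/6) d^3)`` for an equivalent spherical diameter in um."""
    d = np.asarray(diameter, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be > 0")
    out = np.log(_VOLUME_FACTOR * d**3)
    return out if out.ndim else float(out)


def logvolume_to_esd(l):
    """Equivalent spherical diameter (um) for a log cell volume; inverse of esd_to_logvolume."""
    l = np.asarray(l, dtype=float)
    out = (np.exp(l) / _VOLUME_FACTOR) ** (1.0 / 3.0)
    return out if out.ndim else float(out)


def max_growth(l, p: AllometricParams):
    """Maximal (resource-replete) growth rate, d^-1: ``mu0 exp(alpha_mu l + beta_mu l^2)``."""
    l = np.asarray(l, dtype=float)
    return p.mu0 * np.exp(p.alpha_mu * l + p.beta_mu * l * l)


def half_saturation_N(l, p: AllometricParams):
    """Nitrogen half-saturation constant, mmol N m^-3, increasing with size."""
    return p.K0_N * np.exp(p.alpha_K * np.asarray(l, dtype=float))


def half_saturation_fer(l, p: AllometricParams):
    """Iron half-saturation constant, umol Fe m^-3, increasing with size."""
    return p.K0_fer * np.exp(p.alpha_fer * np.asarray(l, dtype=float))


def photo_slope(l, p: AllometricParams):
    """Initial slope of the photosynthesis-irradiance curve, (W m^-2)^-1 d^-1."""
    return p.alpha0_c * np.exp(p.alpha_I * np.asarray(l, dtype=float))


def eppley_factor(T, T_ref: float = 15.0, slope: float = 0.063):
    """Optional Eppley-type temperature multiplier ``exp(slope (T - T_ref))``.

    Off by default everywhere; pass ``temperature_effect=True`` to
    :func:`growth_rate` (or the integrator) to apply it to the maximal
    growth rate.
    """
    return np.exp(slope * (np.asarray(T, dtype=float) - T_ref))


def nutrient_limitation(l, env: Environment, p: AllometricParams, limiter: str | None = None):
    """Liebig minimum of the nitrogen and iron Monod terms, in [0, 1).

    Returns ``(limitation, nitrogen_limited)`` where ``nitrogen_limited`` is
    a boolean (array) flagging which resource is the active limiter.  Ties
    resolve to nitrogen.  ``limiter`` forces the branch ('N' or 'fer'),
    which is how trait derivatives are taken on the limiter active at the
    community mean size.
    """
    l = np.asarray(l, dtype=float)
    lim_N = env.N / (env.N + half_saturation_N(l, p))
    lim_fer = env.fer / (env.fer + half_saturation_fer(l, p))
    if limiter == "N":
        return lim_N, np.broadcast_to(True, np.shape(lim_N))
    if limiter == "fer":
        return lim_fer, np.broadcast_to(False, np.shape(lim_fer))
    if limiter is not None:
        raise ValueError(f"limiter must be 'N', 'fer' or None, got {limiter!r}")
    n_limited = lim_N <= lim_fer
    return np.where(n_limited, lim_N, lim_fer), n_limited


def growth_rate(
    l,
    env: Environment,
    p: AllometricParams,
    limiter: str | None = None,
    temperature_effect: bool = False,
):
    """Realised per-capita growth rate, d^-1.

    ``mu_m * min(N/(N+K_N), fer/(fer+K_fer)) * (1 - exp(-alpha_c I / mu_m))``.
    Zero when light or the limiting nutrient is absent; approaches the
    maximal rate as all resources saturate.
    """
    l = np.asarray(l, dtype=float)
    mu_m = max_growth(l, p)
    if temperature_effect:
        mu_m = mu_m * eppley_factor(env.T)
    lim, _ = nutrient_limitation(l, env, p, limiter)
    light = -np.expm1(-photo_slope(l, p) * env.I / mu_m)
    return mu_m * lim * light


def quota(l, env: Environment, p: AllometricParams, limiter: str | None = None):
    """Flexible nitrogen-to-carbon quota Q_N, mol N (mol C)^-1, in [Q_min, Q_max].

    ``Q_min / (1 - (1 - Q_min/Q_max) L)`` with L the Liebig-Monod
    limitation.  Starved cells sit at Q_min; replete cells approach Q_max.
    """
    lim, _ = nutrient_limitation(np.asarray(l, dtype=float), env, p, limiter)
    return p.Q_min / (1.0 - (1.0 - p.Q_min / p.Q_max) * lim)


def carbon_growth(
    l,
    env: Environment,
    p: AllometricParams,
    limiter: str | None = None,
    temperature_effect: bool = False,
):
    """Carbon-specific growth rate mu / Q_N, d^-1 (per unit carbon biomass)."""
    return growth_rate(l, env, p, limiter, temperature_effect) / quota(l, env, p, limiter)
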
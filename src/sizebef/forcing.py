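"""Synthetic seasonal environmental forcing.

Deterministic time functions standing in for the seasonal variability an
ocean circulation model would impose on a water parcel: a sinusoidal
deep-nutrient (supply) concentration, covarying seasonal light, and a
constant or seasonal temperature.  The annual mean of the supply equals
``supply_mean`` exactly, so changing the amplitude changes variability
without changing the mean resource input — the requirement for a
diversity gradient independent of environmental effects.

By default light peaks half a period after the nutrient supply
(high-supply winter mixing, high-light summer stratification), the
seasonal structure typical of mid-latitude oceans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Forcing", "AMPLITUDE_LOW", "AMPLITUDE_HIGH"]

#: Relative seasonal amplitudes of the nutrient supply used for the
#: low- and high-variability experiment treatments.
AMPLITUDE_LOW = 0.2
AMPLITUDE_HIGH = 0.8


@dataclass(frozen=True)
class Forcing:
    """Seasonal forcing functions of time (t in days).

    supply(t) = supply_mean (1 + amplitude sin(2 pi t / period + phase));
    light and temperature follow the same form with their own amplitudes
    and phase offsets relative to the nutrient phase.
    """

    period: float = 365.0
    supply_mean: float = 10.0          # deep-N analogue, mmol N m^-3
    amplitude: float = AMPLITUDE_HIGH  # relative, in [0, 1)
    phase: float = 0.0                 # radians
    light_mean: float = 100.0          # W m^-2
    light_amplitude: float = 0.3
    light_phase: float = np.pi         # radians, relative to nutrient phase
    temperature_mean: float = 15.0     # deg C
    temperature_amplitude: float = 0.0
    fer_supply_mean: float = 1.0       # deep dissolved iron, umol Fe m^-3

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude < 1.0:
            raise ValueError(f"amplitude must satisfy 0 <= amplitude < 1, got {self.amplitude}")
        if not 0.0 <= self.light_amplitude < 1.0:
            raise ValueError(f"light_amplitude must satisfy 0 <= amplitude < 1, got {self.light_amplitude}")
        if self.period <= 0:
            raise ValueError("period must be > 0")
        if self.supply_mean < 0 or self.light_mean < 0 or self.fer_supply_mean < 0:
            raise ValueError("mean forcing levels must be >= 0")

    def _omega(self) -> float:
        return 2.0 * np.pi / self.period

    def nutrient_supply(self, t):
        """Deep/external nitrogen concentration feeding the mixing term, mmol N m^-3."""
        return self.supply_mean * (1.0 + self.amplitude * np.sin(self._omega() * t + self.phase))

    def iron_supply(self, t):
        """Deep dissolved iron concentration, umol Fe m^-3 (seasonality follows nitrogen)."""
        return self.fer_supply_mean * (1.0 + self.amplitude * np.sin(self._omega() * t + self.phase))

    def light(self, t):
        """Surface irradiance, W m^-2."""
        return self.light_mean * (
            1.0 + self.light_amplitude * np.sin(self._omega() * t + self.phase + self.light_phase)
        )

    def temperature(self, t):
        """Water temperature, deg C."""
        return self.temperature_mean + self.temperature_amplitude * np.sin(
            self._omega() * t + self.phase + self.light_phase
        )

    @classmethod
    def constant(cls, supply: float = 10.0, light: float = 100.0, fer: float = 1.0,
                 temperature: float = 15.0) -> "Forcing":
        """Time-invariant forcing (amplitudes zero), for equilibrium studies."""
        return cls(
            supply_mean=supply,
            amplitude=0.0,
            light_mean=light,
            light_amplitude=0.0,
            temperature_mean=temperature,
            fer_supply_mean=fer,
        )
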
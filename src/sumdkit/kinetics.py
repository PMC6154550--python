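"""Transition-state-theory arithmetic for unbinding-rate changes.

In Eyring/transition-state theory the unbinding rate is proportional to
exp(-dG_off / RT), so a ratio of two koff values maps directly to a
change in the unbinding activation free energy:

    ddG = R T ln(k_ref / k_mod)

The prefactor cancels in the ratio, which is why only the *change*
(not the absolute barrier) is computed.  A positive ddG means the
modulated rate is slower — e.g. a positive allosteric modulator that
slows agonist dissociation raises the unbinding barrier.  Percentwise
koff decreases of order 10-20% correspond to ddG well below 1 kcal/mol
at physiological temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constants import DEFAULT_TEMPERATURE, KB

__all__ = ["RateShift", "ddg_from_rates", "rate_ratio_from_ddg"]

#: Molar gas constant in kcal mol^-1 K^-1 (same number as kB per mole).
R = KB


def ddg_from_rates(
    k_ref: float, k_mod: float, temperature: float = DEFAULT_TEMPERATURE
) -> float:
    """Change in unbinding activation free energy, kcal/mol.

    Positive when ``k_mod < k_ref`` (the modulator slows unbinding).
    Rate units cancel; both rates must be in the same unit (min^-1 by
    convention here).
    """
    if k_ref <= 0 or k_mod <= 0:
        raise ValueError("rates must be > 0")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    return R * temperature * math.log(k_ref / k_mod)


def rate_ratio_from_ddg(ddg: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Inverse map: the rate ratio k_ref/k_mod implied by a ddG (kcal/mol)."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    return math.exp(ddg / (R * temperature))


@dataclass(frozen=True)
class RateShift:
    """A pair of unbinding rates and the implied barrier change.

    ``percent_decrease`` is the plain fractional rate drop
    ``100 (1 - k_mod/k_ref)``; note that experimental reports sometimes
    quote a percent effect computed under a different convention, so
    the raw rate pair is the authoritative input.
    """

    k_ref: float
    k_mod: float
    temperature: float = DEFAULT_TEMPERATURE
    ddg: float = field(init=False)
    percent_decrease: float = field(init=False)

    def __post_init__(self) -> None:
        ddg = ddg_from_rates(self.k_ref, self.k_mod, self.temperature)
        object.__setattr__(self, "ddg", ddg)
        object.__setattr__(
            self, "percent_decrease", 100.0 * (1.0 - self.k_mod / self.k_ref)
        )

    @classmethod
    def from_percent_decrease(
        cls, percent: float, k_ref: float = 1.0, temperature: float = DEFAULT_TEMPERATURE
    ) -> "RateShift":
        """Build a shift from a percent koff decrease (e.g. 18 -> k_mod = 0.82 k_ref)."""
        if not 0 <= percent < 100:
            raise ValueError("percent decrease must be in [0, 100)")
        return cls(k_ref=k_ref, k_mod=k_ref * (1.0 - percent / 100.0), temperature=temperature)
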
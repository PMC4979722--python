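"""Model parameters for the trait-mediated mutualistic community model.

The model couples two guilds (animal pollinators/dispersers and plants) whose
members are morphospecies identified by a single quantitative trait (e.g.
log proboscis length vs. log corolla depth).  Three Gaussian kernels govern
the ecology: trait-dependent carrying capacity (resource accessibility),
trait-similarity competition within a guild, and trait-matching mutualistic
benefit across guilds.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Any

import numpy as np

#: density below which a morphospecies is considered extinct, and
#: interaction strengths are truncated to exactly zero.
EXTINCTION_THRESHOLD = 1e-8


@dataclass
class ModelParams:
    """All rate and kernel constants of the eco-evolutionary model.

    Parameters
    ----------
    r_A, r_P
        Intrinsic per-capita growth rates of animals and plants (1/time).
    h
        Handling time of the saturating (Holling type II) mutualistic
        functional response (time).
    k_A, k_P
        Maximal carrying capacities at the guild resource optimum (density).
    x_Amax, y_Pmax
        Trait values of maximal resource access for animals and plants.
    sigma_A, sigma_P
        Widths of the Gaussian resource-accessibility (carrying capacity)
        kernels, in trait units.
    sigma_C
        Width of the Gaussian intra-guild competition kernel.
    sigma_m
        Tolerance of the mutualistic benefit to trait mismatch; small values
        make every species a specialist.
    c
        Maximal mutualistic benefit at perfect trait matching
        (1/(density * time)).
    m_A, m_P
        Mutation-rate scalings of the canonical equation of adaptive
        dynamics (dimensionless).
    extinction_threshold
        Density below which a morph is removed.
    q_threshold
        Interaction strength below which a link is stored as exactly zero.
    normalized_K
        If True, the carrying-capacity kernel uses the normalized Gaussian
        *density* (its peak scales as 1/(sigma*sqrt(2*pi))); the default is
        the unnormalized Gaussian whose maximum equals k at the optimum.
    """

    r_A: float = 1.0
    r_P: float = 1.0
    h: float = 0.1
    k_A: float = 400.0
    k_P: float = 300.0
    x_Amax: float = 3.0
    y_Pmax: float = 2.0
    sigma_A: float = 1.0
    sigma_P: float = 1.0
    sigma_C: float = 0.3
    sigma_m: float = 0.5
    c: float = 0.1
    m_A: float = 1e-3
    m_P: float = 1e-3
    extinction_threshold: float = EXTINCTION_THRESHOLD
    q_threshold: float = EXTINCTION_THRESHOLD
    normalized_K: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("sigma_A", "sigma_P", "sigma_C", "sigma_m"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"kernel width {name} must be positive")
        if self.h < 0:
            raise ValueError("handling time h must be >= 0")
        if self.c < 0:
            raise ValueError("maximal mutualistic benefit c must be >= 0")
        for name in ("k_A", "k_P"):
            if getattr(self, name) <= 0:
                raise ValueError(f"carrying-capacity scale {name} must be > 0")
        if self.extinction_threshold <= 0 or self.q_threshold <= 0:
            raise ValueError("thresholds must be positive")

    def with_kernels(self, sigma_C: float | None = None,
                     sigma_m: float | None = None,
                     sigma_A: float | None = None) -> "ModelParams":
        """Copy with the swept kernel widths replaced (sigma_P follows sigma_A)."""
        kw: dict[str, Any] = {}
        if sigma_C is not None:
            kw["sigma_C"] = sigma_C
        if sigma_m is not None:
            kw["sigma_m"] = sigma_m
        if sigma_A is not None:
            kw["sigma_A"] = sigma_A
            kw["sigma_P"] = sigma_A
        return replace(self, **kw)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParams":
        return cls(**d)


def sweep_ladder(low_exp: float = -3.0, high_exp: float = 1.0,
                 step_exp: float = 0.25) -> np.ndarray:
    """Multiplicative ladder of kernel widths e^low .. e^high, step e^step.

    The default spans e^-3 (~0.0498) to e (~2.718) in 17 values.
    """
    n = int(round((high_exp - low_exp) / step_exp)) + 1
    return np.exp(np.linspace(low_exp, high_exp, n))
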
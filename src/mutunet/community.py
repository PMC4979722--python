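"""Community containers: guild states, the bipartite community, and the
quantitative interaction matrix."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .params import ModelParams


@dataclass
class GuildState:
    """Traits and population densities of one guild (animals or plants)."""

    traits: np.ndarray
    densities: np.ndarray

    def __post_init__(self) -> None:
        self.traits = np.atleast_1d(np.asarray(self.traits, dtype=float))
        self.densities = np.atleast_1d(np.asarray(self.densities, dtype=float))
        if self.traits.shape != self.densities.shape:
            raise ValueError("traits and densities must have equal length")
        if not np.all(np.isfinite(self.traits)):
            raise ValueError("traits must be finite")
        if np.any(self.densities < 0):
            raise ValueError("densities must be non-negative")

    def __len__(self) -> int:
        return self.traits.size

    def copy(self) -> "GuildState":
        return GuildState(self.traits.copy(), self.densities.copy())


@dataclass
class Community:
    """A bipartite community of animal and plant morphospecies.

    ``alien_index`` optionally marks one animal morph as an introduced alien
    carrying its own private mutualism tolerance ``alien_sigma_m`` (its
    generalization level); all other kernels of the alien use the native
    parameters.
    """

    animals: GuildState
    plants: GuildState
    params: ModelParams
    alien_index: Optional[int] = None
    alien_sigma_m: Optional[float] = None
    #: optional stable morph identifiers (used to draw evolutionary trees
    #: across extinctions and branchings); aligned with the guild arrays
    animal_ids: Optional[np.ndarray] = None
    plant_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.animal_ids is not None:
            self.animal_ids = np.asarray(self.animal_ids, dtype=int)
        if self.plant_ids is not None:
            self.plant_ids = np.asarray(self.plant_ids, dtype=int)
        if self.alien_index is not None:
            if not (0 <= self.alien_index < len(self.animals)):
                raise ValueError("alien_index out of range")
            if self.alien_sigma_m is None:
                self.alien_sigma_m = self.params.sigma_m

    @property
    def n(self) -> int:
        return len(self.animals)

    @property
    def m(self) -> int:
        return len(self.plants)

    def animal_sigma_m(self) -> np.ndarray:
        """Per-animal mutualism tolerance (native sigma_m, alien private)."""
        s = np.full(self.n, self.params.sigma_m)
        if self.alien_index is not None:
            s[self.alien_index] = self.alien_sigma_m
        return s

    def copy(self) -> "Community":
        return Community(self.animals.copy(), self.plants.copy(), self.params,
                         self.alien_index, self.alien_sigma_m,
                         None if self.animal_ids is None else self.animal_ids.copy(),
                         None if self.plant_ids is None else self.plant_ids.copy())

    def with_densities(self, A: np.ndarray, P: np.ndarray) -> "Community":
        return Community(GuildState(self.animals.traits.copy(), np.asarray(A, float)),
                         GuildState(self.plants.traits.copy(), np.asarray(P, float)),
                         self.params, self.alien_index, self.alien_sigma_m,
                         None if self.animal_ids is None else self.animal_ids.copy(),
                         None if self.plant_ids is None else self.plant_ids.copy())

    def total_density(self, native_only: bool = False) -> float:
        tot = self.animals.densities.sum() + self.plants.densities.sum()
        if native_only and self.alien_index is not None:
            tot -= self.animals.densities[self.alien_index]
        return float(tot)


@dataclass
class InteractionMatrix:
    """Quantitative bipartite interaction-strength matrix Q (animals x plants).

    Entries below the threshold are stored as exactly zero (negligible
    interactions).
    """

    Q: np.ndarray
    animal_traits: Optional[np.ndarray] = None
    plant_traits: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        if self.Q.ndim != 2:
            raise ValueError("Q must be 2-D")
        if np.any(self.Q < 0):
            raise ValueError("interaction strengths must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.Q.shape

    def nonzero_fraction(self) -> float:
        return float(np.count_nonzero(self.Q) / self.Q.size)
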
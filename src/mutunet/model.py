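"""Model primitives: Gaussian kernels, adaptive interaction preferences,
per-capita growth rates and the quantitative interaction-strength matrix.

Population dynamics follow a bipartite Lotka-Volterra system with
trait-similarity competition within guilds and a saturating (Holling
type II) mutualistic benefit across guilds,

    dA_i/dt = A_i f_A(x_i),
    f_A(x_i) = r_A - r_A * sum_k gamma(x_i, x_k) A_k / K_A(x_i)
               + sum_j b_ij w_ij P_j / (1 + h sum_j w_ij P_j),

mirrored for plants.  The interaction preference w implements adaptive
foraging: the pairwise benefit divided by the density-weighted mean benefit
offered to the partner by the focal guild.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import Community, InteractionMatrix
from .params import ModelParams

#: mutualistic benefits below this are treated as exactly zero; far below
#: the interaction-strength threshold, this only protects the adaptive
#: preference ratios from floating-point under/overflow
B_FLOOR = 1e-30

__all__ = [
    "competition_kernel",
    "carrying_capacity",
    "mutualistic_benefit",
    "build_kernels",
    "interaction_preference",
    "percapita_growth",
    "growth_rates",
    "interaction_strength_matrix",
]


def competition_kernel(delta, sigma_C: float):
    """Gaussian competition weight exp(-delta^2 / (2 sigma_C^2)).

    Morphs with more similar traits compete more strongly; the weight is 1
    at identical traits and symmetric in the sign of the difference.
    """
    if sigma_C <= 0:
        raise ValueError("sigma_C must be positive")
    delta = np.asarray(delta, dtype=float)
    return np.exp(-delta ** 2 / (2.0 * sigma_C ** 2))


def carrying_capacity(x, guild: str, params: ModelParams):
    """Trait-dependent carrying capacity K(x) = k * G(x - x_max; sigma).

    By default the Gaussian is unnormalized so the maximum equals the scale
    constant k at the resource optimum; with ``params.normalized_K`` the
    Gaussian probability density is used instead.
    """
    params.validate()
    x = np.asarray(x, dtype=float)
    if guild == "animal":
        k, xmax, sigma = params.k_A, params.x_Amax, params.sigma_A
    elif guild == "plant":
        k, xmax, sigma = params.k_P, params.y_Pmax, params.sigma_P
    else:
        raise ValueError("guild must be 'animal' or 'plant'")
    g = np.exp(-(x - xmax) ** 2 / (2.0 * sigma ** 2))
    if params.normalized_K:
        g = g / (sigma * np.sqrt(2.0 * np.pi))
    return k * g


def mutualistic_benefit(x, y, params: ModelParams, sigma_m: float | None = None):
    """Assortative mutualistic benefit b = c * exp(-(x-y)^2 / (2 sigma_m^2))."""
    s = params.sigma_m if sigma_m is None else sigma_m
    if np.any(np.asarray(s) <= 0):
        raise ValueError("sigma_m must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return params.c * np.exp(-(x - y) ** 2 / (2.0 * np.asarray(s) ** 2))


@dataclass
class Kernels:
    """Trait-dependent quantities cached for a fixed trait configuration."""

    gamma_A: np.ndarray  # (n, n) competition weights among animals
    gamma_P: np.ndarray  # (m, m) competition weights among plants
    K_A: np.ndarray      # (n,) animal carrying capacities
    K_P: np.ndarray      # (m,) plant carrying capacities
    b: np.ndarray        # (n, m) pairwise mutualistic benefits


def build_kernels(community: Community) -> Kernels:
    p = community.params
    x = community.animals.traits
    y = community.plants.traits
    gamma_A = competition_kernel(x[:, None] - x[None, :], p.sigma_C)
    gamma_P = competition_kernel(y[:, None] - y[None, :], p.sigma_C)
    K_A = carrying_capacity(x, "animal", p)
    K_P = carrying_capacity(y, "plant", p)
    # pairwise benefit; an alien animal row uses its private tolerance
    sm = community.animal_sigma_m()
    b = p.c * np.exp(-(x[:, None] - y[None, :]) ** 2 / (2.0 * sm[:, None] ** 2))
    b[b < B_FLOOR] = 0.0  # avoid overflow in preference ratios of dead pairs
    return Kernels(gamma_A, gamma_P, K_A, K_P, b)


def _preferences(b: np.ndarray, A: np.ndarray, P: np.ndarray):
    """Adaptive preference matrices for batched density vectors.

    ``A`` has shape (..., n), ``P`` shape (..., m); returns ``w_AP`` of
    shape (..., n, m) and ``w_PA`` of shape (..., m, n).  Columns whose
    density-weighted benefit sum vanishes get preference zero (no feasible
    interaction, e.g. transiently after extinctions).
    """
    sumA = A.sum(axis=-1)
    sumP = P.sum(axis=-1)
    denomA = A @ b            # (..., m): sum_k A_k b_kj
    denomP = P @ b.T          # (..., n): sum_k P_k b_ik
    with np.errstate(divide="ignore", invalid="ignore"):
        w_AP = b * (sumA[..., None, None] / denomA[..., None, :])
        w_PA = b.T * (sumP[..., None, None] / denomP[..., None, :])
    w_AP = np.where(denomA[..., None, :] > 0, w_AP, 0.0)
    w_PA = np.where(denomP[..., None, :] > 0, w_PA, 0.0)
    return w_AP, w_PA


def interaction_preference(community: Community):
    """Adaptive interaction preference matrices (w_AP: n x m, w_PA: m x n).

    w_AiPj = b_ij * (sum_k A_k) / (sum_k A_k b_kj): an animal prefers
    plants that are common and trait-matched, normalized by the mean
    benefit plant j receives over all animal suitors.
    """
    kern = build_kernels(community)
    return _preferences(kern.b, community.animals.densities,
                        community.plants.densities)


def growth_rates(kern: Kernels, params: ModelParams,
                 A: np.ndarray, P: np.ndarray):
    """Per-capita growth rates (f_A, f_P) for batched density vectors.

    Accepts ``A`` of shape (..., n) and ``P`` of shape (..., m); vectorized
    over leading axes so finite-difference Jacobians need one call.
    Zero-density morphs obtain well-defined rates (rare-invader fitness).
    """
    n = kern.K_A.size
    m = kern.K_P.size
    A = np.asarray(A, dtype=float)
    P = np.asarray(P, dtype=float)
    w_AP, w_PA = _preferences(kern.b, A, P)

    if n:
        comp_A = (A @ kern.gamma_A.T) / kern.K_A
        if m:
            sat = (w_AP * P[..., None, :]).sum(axis=-1)
            num = (kern.b * w_AP * P[..., None, :]).sum(axis=-1)
            mut_A = num / (1.0 + params.h * sat)
        else:
            mut_A = np.zeros(A.shape)
        f_A = params.r_A - params.r_A * comp_A + mut_A
    else:
        f_A = np.zeros(A.shape)

    if m:
        comp_P = (P @ kern.gamma_P.T) / kern.K_P
        if n:
            sat = (w_PA * A[..., None, :]).sum(axis=-1)
            num = (kern.b.T * w_PA * A[..., None, :]).sum(axis=-1)
            mut_P = num / (1.0 + params.h * sat)
        else:
            mut_P = np.zeros(P.shape)
        f_P = params.r_P - params.r_P * comp_P + mut_P
    else:
        f_P = np.zeros(P.shape)
    return f_A, f_P


def percapita_jacobian(kern: Kernels, params: ModelParams,
                       A: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the per-capita rates, d(f_A, f_P)/d(A, P).

    The adaptive preferences depend on densities, so the mutualism block
    carries both the direct functional-response terms and the indirect
    renormalization terms of w.  Returns an (n+m) x (n+m) matrix.
    """
    n, m = kern.K_A.size, kern.K_P.size
    h = params.h
    b = kern.b
    J = np.zeros((n + m, n + m))
    if n:
        J[:n, :n] = -params.r_A * kern.gamma_A / kern.K_A[:, None]
    if m:
        J[n:, n:] = -params.r_P * kern.gamma_P / kern.K_P[:, None]
    if n and m:
        sumA, sumP = A.sum(), P.sum()
        DA = A @ b            # (m,) per plant
        DP = b @ P            # (n,) per animal
        with np.errstate(divide="ignore", invalid="ignore"):
            E = np.where(DA[None, :] > 0, b / DA[None, :], 0.0)     # (n, m)
            EP = np.where(DP[:, None] > 0, b / DP[:, None], 0.0)    # (n, m): EP[i, j] = b_ij / DP_i
        wA = E * sumA                                               # (n, m)
        wP = EP.T * sumP                                            # (m, n)
        # animal rows
        S = wA @ P
        U = (b * wA) @ P
        V = 1.0 + h * S
        alpha = (b * E) @ P
        beta = E @ P
        G = b * wA * P[None, :]
        H = wA * P[None, :]
        dU = alpha[:, None] - G @ E.T      # (n, n): dU_i/dA_l
        dS = beta[:, None] - H @ E.T
        J[:n, :n] += (dU * V[:, None] - U[:, None] * h * dS) / V[:, None] ** 2
        J[:n, n:] = wA * (b * V[:, None] - h * U[:, None]) / V[:, None] ** 2
        # plant rows
        SP = wP @ A
        UP = (b.T * wP) @ A
        VP = 1.0 + h * SP
        alphaP = (b.T * EP.T) @ A
        betaP = EP.T @ A
        GP = b.T * wP * A[None, :]
        HP = wP * A[None, :]
        dUP = alphaP[:, None] - GP @ EP
        dSP = betaP[:, None] - HP @ EP
        J[n:, n:] += (dUP * VP[:, None] - UP[:, None] * h * dSP) / VP[:, None] ** 2
        J[n:, :n] = wP * (b.T * VP[:, None] - h * UP[:, None]) / VP[:, None] ** 2
    return J


def percapita_growth(community: Community):
    """Per-capita growth-rate vectors (f_A of length n, f_P of length m)."""
    kern = build_kernels(community)
    return growth_rates(kern, community.params,
                        community.animals.densities,
                        community.plants.densities)


def interaction_strength_matrix(community: Community) -> InteractionMatrix:
    """Quantitative interaction strengths q_ij (recruits per unit time).

    q_ij averages the per-pair saturating recruitment of animal i from
    plant j and of plant j from animal i; entries below the threshold are
    stored as exactly zero.
    """
    p = community.params
    kern = build_kernels(community)
    A = community.animals.densities
    P = community.plants.densities
    w_AP, w_PA = _preferences(kern.b, A, P)
    qA = A[:, None] * kern.b * w_AP * P[None, :] / (1.0 + p.h * w_AP * P[None, :])
    qP = P[:, None] * kern.b.T * w_PA * A[None, :] / (1.0 + p.h * w_PA * A[None, :])
    Q = 0.5 * (qA + qP.T)
    Q[Q < p.q_threshold] = 0.0
    return InteractionMatrix(Q, community.animals.traits.copy(),
                             community.plants.traits.copy())
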
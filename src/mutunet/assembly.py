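"""Trait evolution by adaptive dynamics: invasion fitness, selection
gradients, the canonical equation, evolutionary branching and the
parameter-sweep ensemble generator.

Community assembly follows the classical adaptive-dynamics loop: residents
sit at their stable ecological equilibrium, rare mutants are scored by
their per-capita growth rate in the resident environment, traits flow
along the canonical equation dx_i/dt = m * N_i * g_i until directional
selection ceases, and morphs that sit at a convergence-stable fitness
minimum permitting mutual invasion split into two daughter lineages.
Repeating the branching E times yields bipartite networks with at most
2^E morphs per guild (small E=4, medium E=5, large E=6).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .community import Community, GuildState
from .dynamics import _newton_equilibrium, find_equilibrium
from .model import B_FLOOR, build_kernels, carrying_capacity
from .params import ModelParams, sweep_ladder

__all__ = [
    "SingularityState",
    "AssemblyLog",
    "invasion_fitness",
    "selection_gradient",
    "evolve_to_singularity",
    "branching_conditions",
    "apply_branching",
    "assemble_network",
    "generate_ensemble",
]

#: strict-positivity tolerance for curvature-based branching tests; at
#: degenerate parameter points the fitness landscape is exactly flat and
#: finite differences return pure rounding noise.
CURVATURE_TOL = 1e-6

#: singularity criterion: max canonical-equation speed |m * N * g|
GRAD_TOL = 1e-7


class NotAtEquilibriumError(RuntimeError):
    pass


def _check_equilibrium(community: Community, tol: float = 1e-6) -> None:
    from .model import percapita_growth
    fA, fP = percapita_growth(community)
    N = np.concatenate([community.animals.densities,
                        community.plants.densities])
    f = np.concatenate([fA, fP])
    if N.size and np.max(np.abs(N * f) / np.maximum(N, 1.0)) > tol:
        raise NotAtEquilibriumError(
            "community is not at ecological equilibrium")


def invasion_fitness(community: Community, guild: str, mutant_traits,
                     check_equilibrium: bool = False):
    """Per-capita growth rate of rare mutants in the resident environment.

    Mutants enter at negligible density, so resident densities and the
    adaptive-preference normalizations are unchanged; the fitness of a
    whole batch of candidate traits is therefore a closed-form expression
    in the resident equilibrium and evaluates vectorized.
    """
    if check_equilibrium:
        _check_equilibrium(community)
    p = community.params
    xs = np.atleast_1d(np.asarray(mutant_traits, dtype=float))
    A = community.animals.densities
    P = community.plants.densities
    x = community.animals.traits
    y = community.plants.traits
    sm = community.animal_sigma_m()

    if guild == "animal":
        # competition-to-capacity ratio computed in log space: far outside
        # the viable range both gamma and K underflow and their quotient
        # would otherwise be 0/0
        expo = (-(xs[:, None] - x[None, :]) ** 2 / (2.0 * p.sigma_C ** 2)
                + (xs[:, None] - p.x_Amax) ** 2 / (2.0 * p.sigma_A ** 2))
        comp_over_K = (np.exp(np.minimum(expo, 700.0)) @ A) / p.k_A
        if p.normalized_K:
            comp_over_K *= p.sigma_A * np.sqrt(2.0 * np.pi)
        # mutant carries the native tolerance
        b_mut = p.c * np.exp(-(xs[:, None] - y[None, :]) ** 2
                             / (2.0 * p.sigma_m ** 2))
        b_mut[b_mut < B_FLOOR] = 0.0
        if community.m and A.sum() > 0:
            b_res = p.c * np.exp(-(x[:, None] - y[None, :]) ** 2
                                 / (2.0 * sm[:, None] ** 2))
            b_res[b_res < B_FLOOR] = 0.0
            denom = A @ b_res  # per plant j
            with np.errstate(divide="ignore", invalid="ignore"):
                w = b_mut * (A.sum() / denom[None, :])
            w = np.where(denom[None, :] > 0, w, 0.0)
            sat = w @ P
            mut = ((b_mut * w) @ P) / (1.0 + p.h * sat)
        else:
            mut = np.zeros(xs.shape)
        f = p.r_A - p.r_A * comp_over_K + mut
    elif guild == "plant":
        expo = (-(xs[:, None] - y[None, :]) ** 2 / (2.0 * p.sigma_C ** 2)
                + (xs[:, None] - p.y_Pmax) ** 2 / (2.0 * p.sigma_P ** 2))
        comp_over_K = (np.exp(np.minimum(expo, 700.0)) @ P) / p.k_P
        if p.normalized_K:
            comp_over_K *= p.sigma_P * np.sqrt(2.0 * np.pi)
        b_mut = p.c * np.exp(-(x[None, :] - xs[:, None]) ** 2
                             / (2.0 * sm[None, :] ** 2))  # (B, n)
        b_mut[b_mut < B_FLOOR] = 0.0
        if community.n and P.sum() > 0:
            b_res = p.c * np.exp(-(x[:, None] - y[None, :]) ** 2
                                 / (2.0 * sm[:, None] ** 2))
            b_res[b_res < B_FLOOR] = 0.0
            denom = P @ b_res.T  # per animal i
            with np.errstate(divide="ignore", invalid="ignore"):
                w = b_mut * (P.sum() / denom[None, :])
            w = np.where(denom[None, :] > 0, w, 0.0)
            sat = w @ A
            mut = ((b_mut * w) @ A) / (1.0 + p.h * sat)
        else:
            mut = np.zeros(xs.shape)
        f = p.r_P - p.r_P * comp_over_K + mut
    else:
        raise ValueError("guild must be 'animal' or 'plant'")
    return f if np.ndim(mutant_traits) else float(f[0])


def selection_gradient(community: Community, step: float = 1e-6):
    """Selection gradients g_A, g_P: d(invasion fitness)/d(mutant trait)
    evaluated at each resident trait, by central differences."""
    g_A = np.zeros(community.n)
    g_P = np.zeros(community.m)
    if community.n:
        x = community.animals.traits
        f = invasion_fitness(community, "animal",
                             np.concatenate([x + step, x - step]))
        g_A = (f[:community.n] - f[community.n:]) / (2.0 * step)
    if community.m:
        y = community.plants.traits
        f = invasion_fitness(community, "plant",
                             np.concatenate([y + step, y - step]))
        g_P = (f[:community.m] - f[community.m:]) / (2.0 * step)
    return g_A, g_P


def _canonical_speeds(comm: Community, g_A: np.ndarray, g_P: np.ndarray):
    p = comm.params
    v_A = p.m_A * comm.animals.densities * g_A
    v_P = p.m_P * comm.plants.densities * g_P
    return v_A, v_P


def _flow_state(comm: Community, eq_tol: float, d: int):
    """Equilibrate and return (community, canonical velocity, speed) or
    None if the equilibrium fails or a morph went extinct."""
    eq = find_equilibrium(comm, tol=eq_tol, require_stable=False)
    if not eq.converged or eq.community.n + eq.community.m != d:
        return None
    comm = eq.community
    g_A, g_P = selection_gradient(comm)
    v_A, v_P = _canonical_speeds(comm, g_A, g_P)
    v = np.concatenate([v_A, v_P])
    return comm, v, float(np.max(np.abs(v), initial=0.0))


def _with_traits(comm: Community, traits: np.ndarray) -> Community:
    out = comm.copy()
    out.animals.traits = traits[:comm.n].copy()
    out.plants.traits = traits[comm.n:].copy()
    return out


def _newton_polish(community: Community, grad_tol: float, eq_tol: float,
                   fd_step: float = 1e-5, max_iter: int = 8,
                   max_move: float = 0.02):
    """Capped Newton solve of the selection-gradient root g(x, y) = 0.

    Re-equilibrates inside every trait perturbation.  Converged roots are
    accepted only if they are attractors of the canonical flow (all
    eigenvalues of d(m N g)/d(trait) with negative real part), which
    rejects the collapsed parent/daughter saddle right after a branching;
    a collapsed same-guild trait pair is rejected outright.  Returns the
    converged community or None.
    """
    comm = community.copy()
    d = comm.n + comm.m
    for _ in range(max_iter):
        eq = find_equilibrium(comm, tol=eq_tol, require_stable=False)
        if not eq.converged or eq.community.n + eq.community.m != d:
            return None
        comm = eq.community
        for tr in (comm.animals.traits, comm.plants.traits):
            if tr.size > 1 and np.min(np.diff(np.sort(tr))) < 3e-3:
                return None
        g_A, g_P = selection_gradient(comm)
        g = np.concatenate([g_A, g_P])
        mN = np.concatenate([comm.params.m_A * comm.animals.densities,
                             comm.params.m_P * comm.plants.densities])
        speed = float(np.max(np.abs(mN * g), initial=0.0))
        J = np.empty((d, d))
        for k in range(d):
            pert = comm.copy()
            if k < comm.n:
                pert.animals.traits[k] += fd_step
            else:
                pert.plants.traits[k - comm.n] += fd_step
            eq_k = find_equilibrium(pert, tol=eq_tol, require_stable=False)
            if not eq_k.converged or eq_k.community.n + eq_k.community.m != d:
                return None
            gA_k, gP_k = selection_gradient(eq_k.community)
            J[:, k] = (np.concatenate([gA_k, gP_k]) - g) / fd_step
        if speed < grad_tol:
            if np.max(np.linalg.eigvals(mN[:, None] * J).real) > 1e-8:
                return None
            final = find_equilibrium(comm, tol=eq_tol, require_stable=True)
            return final.community if final.converged else None
        try:
            dx = np.linalg.solve(J, -g)
        except np.linalg.LinAlgError:
            return None
        scale = np.max(np.abs(dx))
        if scale > max_move:
            dx *= max_move / scale
        comm = _with_traits(comm, np.concatenate(
            [comm.animals.traits, comm.plants.traits]) + dx)
    return None


def _implicit_flow_polish(community: Community, grad_tol: float,
                          eq_tol: float, fd_step: float = 1e-5,
                          max_iter: int = 16, dt0: float = 10.0,
                          max_move: float = 0.05):
    """Stiff-flow accelerator: implicit (backward-Euler) integration of the
    canonical trait flow dx/dt = m N g.

    The flow near a singularity is stiff (fast relaxation transverse to a
    slowly contracting collective mode), so explicit stepping is limited to
    tiny steps; the linearly implicit step (I - dt J)^-1 dt v with the
    finite-difference flow Jacobian J (equilibria re-solved inside every
    perturbation) is unconditionally stable and follows the slow manifold
    with dt growing geometrically.  Because it tracks the true flow it
    cannot converge to repelling roots such as the collapsed
    parent/daughter saddle right after a branching.  Steps are accepted
    only if the flow speed decreases; dt shrinks otherwise.  Returns the
    converged community at the singularity, or None (caller falls back to
    explicit stepping).
    """
    d = community.n + community.m
    state = _flow_state(community.copy(), eq_tol, d)
    if state is None:
        return None
    comm, v, speed = state
    dt = dt0
    recent: list[float] = []
    for _ in range(max_iter):
        recent.append(speed)
        if len(recent) > 8 and speed > 0.7 * recent[-8]:
            return None  # no meaningful contraction: give up cheaply
        if speed < grad_tol:
            final = find_equilibrium(comm, tol=eq_tol, require_stable=True)
            return final.community if final.converged else None
        J = np.empty((d, d))
        for k in range(d):
            pert = comm.copy()
            if k < comm.n:
                pert.animals.traits[k] += fd_step
            else:
                pert.plants.traits[k - comm.n] += fd_step
            pst = _flow_state(pert, eq_tol, d)
            if pst is None:
                return None
            J[:, k] = (pst[1] - v) / fd_step
        x0 = np.concatenate([comm.animals.traits, comm.plants.traits])
        accepted = False
        for _retry in range(16):
            try:
                dx = np.linalg.solve(np.eye(d) - dt * J, dt * v)
            except np.linalg.LinAlgError:
                dt *= 0.25
                continue
            if not np.all(np.isfinite(dx)) or np.max(np.abs(dx)) > max_move:
                dt *= 0.25
                continue
            trial = _flow_state(_with_traits(comm, x0 + dx), eq_tol, d)
            if trial is not None and trial[2] < speed:
                comm, v, speed = trial
                dt *= 3.0
                accepted = True
                break
            dt *= 0.25
            if dt < 1e-3:
                return None
        if not accepted:
            return None
    return None


def _polish_singularity(community: Community, grad_tol: float,
                        eq_tol: float, **kw):
    """Locate the singularity from inside its basin: a capped Newton jump
    first (fast, crosses narrow nonlinear valleys), the implicit-flow
    accelerator as fallback."""
    out = _newton_polish(community, grad_tol, eq_tol)
    if out is not None:
        return out
    return _implicit_flow_polish(community, grad_tol, eq_tol)


@dataclass
class SingularityState:
    """Community at an evolutionary singularity (gradients vanished)."""

    community: Community
    gradients: tuple[np.ndarray, np.ndarray]
    converged: bool
    steps: int
    time_evolved: float
    trajectory: list = field(default_factory=list)  # (t, ids_A, x, ids_P, y)


def evolve_to_singularity(community: Community, grad_tol: float = GRAD_TOL,
                          max_steps: int = 4000, max_dx: float = 0.005,
                          eq_tol: float = 1e-9, record: bool = False,
                          stability_every: int = 100,
                          polish_threshold: float = 5e-3,
                          stall_window: int = 300,
                          max_polish_failures: int = 3) -> SingularityState:
    """Follow the canonical equation until directional selection ceases.

    Alternates ecological equilibration with an adaptive Euler step on the
    trait flow dx_i = m * N_i * g_i * dt.  The step is chosen so no trait
    moves more than ``max_dx`` per step and so that dt stays below the
    stability limit of the locally stiffest mode, estimated per morph from
    the velocity change of the previous step (a secant estimate of the
    flow's local contraction rate); this gives geometric convergence into
    the singularity without overshoot oscillation.
    """
    comm = community.copy()
    if comm.animal_ids is None:
        comm.animal_ids = np.arange(comm.n)
    if comm.plant_ids is None:
        comm.plant_ids = np.arange(comm.m)
    t = 0.0
    prev_v: dict[int, float] = {}
    prev_x: dict[int, float] = {}
    next_polish = 30  # let freshly branched daughters separate first
    polish_failures = 0
    speed_hist: list[float] = []
    traj: list = []
    for step_i in range(max_steps):
        check = (step_i % stability_every == 0)
        # fast path: direct warm-started Newton on the previous equilibrium
        # (trait steps are tiny); the full solver handles extinctions,
        # integration fallback and periodic stability verification
        cand = None
        if not check and np.all(comm.animals.densities > 0) \
                and np.all(comm.plants.densities > 0):
            kern = build_kernels(comm)
            cand = _newton_equilibrium(comm, kern, eq_tol)
            if cand is not None and (
                    np.any(cand.animals.densities
                           < comm.params.extinction_threshold)
                    or np.any(cand.plants.densities
                              < comm.params.extinction_threshold)):
                cand = None
        if cand is not None:
            comm = cand
        else:
            eq = find_equilibrium(comm, tol=eq_tol, require_stable=check)
            if not eq.converged:
                return SingularityState(eq.community,
                                        (np.array([]), np.array([])),
                                        False, step_i, t, traj)
            comm = eq.community
        if comm.n == 0 and comm.m == 0:
            return SingularityState(comm, (np.array([]), np.array([])),
                                    False, step_i, t, traj)
        g_A, g_P = selection_gradient(comm)
        p = comm.params
        v_A = p.m_A * comm.animals.densities * g_A
        v_P = p.m_P * comm.plants.densities * g_P
        speed = max(np.max(np.abs(v_A), initial=0.0),
                    np.max(np.abs(v_P), initial=0.0))
        if record:
            traj.append((t, comm.animal_ids.copy(),
                         comm.animals.traits.copy(),
                         comm.plant_ids.copy(), comm.plants.traits.copy()))
        if speed < grad_tol:
            eq = find_equilibrium(comm, tol=eq_tol, require_stable=True)
            if not eq.converged:
                return SingularityState(eq.community, (g_A, g_P), False,
                                        step_i, t, traj)
            return SingularityState(eq.community, (g_A, g_P), True,
                                    step_i, t, traj)
        speed_hist.append(speed)
        # stall detector: a slow, barely-decaying flow in the soft-mode
        # regime will not reach the singularity in any reasonable effort;
        # such parameter sets are discarded upstream
        if (speed < polish_threshold and polish_failures >= 2
                and len(speed_hist) > stall_window
                and speed > 0.5 * speed_hist[-stall_window]):
            return SingularityState(comm, (g_A, g_P), False, step_i, t, traj)
        if polish_failures > max_polish_failures:
            return SingularityState(comm, (g_A, g_P), False, step_i, t, traj)
        if speed < polish_threshold and step_i >= next_polish:
            cand = _polish_singularity(comm, grad_tol, eq_tol)
            if cand is not None:
                g_A, g_P = selection_gradient(cand)
                if record:
                    traj.append((t, cand.animal_ids.copy(),
                                 cand.animals.traits.copy(),
                                 cand.plant_ids.copy(),
                                 cand.plants.traits.copy()))
                return SingularityState(cand, (g_A, g_P), True,
                                        step_i, t, traj)
            next_polish = step_i + 40  # saddle or failed solve: keep flowing
            polish_failures += 1
        cur_v = {int(i): float(v) for i, v in zip(comm.animal_ids, v_A)}
        cur_v.update({int(i): float(v) for i, v in zip(comm.plant_ids, v_P)})
        cur_x = {int(i): float(x) for i, x in
                 zip(comm.animal_ids, comm.animals.traits)}
        cur_x.update({int(i): float(x) for i, x in
                      zip(comm.plant_ids, comm.plants.traits)})
        lam = 0.0
        for mid, v in cur_v.items():
            if mid in prev_v:
                dx = cur_x[mid] - prev_x[mid]
                if abs(dx) > 1e-13:
                    lam = max(lam, abs(v - prev_v[mid]) / abs(dx))
        prev_v, prev_x = cur_v, cur_x
        # coarser displacement cap during directional transport, fine cap
        # near the singularity (path accuracy matters most there)
        cap = max_dx if speed < 4 * polish_threshold else 4 * max_dx
        dt = cap / speed
        if lam > 0:
            dt = min(dt, 1.5 / lam)
        comm = Community(
            GuildState(comm.animals.traits + dt * v_A,
                       comm.animals.densities.copy()),
            GuildState(comm.plants.traits + dt * v_P,
                       comm.plants.densities.copy()),
            p, comm.alien_index, comm.alien_sigma_m,
            comm.animal_ids, comm.plant_ids)
        t += dt
    return SingularityState(comm, (g_A, g_P), False, max_steps, t, traj)


def _gradient_of_morph(community: Community, guild: str, index: int,
                       step: float = 1e-6) -> float:
    traits = (community.animals.traits if guild == "animal"
              else community.plants.traits)
    x0 = traits[index]
    up = invasion_fitness(community, guild, np.array([x0 + step]))[0]
    dn = invasion_fitness(community, guild, np.array([x0 - step]))[0]
    return float((up - dn) / (2.0 * step))


def _perturbed_equilibrium(community: Community, guild: str, index: int,
                           new_trait: float, eq_tol: float = 1e-9):
    comm = community.copy()
    if guild == "animal":
        comm.animals.traits[index] = new_trait
    else:
        comm.plants.traits[index] = new_trait
    eq = find_equilibrium(comm, tol=eq_tol, require_stable=False)
    return eq


def branching_conditions(singularity: SingularityState, guild: str,
                         index: int, step: float = 1e-4,
                         curv_tol: float = CURVATURE_TOL):
    """The three evolutionary-branching tests for one morph.

    Returns (convergence_stable, disruptive, mutually_invasible):
    the singularity attracts directional selection (dg/dx < 0), sits at a
    fitness minimum (d2f/dx'2 > 0), and resident and mutant can invade one
    another (resident + mutant curvature > 0).  All derivatives by central
    differences; resident-trait derivatives re-equilibrate the community.
    """
    comm = singularity.community
    traits = (comm.animals.traits if guild == "animal" else comm.plants.traits)
    x0 = float(traits[index])

    # mutant curvature at fixed resident environment
    f0 = invasion_fitness(comm, guild, np.array([x0]))[0]
    fp = invasion_fitness(comm, guild, np.array([x0 + step]))[0]
    fm = invasion_fitness(comm, guild, np.array([x0 - step]))[0]
    mutant_curv = (fp - 2.0 * f0 + fm) / step ** 2
    disruptive = mutant_curv > curv_tol

    # resident-trait perturbations (with re-equilibration) give both the
    # convergence test dg/dx and the resident curvature of Eq-style
    # mutual-invasibility
    eq_p = _perturbed_equilibrium(comm, guild, index, x0 + step)
    eq_m = _perturbed_equilibrium(comm, guild, index, x0 - step)
    if not (eq_p.converged and eq_m.converged):
        return False, bool(disruptive), False
    # the focal morph must have survived the perturbation
    size = (eq_p.community.n, eq_m.community.n) if guild == "animal" \
        else (eq_p.community.m, eq_m.community.m)
    orig = comm.n if guild == "animal" else comm.m
    if size[0] != orig or size[1] != orig:
        return False, bool(disruptive), False

    g_p = _gradient_of_morph(eq_p.community, guild, index)
    g_m = _gradient_of_morph(eq_m.community, guild, index)
    convergent = (g_p - g_m) / (2.0 * step) < -curv_tol

    f_res_p = invasion_fitness(eq_p.community, guild, np.array([x0]))[0]
    f_res_m = invasion_fitness(eq_m.community, guild, np.array([x0]))[0]
    resident_curv = (f_res_p + f_res_m) / step ** 2  # f(x0; x0) = 0
    coexisting = (resident_curv + mutant_curv) > curv_tol

    return bool(convergent), bool(disruptive), bool(coexisting)


def apply_branching(community: Community,
                    morphs_to_split: dict[str, Sequence[int]],
                    trait_offset: float = 0.01,
                    daughter_fraction: float = 0.1,
                    next_id: Optional[int] = None):
    """Split the listed morphs: daughter at trait + 0.01 carrying 10% of the
    parent density, parent reduced to 90%; total density is conserved.

    Returns (community, next_id); fresh ids are assigned to daughters when
    the community tracks morph identities.
    """
    comm = community.copy()
    ids_known = comm.animal_ids is not None and comm.plant_ids is not None
    if next_id is None and ids_known:
        next_id = int(max(comm.animal_ids.max(initial=-1),
                          comm.plant_ids.max(initial=-1))) + 1
    for guild in ("animal", "plant"):
        idxs = list(morphs_to_split.get(guild, ()))
        if not idxs:
            continue
        gs = comm.animals if guild == "animal" else comm.plants
        new_traits = []
        new_dens = []
        new_ids = []
        for i in idxs:
            new_traits.append(gs.traits[i] + trait_offset)
            new_dens.append(daughter_fraction * gs.densities[i])
            gs.densities[i] *= (1.0 - daughter_fraction)
            if ids_known:
                new_ids.append(next_id)
                next_id += 1
        traits = np.concatenate([gs.traits, new_traits])
        dens = np.concatenate([gs.densities, new_dens])
        if guild == "animal":
            comm.animals = GuildState(traits, dens)
            if ids_known:
                comm.animal_ids = np.concatenate([comm.animal_ids, new_ids])
        else:
            comm.plants = GuildState(traits, dens)
            if ids_known:
                comm.plant_ids = np.concatenate([comm.plant_ids, new_ids])
    return comm, next_id


@dataclass
class BranchingEvent:
    time: float
    guild: str
    parent_id: int
    parent_trait: float
    daughter_id: int
    daughter_trait: float


@dataclass
class AssemblyLog:
    """Complete record of one community assembly (one network)."""

    final_community: Community
    singularity: Optional[SingularityState]
    events: list[BranchingEvent]
    n_events: int
    converged: bool
    params: ModelParams
    seed: Optional[int] = None
    trajectory: list = field(default_factory=list)

    @property
    def monomorphic(self) -> bool:
        return self.n_events == 0

    def guild_sizes(self) -> tuple[int, int]:
        return self.final_community.n, self.final_community.m


def initial_community(params: ModelParams, offset: float = 0.5) -> Community:
    """Monomorphic starting point: one animal and one plant, each a bit
    below its resource optimum at half carrying capacity."""
    x0 = params.x_Amax - offset
    y0 = params.y_Pmax - offset
    A0 = 0.5 * float(carrying_capacity(x0, "animal", params))
    P0 = 0.5 * float(carrying_capacity(y0, "plant", params))
    return Community(GuildState([x0], [A0]), GuildState([y0], [P0]), params,
                     animal_ids=np.array([0]), plant_ids=np.array([1]))


def assemble_network(params: ModelParams, target_events: int = 4,
                     seed: Optional[int] = None, record: bool = False,
                     max_steps: int = 4000) -> AssemblyLog:
    """Assemble a native network by repeated evolutionary branching.

    Starting monomorphic, the community evolves to its singularity; every
    morph passing the three branching conditions splits (one event per
    round in which at least one morph split), until ``target_events``
    events occurred or no morph qualifies.  The returned final state is at
    the singularity and ecological equilibrium.  Deterministic: the seed is
    only recorded for provenance.
    """
    if target_events < 1:
        raise ValueError("target_events must be >= 1")
    comm = initial_community(params)
    events: list[BranchingEvent] = []
    trajectory: list = []
    n_events = 0
    next_id = 2
    sing = None
    t_accum = 0.0
    while True:
        sing = evolve_to_singularity(comm, record=record, max_steps=max_steps)
        if record:
            trajectory.extend([(t_accum + t, ia, x, ip, y)
                               for (t, ia, x, ip, y) in sing.trajectory])
        t_accum += sing.time_evolved
        if not sing.converged:
            return AssemblyLog(sing.community, sing, events, n_events, False,
                               params, seed, trajectory)
        if n_events >= target_events:
            break
        comm_s = sing.community
        to_split: dict[str, list[int]] = {"animal": [], "plant": []}
        for guild, size in (("animal", comm_s.n), ("plant", comm_s.m)):
            for i in range(size):
                conv, disr, coex = branching_conditions(sing, guild, i)
                if conv and disr and coex:
                    to_split[guild].append(i)
        if not (to_split["animal"] or to_split["plant"]):
            break
        for guild in ("animal", "plant"):
            gs = comm_s.animals if guild == "animal" else comm_s.plants
            ids = (comm_s.animal_ids if guild == "animal"
                   else comm_s.plant_ids)
            for k, i in enumerate(to_split[guild]):
                events.append(BranchingEvent(
                    t_accum, guild, int(ids[i]), float(gs.traits[i]),
                    next_id + k if guild == "animal"
                    else next_id + len(to_split["animal"]) + k,
                    float(gs.traits[i]) + 0.01))
        comm, next_id = apply_branching(comm_s, to_split, next_id=next_id)
        n_events += 1
    return AssemblyLog(sing.community, sing, events, n_events, True, params,
                       seed, trajectory)


SIZE_CLASS_EVENTS = {"small": 4, "medium": 5, "large": 6}


def generate_ensemble(size_classes: dict[str, int],
                      seed: int = 0,
                      ladder: Optional[np.ndarray] = None,
                      max_attempts_factor: int = 30,
                      min_morphs: int = 2,
                      require_full_events: bool = True,
                      progress: bool = False) -> list[AssemblyLog]:
    """Assemble an ensemble of networks across the kernel-width sweep.

    Kernel combinations (sigma_C, sigma_m, sigma_A = sigma_P) are drawn
    uniformly (seeded) from the multiplicative ladder e^-3..e with step
    e^(1/4); combinations yielding monomorphic or non-converged systems, or
    a guild with fewer than ``min_morphs`` morphs, are discarded, exactly
    as undiversified parameter sets are dropped from the study design.

    ``size_classes`` maps class names ('small'/'medium'/'large', i.e. 4/5/6
    branching events) to requested network counts.
    """
    if ladder is None:
        ladder = sweep_ladder()
    rng = np.random.default_rng(seed)
    logs: list[AssemblyLog] = []
    for cls, count in size_classes.items():
        target_events = SIZE_CLASS_EVENTS.get(cls)
        if target_events is None:
            raise ValueError(f"unknown size class {cls!r}")
        got = 0
        attempts = 0
        max_attempts = max_attempts_factor * max(count, 1)
        while got < count and attempts < max_attempts:
            attempts += 1
            sC, sm, sA = rng.choice(ladder, size=3)
            params = ModelParams().with_kernels(sigma_C=float(sC),
                                                sigma_m=float(sm),
                                                sigma_A=float(sA))
            sub_seed = int(rng.integers(0, 2 ** 31 - 1))
            try:
                log = assemble_network(params, target_events, seed=sub_seed)
            except (np.linalg.LinAlgError, FloatingPointError):
                continue
            if not log.converged:
                continue
            if require_full_events and log.n_events != target_events:
                continue
            n, m = log.guild_sizes()
            if n < min_morphs or m < min_morphs:
                continue
            # a community without realized mutualistic links (all q_ij
            # below threshold) is not a bipartite network; discard
            from .model import interaction_strength_matrix
            if interaction_strength_matrix(log.final_community).Q.sum() <= 0:
                continue
            logs.append(log)
            got += 1
            if progress:
                print(f"[{cls}] {got}/{count} "
                      f"(sC={sC:.3f} sm={sm:.3f} sA={sA:.3f}; {n}x{m})",
                      flush=True)
    if not logs:
        raise RuntimeError("ensemble generation yielded no viable networks")
    return logs
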
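"""Network stability metrics and the alien-invasion trial engine.

Stability side: resilience (Jacobian return rate), topological robustness
to generalist-first species removal, and disruptiveness (mean curvature of
invasion fitness at the singularity, a measure of evolutionary
instability).  Invasion side: an alien animal is introduced into a native
community at its preinvasion singularity with traits frozen, population
densities alone follow the ecological dynamics, and invasiveness/impact
are read off after 25 time units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .assembly import invasion_fitness
from .community import Community, GuildState, InteractionMatrix
from .dynamics import integrate_dynamics, jacobian

__all__ = [
    "InvasionScenario",
    "InvasionOutcome",
    "StabilityMetrics",
    "resilience",
    "robustness",
    "disruptiveness",
    "introduction_schedule",
    "run_invasion_trial",
    "invasiveness_impact_grid",
    "invasibility",
    "ensemble_invasion_record",
]

#: measurement horizon of every invasion trial, in model time units
MEASUREMENT_TIME = 25.0

#: interval between consecutive introductions
PULSE_INTERVAL = 5.0

#: floor applied to a vanished alien's final density so the log growth
#: rate stays finite (the trial is marked failed)
LOG_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# stability metrics


def resilience(community: Community, use_modulus: bool = False) -> float:
    """Resilience RES = ln |lambda| of the dominant Jacobian eigenvalue.

    The dominant eigenvalue is the one with the largest real part (the
    slowest-returning perturbation mode); ``use_modulus`` switches to the
    largest-modulus reading.  The community must be at a stable
    equilibrium, as preinvasion communities are.
    """
    J = jacobian(community)
    eig = np.linalg.eigvals(J)
    if np.max(eig.real) >= 0:
        raise ValueError("resilience requires a stable equilibrium")
    lam = eig[np.argmax(np.abs(eig))] if use_modulus else eig[np.argmax(eig.real)]
    return float(np.log(np.abs(lam)))


def robustness(Q: Union[np.ndarray, InteractionMatrix]) -> float:
    """Topological robustness ROB to generalist-first removal.

    Species of both guilds are pooled and removed one at a time in order
    of decreasing weighted degree (marginal interaction total); after each
    removal, species left with no interaction partners go secondarily
    extinct.  ROB is the fraction of species that had to be removed for
    more than 50% of all species to be lost.
    """
    if isinstance(Q, InteractionMatrix):
        Q = Q.Q
    Q = np.asarray(Q, dtype=float)
    n, m = Q.shape
    total = n + m
    if total == 0 or Q.sum() <= 0:
        raise ValueError("robustness undefined for an empty network")
    degree = np.concatenate([Q.sum(axis=1), Q.sum(axis=0)])
    order = np.argsort(-degree, kind="stable")
    alive_r = np.ones(n, dtype=bool)
    alive_c = np.ones(m, dtype=bool)
    removed = 0
    for sp in order:
        if sp < n:
            if not alive_r[sp]:
                continue
            alive_r[sp] = False
        else:
            if not alive_c[sp - n]:
                continue
            alive_c[sp - n] = False
        removed += 1
        # topological cascade: species with no remaining partners die off
        changed = True
        while changed:
            changed = False
            sub = Q[np.ix_(alive_r, alive_c)]
            if alive_r.any() and alive_c.any():
                dead_r = sub.sum(axis=1) <= 0
                dead_c = sub.sum(axis=0) <= 0
            else:
                dead_r = np.ones(alive_r.sum(), dtype=bool)
                dead_c = np.ones(alive_c.sum(), dtype=bool)
            if dead_r.any():
                idx = np.flatnonzero(alive_r)[dead_r]
                alive_r[idx] = False
                changed = True
            if dead_c.any():
                idx = np.flatnonzero(alive_c)[dead_c]
                alive_c[idx] = False
                changed = True
        lost = total - int(alive_r.sum()) - int(alive_c.sum())
        if lost > 0.5 * total:
            return removed / total
    return 1.0


def fitness_curvature(community: Community, guild: str, trait: float,
                      step: float = 1e-4) -> float:
    """Central second difference of invasion fitness at a trait value."""
    xs = np.array([trait - step, trait, trait + step])
    f = invasion_fitness(community, guild, xs)
    return float((f[0] - 2.0 * f[1] + f[2]) / step ** 2)


def disruptiveness(community: Community, step: float = 1e-4,
                   aggregate: str = "mean") -> float:
    """Disruptiveness DIS: strength of disruptive selection on animals.

    The curvature of each animal morph's invasion fitness at its singular
    trait, aggregated as the mean over morphs (``aggregate='sum'`` gives
    the summed variant).  Positive values mean the community sits at
    fitness minima and is evolutionarily unstable (branching-prone).
    """
    if community.n == 0:
        raise ValueError("no animal morphs")
    curv = [fitness_curvature(community, "animal", x, step)
            for x in community.animals.traits]
    if aggregate == "mean":
        return float(np.mean(curv))
    if aggregate == "sum":
        return float(np.sum(curv))
    raise ValueError("aggregate must be 'mean' or 'sum'")


@dataclass
class StabilityMetrics:
    RES: float
    ROB: float
    DIS: float
    INVb: float


# ---------------------------------------------------------------------------
# invasion trials


@dataclass
class InvasionScenario:
    """Definition of one alien introduction.

    rtv
        Relative trait value: 0 maps to the lowest and 1 to the highest
        native animal trait (values outside [0, 1] probe beyond the
        native range).
    glr
        Generalization-level ratio: the alien's mutualism tolerance is
        glr * native sigma_m (1/5 = extreme specialist, 5 = extreme
        generalist).
    propagule_fraction
        Total introduced density as a fraction of the mean native animal
        density (the study used 0.05, 0.10 and 0.25).
    mode
        Introduction schedule 1-5 (once-off, two equal pulses, three
        increasing, three decreasing, five equal).
    """

    rtv: float
    glr: float = 1.0
    propagule_fraction: float = 0.10
    mode: int = 1
    measurement_time: float = MEASUREMENT_TIME

    def __post_init__(self) -> None:
        if self.glr <= 0:
            raise ValueError("glr must be positive")
        if self.propagule_fraction <= 0:
            raise ValueError("propagule_fraction must be positive")


@dataclass
class InvasionOutcome:
    INVn: float            # alien relative growth rate ln(final/introduced)
    IMP: float             # |ln| change of total native animal density
    success: bool          # INVn > 0
    native_decline: bool   # total native density decreased
    native_change: float   # relative change of total native density
    alien_final: float
    failed: bool           # alien extinct before measurement
    trajectory: Optional[object] = None


def introduction_schedule(mode: int, total: float) -> list[tuple[float, float]]:
    """Pulse times and amounts for the five introduction modes.

    1: all at t=0; 2: two equal pulses; 3: three increasing (20/30/50%);
    4: three decreasing (50/30/20%); 5: five equal pulses of 20%; pulses
    are separated by five time units.
    """
    if total <= 0:
        raise ValueError("total propagule size must be positive")
    dt = PULSE_INTERVAL
    if mode == 1:
        fracs = [1.0]
    elif mode == 2:
        fracs = [0.5, 0.5]
    elif mode == 3:
        fracs = [0.2, 0.3, 0.5]
    elif mode == 4:
        fracs = [0.5, 0.3, 0.2]
    elif mode == 5:
        fracs = [0.2] * 5
    else:
        raise ValueError(f"unknown introduction mode {mode!r}")
    return [(i * dt, f * total) for i, f in enumerate(fracs)]


def _alien_trait(native: Community, rtv: float) -> float:
    lo = float(native.animals.traits.min())
    hi = float(native.animals.traits.max())
    return lo + rtv * (hi - lo)


def run_invasion_trial(native: Community, scenario: InvasionScenario,
                       record: bool = False,
                       rtol: float = 1e-8) -> InvasionOutcome:
    """Introduce an alien animal and measure invasiveness and impact.

    The alien enters with trait mapped by rtv onto the native animal trait
    range and a private mutualism tolerance glr * sigma_m; traits stay
    frozen and only densities evolve.  Propagules are added instantaneously
    at the schedule times; at t=25 the invasiveness INVn = ln(alien final
    density / total propagules) and the impact IMP = |ln(native animal
    total after / before)| are recorded.
    """
    if native.n == 0 or native.m == 0:
        raise ValueError("native community needs both guilds")
    p = native.params
    trait = _alien_trait(native, scenario.rtv)
    T = scenario.propagule_fraction * float(native.animals.densities.mean())
    schedule = introduction_schedule(scenario.mode, T)
    pulse = dict(schedule)

    A0 = np.concatenate([native.animals.densities, [0.0]])
    x0 = np.concatenate([native.animals.traits, [trait]])
    comm = Community(GuildState(x0, A0),
                     native.plants.copy(), p,
                     alien_index=native.n,
                     alien_sigma_m=scenario.glr * p.sigma_m)

    native_A0 = float(native.animals.densities.sum())
    native_tot0 = float(native.animals.densities.sum()
                        + native.plants.densities.sum())
    times = sorted(pulse)
    t_end = scenario.measurement_time
    segments = []
    trajs = []
    t_cur = 0.0
    for t_pulse in times:
        if t_pulse > t_cur:
            res = integrate_dynamics(comm, t_pulse - t_cur, record=record,
                                     rtol=rtol)
            comm = res.community if record else res
            if record:
                trajs.append((t_cur, res))
            t_cur = t_pulse
        A = comm.animals.densities.copy()
        A[-1] += pulse[t_pulse]
        comm = comm.with_densities(A, comm.plants.densities)
    if t_end > t_cur:
        res = integrate_dynamics(comm, t_end - t_cur, record=record,
                                 rtol=rtol)
        comm = res.community if record else res
        if record:
            trajs.append((t_cur, res))

    alien_final = float(comm.animals.densities[-1])
    failed = alien_final < p.extinction_threshold
    INVn = float(np.log(max(alien_final, LOG_FLOOR) / T))
    native_A = float(comm.animals.densities[:-1].sum())
    IMP = float(abs(np.log(native_A / native_A0)))
    native_tot = float(comm.animals.densities[:-1].sum()
                       + comm.plants.densities.sum())
    change = (native_tot - native_tot0) / native_tot0
    return InvasionOutcome(INVn=INVn, IMP=IMP, success=INVn > 0,
                           native_decline=native_tot < native_tot0,
                           native_change=float(change),
                           alien_final=alien_final, failed=failed,
                           trajectory=trajs if record else None)


def default_rtv_grid(k: int = 9) -> np.ndarray:
    return np.linspace(0.0, 1.0, k)


def default_glr_grid(k: int = 9) -> np.ndarray:
    """Log-symmetric ladder from 1/5 to 5 (centered on 1)."""
    return np.logspace(np.log10(0.2), np.log10(5.0), k)


def invasiveness_impact_grid(native: Community,
                             rtv_grid: Optional[Sequence[float]] = None,
                             glr_grid: Optional[Sequence[float]] = None,
                             propagule_fraction: float = 0.10,
                             mode: int = 1) -> list[list[InvasionOutcome]]:
    """Full factorial invasion outcomes over the rtv x glr design
    (defaults: 9 evenly spaced trait positions x 9 log-spaced
    generalization ratios)."""
    if rtv_grid is None:
        rtv_grid = default_rtv_grid()
    if glr_grid is None:
        glr_grid = default_glr_grid()
    out = []
    for rtv in rtv_grid:
        row = []
        for glr in glr_grid:
            sc = InvasionScenario(rtv=float(rtv), glr=float(glr),
                                  propagule_fraction=propagule_fraction,
                                  mode=mode)
            row.append(run_invasion_trial(native, sc))
        out.append(row)
    return out


def invasibility(native: Community, propagule_fraction: float = 0.10,
                 mode: int = 1, n_traits: int = 9) -> float:
    """INVb: proportion of successful invasions over alien traits spanning
    the native range (glr = 1)."""
    successes = 0
    for rtv in default_rtv_grid(n_traits):
        sc = InvasionScenario(rtv=float(rtv), glr=1.0,
                              propagule_fraction=propagule_fraction,
                              mode=mode)
        if run_invasion_trial(native, sc).success:
            successes += 1
    return successes / n_traits


def ensemble_invasion_record(native: Community,
                             propagule_fraction: float = 0.10,
                             mode: int = 1) -> InvasionOutcome:
    """Reference invasion used in the cross-network correlation analysis:
    alien trait = density-weighted mean native animal trait, glr = 1."""
    w = native.animals.densities
    mean_trait = float((native.animals.traits * w).sum() / w.sum())
    lo = float(native.animals.traits.min())
    hi = float(native.animals.traits.max())
    rtv = 0.5 if hi == lo else (mean_trait - lo) / (hi - lo)
    sc = InvasionScenario(rtv=rtv, glr=1.0,
                          propagule_fraction=propagule_fraction, mode=mode)
    return run_invasion_trial(native, sc)
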
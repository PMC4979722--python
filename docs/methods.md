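# Methods

## The model

`mutunet` simulates the assembly and invasion of bipartite mutualistic
networks (animal pollinators/seed dispersers and plants) in which every
interaction is mediated by a single quantitative trait per morphospecies
(e.g. log proboscis length against log corolla-tube depth).

### Ecological dynamics

Population densities follow a Lotka–Volterra system with intra-guild
competition and a saturating cross-guild mutualistic benefit (Holling
type II):

    dA_i/dt = A_i f_A(x_i)
    f_A(x_i) = r_A − r_A Σ_k γ(x_i, x_k) A_k / K_A(x_i)
               + Σ_j b(x_i, y_j) w_ij P_j / (1 + h Σ_j w_ij P_j)

mirrored for plants. Three Gaussian kernels set the trait dependence:

| kernel | form | meaning |
|---|---|---|
| carrying capacity | `K(x) = k exp(−(x−x_max)²/2σ_A²)` | resource accessibility peaks at the optimum |
| competition | `γ(Δ) = exp(−Δ²/2σ_C²)` | similar traits compete hardest |
| mutualistic benefit | `b = c exp(−(x−y)²/2σ_m²)` | matched partners profit most |

The adaptive interaction preference
`w_ij = b_ij Σ_k A_k / Σ_k A_k b_kj` redistributes foraging toward
partners that are both common and trait-matched; it depends only on
density ratios, so preferences are invariant to rescaling a guild.

The default carrying-capacity kernel is the *unnormalized* Gaussian, so
its maximum equals the scale constant k at the optimum; the normalized
probability-density variant is available via `ModelParams(normalized_K=
True)`. With the normalized form the peak capacity would shrink as σ_A
grows across the sweep, entangling kernel width with community size; the
unnormalized reading keeps "maximum resource level k" literal.

Reference parameters: r_A = r_P = 1, h = 0.1, k_A = 400, k_P = 300,
x_Amax = 3, y_Pmax = 2, c = 0.1, m_A = m_P = 10⁻³; a morph is extinct
below density 10⁻⁸ and interaction strengths below 10⁻⁸ are stored as
exact zeros.

### Trait evolution

Trait dynamics follow adaptive dynamics: residents sit at their stable
ecological equilibrium, a rare mutant's invasion fitness is its
per-capita growth rate in that environment, and traits flow along the
canonical equation `dx_i/dt = m N_i g_i` with the selection gradient
`g_i = ∂f/∂x'` at the resident trait. A morph at an evolutionary
singularity branches when three numerical conditions hold
simultaneously: convergence stability (`∂g/∂x < 0`, per-morph diagonal
partial with the equilibrium re-solved inside the perturbation),
disruptive selection (`∂²f/∂x'² > 0`), and mutual invasibility (resident
plus mutant curvature > 0). A branching event splits *every* qualifying
morph in both guilds at once: the daughter starts at trait + 0.01 with
10% of the parent density, the parent keeps 90%. Four, five or six
consecutive events define the small/medium/large size classes (at most
2^E morphs per guild).

## Numerical scheme

- **Equilibria.** Densities are integrated in log space (adaptive
  explicit Runge–Kutta, rtol 10⁻⁸), which preserves positivity without
  clipping; along evolutionary trajectories a damped Newton solve on
  log-densities with the analytic per-capita Jacobian, warm-started from
  the previous equilibrium, replaces most integrations. Convergence
  means `max_i |dN_i/dt| < 10⁻⁹ max(N_i, 1)`; converged equilibria are
  verified asymptotically stable via the Jacobian spectrum. The public
  `jacobian` uses central finite differences on the exact right-hand
  side (the analytic form backs the solver and is tested against it).
- **Canonical flow.** Explicit Euler with an adaptive step: no trait
  moves more than 0.005 per step and the step respects a secant estimate
  of the locally stiffest flow mode. Near a singularity the flow is
  stiff, so once the maximal speed `|m N g|` falls below 5·10⁻³ the
  singularity is located directly: a capped Newton solve of the
  gradient-map root first (fast, and able to cross narrow nonlinear
  valleys), falling back to a linearly implicit (backward-Euler) flow
  integrator whose steps are unconditionally stable. Newton roots are
  accepted only if they are attractors of the canonical flow — this
  rejects the collapsed parent/daughter saddle immediately after a
  branching — and any solve in which a morph goes extinct is abandoned.
  A singularity is declared at `max |m N g| < 10⁻⁷`.
- **Derivative steps.** First derivatives (gradients) use central
  differences with step 10⁻⁶; curvature-like quantities (branching
  tests, disruptiveness, convergence test) use step 10⁻⁴. The branching
  inequalities are applied with a strict tolerance of 10⁻⁶ because at
  degenerate kernel combinations (σ_C = σ_A with c = 0) the landscape is
  exactly flat and finite differences return rounding noise of arbitrary
  sign.
- **Non-convergence.** Trait configurations whose flow speed stops
  contracting (a near-neutral collective drift that would need orders of
  magnitude more evolutionary time) are flagged non-converged; the
  ensemble generator discards them exactly as it discards monomorphic
  parameter combinations. The realized ensemble therefore consists of
  networks that reach a clean singularity, which parallels the study
  design of keeping only diversified systems.

## The ensemble generator (synthetic-data source)

Kernel combinations (σ_C, σ_m, σ_A = σ_P) are drawn uniformly (seeded)
from the 17-point multiplicative ladder e⁻³ … e with step e^(1/4).
A draw is kept when the assembly converges, performs the full number of
branching events for its size class, and leaves at least two morphs in
each guild; otherwise the draw is discarded and repeated. Assembly
itself is deterministic given the parameters; the seed only drives the
sweep sampling and the modularity annealing. The generator emulates the
variation in network architecture that the kernel sweep produces; it
does not emulate demographic stochasticity, environmental noise,
sampling effort, or observation error of real interaction networks, so
passing tests certify the model's internal logic, not field data
behavior.

## Network metrics

All four architecture metrics operate on the quantitative interaction
matrix `q_ij = ½[A_i b w_ij P_j/(1+h w_ij P_j) + P_j b w_ji A_i/(1+h
w_ji A_i)]` (entries < 10⁻⁸ zeroed) and are invariant to positive
rescaling of Q:

- **SPE (H2′)** standardizes the Shannon entropy of interactions between
  the marginal-constrained extremes: H2max is the entropy of the
  marginal outer product; H2min is found by a greedy largest-allocation
  packing with 100 seeded randomized tie-break restarts (the exact
  minimum is a hard transportation problem). 1×1 matrices return 0 by
  convention (no specialization contrast exists).
- **CON** is the quantitative linkage density — the marginal-weighted
  mean of 2^H with H the base-2 entropy of each species' interaction
  distribution (effective partner count) — divided by n + m.
- **NEST (WNODF)** packs rows and columns by decreasing fill with
  marginal-total tie-break; an ordered pair contributes the percentage
  of the more specialized species' links that are strictly weaker than
  the generalist's, and pairs without strictly decreasing fill score 0.
  This matches the reference R implementation (vegan `nestednodf`,
  weighted), which is cross-checked in the test suite.
- **MOD** maximizes Barber's weighted bipartite modularity
  `Σ_ij [q_ij/F − R_i C_j/F²] δ(module_i, module_j)` by simulated
  annealing (T₀ = 1, geometric cooling ratio 0.995, 10⁴ steps, best of 5
  restarts, seeded): single-node relabeling moves with occasional module
  merges; restarts stand in for explicit split moves. This is an
  equivalent-objective substitute for the hierarchical QuanBimo search;
  reported values carry their seed.

## Stability and invasion

- **RES** = ln|λ| with λ the Jacobian eigenvalue of largest real part at
  the preinvasion equilibrium (the slowest-returning mode; a
  largest-modulus variant is available).
- **ROB**: species of both guilds pooled and removed generalist-first by
  weighted degree (static initial ordering, ties by index); partners
  left without any link go secondarily extinct (topological cascade);
  ROB is the removed fraction when more than 50% of species are lost.
- **DIS**: the mean over animal morphs of the invasion-fitness curvature
  at the singular trait (step 10⁻⁴); a summed variant is available
  behind the `aggregate` flag. Positive DIS marks evolutionarily
  unstable (branching-prone) communities.
- **Invasion trials** freeze all traits, append an alien animal at trait
  `min + rtv (max − min)` of the native animal traits with private
  tolerance `glr · σ_m`, and integrate the ecology to t = 25 with
  propagules added instantaneously at t ∈ {0, 5, 10, 15, 20} according
  to the introduction mode (once-off; two equal; three increasing
  20/30/50%; three decreasing 50/30/20%; five equal). INVn = ln(alien
  density at t = 25 / total propagules); IMP = |ln| change of total
  native animal density. A vanished alien's final density is floored at
  10⁻⁸ inside the logarithm so INVn stays finite and order-consistent,
  and the trial is marked failed. "Native decline" compares the summed
  density of both native guilds at t = 25 with its preinvasion value.
- **INVb** is the success proportion over 9 evenly spaced rtv values at
  glr = 1 (once-off, 10% propagule by default); the 9-point grid mirrors
  the trial design. The cross-network reference invasion uses the
  density-weighted mean native animal trait at glr = 1.

## Ensemble statistics

Ten observables per network (SPE, CON, NEST, MOD, RES, ROB, DIS, INVb,
INVn, IMP) are rank-correlated (tie-corrected Spearman; constant columns
give missing values, never zero). The metric map uses classical MDS of
the distance d = 1 − r (two components; a 1 − |r| variant is available),
k-means with 50 seeded restarts for each k, and selects the smallest k
whose between-cluster variance share in the embedding exceeds 95%.
Hierarchical grouping uses average linkage on the same distance with
support from an ordinary row bootstrap (default 1000 resamples): the
support of a cluster is the fraction of bootstrap dendrograms containing
the identical metric set, reported at the 0.95 level. This ordinary
bootstrap replaces the multiscale (AU) bootstrap of pvclust; plain
bootstrap proportions are biased low for small clusters, so its support
values are conservative.

## Problem sizes

The bundled acceptance analysis assembles 40 small and 30 medium
networks across the sweep and runs the 9×9 alien grid on 30 medium
networks; these counts are the package's reduced study conditions,
chosen so a complete run finishes on a laptop core in well under half an
hour while leaving the correlation signs and magnitudes stable. The full
thousand-network design is reproducible by raising the counts in
`StudyConfig`.

## Known limitations

- No demographic or environmental stochasticity; the canonical equation
  is the deterministic mutation-limited flow, without polymorphic trait
  distributions.
- Guild-symmetric parameters; aliens are animals only (the model is
  symmetric across guilds).
- The extinction threshold doubles as the interaction-strength cutoff.
- Simulated-annealing modularity is a heuristic; on adversarial matrices
  it can undershoot the optimum, which the seeded restarts mitigate but
  do not eliminate.
- Slow-drift parameter combinations are discarded rather than integrated
  for unbounded evolutionary time; see "Non-convergence" above.
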
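# Methods

## Model

`drivespread` models three mosquito compartments on a 1D transect
[0, L] km, indexed by zygosity at a transgene locus: wild u1 = (w,w),
heterozygous u2 = (w,g) and homozygous transgenic u3 = (g,g). The model
assumes equal fitness of all genotypes (supported for non-inbred
heterozygous *Anopheles stephensi* lines), an implicit 1:1 sex ratio with
unsexed totals, random local mating, logistic density dependence acting on
births, and Fickian dispersal with no advection (urban-dispersal setting).
Seasonality, stage structure, fitness costs, resistant alleles and
sex-specific drive efficiency are out of scope.

The genotype densities obey

    ∂u_k/∂t = κ_k u_k,xx + (ε/N − γ/C) S_k(u) − δ u_k,
    S_k(u) = Σ_{i≤j} m_ij x^k_ij u_i u_j,

with zero-flux boundaries, where x^1 = a, x^2 = b, x^3 = c are the
offspring-frequency tables and m_ij is 1 for selfing pairs and 2 for cross
pairs. The multiplicity convention is forced: it is the unique choice
under which Σ_k S_k = N², so that adding the three equations yields the
logistic-with-harvesting aggregate dN/dt = γN(1−N/C) − δ2N and its
equilibrium N* = C(1 − δ2/γ). The ε/N birth factor is defined as 0 at
N = 0 (the mating sums vanish like N²).

Two inheritance modes: Mendelian (classical Punnett fractions), and
gene-drive conversion in which heterozygous offspring become homozygous
with efficiency f (b → (1−f)b, c → c + fb). Under Mendelian inheritance
the reaction dynamics conserve the transgene frequency
q = (u2 + 2u3)/(2N) and drive genotype proportions to Hardy–Weinberg
(p², 2pq, q²); with f > 0, q increases monotonically toward fixation.
Both facts are exercised as numerical tests.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| ε | emergence rate into adulthood | 5.1 | week⁻¹ |
| δ1 | natural mortality | 3.9 | week⁻¹ |
| δ2 | density-independent removal (predation, control) | 0.5 | week⁻¹ |
| γ = ε − δ1 | intrinsic growth rate | 1.2 | week⁻¹ |
| δ = δ1 + δ2 | total linear death rate | 4.4 | week⁻¹ |
| C | carrying capacity | 2500 | km⁻¹ |
| f | drive conversion efficiency | 0.14 (drive scenarios) | – |
| κ | diffusion coefficient | U(0.01, 0.05) | km²/week |
| L, T | domain, horizon | 30 km, 12 weeks | |

γ derives from a daily finite rate of increase of 1.19 for laboratory
*A. stephensi*: (1.19)⁷ = 3.38 per week, γ = ln 3.38 ≈ 1.2. We fix
γ = 1.2 exactly (the conventional rounded value) so that δ1 = 5.1 − 1.2 =
3.9; `vital_rates_from_daily` returns both rounded and unrounded values.
The δ used in the genotype equations is not independently given; δ = δ1 +
δ2 is the unique value consistent with the aggregate reduction above. The
κ interval brackets the point estimate from the female-dispersal
regression y = 58.741 + 23.731x m/day: 224.86 m/week, κ = (0.22486 km)²/2
≈ 0.0253 km²/week for 1D diffusion (`dispersal_to_kappa`). The drive
efficiency 0.14 corresponds to transmission through the female germline;
the male-line value (0.98) can be set via the scenario `f` field. No
sex-averaged mixing rule is applied since none is established.

## Discretization

* Space: Galerkin Lagrange finite elements (linear by default, quadratic
  optional) with consistent mass matrix; no essential boundary
  constraints, so zero flux is natural and 1ᵀMu is conserved to machine
  precision per diffusion step. The default mesh has three blocks
  [0,10], [10,20], [20,30] with 20/40/20 uniformly spaced vertices and
  shared block boundaries (78 nodes, 77 elements); quadratic adds one
  midside node per element (155 nodes). We read "nodes per block" as
  vertex counts with merged interfaces — the alternative (duplicated
  interface nodes) would be non-conforming. Reported totals are
  insensitive to this choice (checked under 4x refinement and quadratic
  elements).
* Time: sequential (Lie) splitting with Δt = 0.01 week: one Crank–Nicolson
  diffusion step, then one classical RK4 step of the reaction system at
  each node, diffusion first. The splitting is first-order in Δt
  (verified by self-convergence, slope ≈ 1); Δt = 0.01 makes the RK4 and
  CN errors negligible against the splitting error, and halving Δt moves
  the 12-week totals by far less than the reporting precision. No Strang
  symmetrization, matching the sequential formulation.
* Positivity: the consistent-mass CN step undershoots at the sharp edges
  of the piecewise-constant release profiles (a Gibbs artifact of a few
  per mille of the jump, present only while the profile is sharp).
  Negative densities must not reach the reaction operator — the ε/N
  factor is controlled by S ≤ N² only for nonnegative states, and
  sustained negative dips can destabilize the coupled system. Each
  sub-step therefore clips negative nodal values to zero; the associated
  mass error is orders of magnitude below the reporting precision.
  Undershoot beyond 5% of the field scale aborts as a genuine
  instability. Pure-reaction trajectories use a much stricter roundoff
  threshold.
* Initial conditions are interpolated nodally; release segments are
  closed intervals, so boundary nodes take the inside value and the
  trapezoidal release total slightly exceeds the nominal count (e.g.
  ~1026 for a nominal 1000 on the default mesh). This is reported, not
  rescaled.
* The CN system is LU-factorized once per (mesh, κ, Δt) and reused across
  all steps of a realization; genotypes sharing a κ share the factor.

## Monte Carlo layer

Each realization draws κ ~ U(s_i, s_f) — by default one shared draw for
all three genotypes (no evidence of differential flight capacity), with an
independent-draws mode available. Realization k uses an RNG stream seeded
by (seed, k), so ensembles are reproducible and order-independent. The
ensemble mean is the sample average; the variance uses the population
(1/N_s) normalization of the squared fluctuation around the mean, with the
unbiased variant behind a flag. The "cumulative variance" reported
alongside is the running sum of the variance field over the output times
(T = 3, 6, 9, 12 weeks by default) — a definition chosen for its monotone
growth in T; the raw variance is always available. The sample-size
diagnostic E_rel(N_s) is the relative change, in the spatial L2 norm of
the wild-population moment at the final time, between nested prefixes of
N_s and N_s+1 realizations; with the default scenarios it falls below 1%
by N_s ≈ 150, which is the default ensemble size.

## Scenarios

All seven built-in scenarios share the default parameters above
and differ only in the initial segments: an equal 250/250 per-km release
on [13,17] (laboratory analogue); 500 wild + 250 het on [13,17]; the
drive variant 500/215/35; 500 wild on [13,17] with 1000 het concentrated
on [14.5,15.5] (and the 860/140 drive split); and 500 wild on [13,17]
with 1000 transgenics spread over [12,18] at 166.67 per km (drive split
143.33/23.33). Drive releases split 1000 transgenics as 860 het + 140 hom
(14% pre-converted), giving a parental transgene frequency q = 0.19. The
printed densities 166.67/143.33/23.33 are used exactly as stated rather
than 1000/6 etc.

## What the generator does and does not emulate

The scenarios are synthetic study conditions, not field data: determinate
piecewise-constant releases, homogeneous habitat, constant weekly vital
rates, and dispersal uncertainty as the only stochastic input. Passing
tests therefore demonstrate the correctness and convergence of the
numerics and the internal genetics (HW invariance, drive fixation,
aggregate logistics), not predictive accuracy for real release campaigns,
which would add seasonality, patchy carrying capacity, advection, fitness
costs and demographic stochasticity.

## Numerical caveats and limitations

* Grand totals respond strongly to κ (~±20% over the default interval),
  so ensemble totals carry Monte Carlo error of order 1% at N_s = 150;
  genotype shares and q are far more robust (Hardy–Weinberg- or
  fixation-forced).
* With a shared κ the aggregate identity makes the grand total
  independent of the inheritance mode for a fixed total release profile —
  a strong internal consistency check this implementation satisfies
  exactly, and a useful yardstick when comparing against other solvers
  for the same system: paired Mendelian/drive totals that disagree signal
  numerical artifacts of that size.
* The wide-strip Mendelian release converges to a final transgene
  frequency q ≈ 0.318, stable under every refinement of mesh, step and
  element order we tested (dt from 0.3 down to 0.0025, 4x mesh
  refinement, quadratic elements, either κ coupling mode).
* Crank–Nicolson is unconditionally stable but not monotone; the
  positivity clip above is the standard remedy and is monitored, not
  silently unbounded.
* 2D domains, advection, spatially varying κ within a realization, and
  epidemiological coupling are out of scope.
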
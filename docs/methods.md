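# Methods

## Model

The system is an idealized chemostat: dilution rate `a` (default
0.04 d⁻¹), inflow concentrations `s` (by default only organic-matter
nitrogen s₁ and nitrate s₂ are nonzero), and twelve state variables —
seven biomasses and five resource pools, all in μM of nitrogen atoms
(N₂O is tracked in N-atom units, so half a μM of N₂O molecules is one μM
N). Resources are essential and non-substitutable: each functional type
needs one electron donor (OM, or NH₄⁺ for anammox) and one acceptor.
Growth is Liebig-limited Monod kinetics; uptake of the non-limiting
resource is slaved to the limiting one, which makes the right-hand side
continuous but not smooth at limitation switches. No smoothing is
applied; the integrator (LSODA, rtol 1e-8, atol 1e-12) handles the kinks
through step-size control.

Excretion closes the nitrogen budget type by type. The NO₃⁻→NO₂⁻ reducer
routes all reduced nitrate-N to nitrite (rate μ₁/y₁₂ per biomass); the
two N₂O producers route all acceptor-N to N₂O; the NO₂⁻→N₂, N₂O→N₂ and
complete denitrifiers route acceptor-N to N₂ gas, the only loss term.
Every heterotroph remineralizes NH₄⁺ at e = μ (1/y_OM − 1): OM-N uptake =
biomass synthesis + NH₄⁺ release, exactly. Across the built-in yields
(0.138–0.298) this makes NH₄⁺ regeneration 70.2%–86.2% of OM-N uptake. A
scalar multiplier (`nh4_fraction`) is exposed for sensitivity runs but
defaults to the exact nitrogen balance. Anammox excretes nothing; its
non-assimilated substrate N (both NH₄⁺ and NO₂⁻ streams) leaves as N₂.
Anammox nitrate release is neglected. With these rules the instantaneous
budget a·Σs − a·(ΣR+ΣB) − d/dt(ΣR+ΣB) − N₂flux vanishes identically;
tests verify it to 1e-8 relative along trajectories (it holds to machine
precision by construction).

## Trait parameterization

The built-in table carries the published kinetics of this guild: shared
uptake kinetics among competing heterotroph modules (V^m = 1.377 d⁻¹ on
OM with K = 0.1 μM; V^m = 50.8 d⁻¹ on N acceptors with K = 4 μM, except
0.6 μM for N₂O and 0.45 μM for both anammox substrates) and
energetics-derived yields. The dilution rate is not part of the table; the
default a = 0.04 d⁻¹ is the value recovered by inverting
R* = K·a/(y·V^m − a) against the published subsistence column (e.g. B1/OM:
0.1·0.04/(0.15·1.377 − 0.04) = 0.02402 vs printed 0.024). Because printed
yields are rounded, back-computed R* values match the printed column to
~2% where yields carry three significant digits and to ~5% where they
carry two (B1/NO₃⁻, B5/NH₄⁺, B5/NO₂⁻); the exact unrounded yields are not
recoverable and no attempt is made to fit them.

## Equilibria, invasion, assembly

`find_equilibrium` integrates in doubling checkpoints (10³, 2·10³, …, up
to 10⁶ days) until the scaled residual max|dX/dt|/(|X|+1e-6) drops below
1e-8; runs that exhaust the horizon are labelled nonstationary, never
averaged. Biomasses below the extinction threshold (1e-9 μM N) are
clipped to zero between checkpoints, and — important numerically — the
integrator pins never-inoculated or extinct types to exactly zero.
Without that mask, solver round-off can seed an absent population with
~1e-16 μM of biomass which then grows ecologically if the state is
invasible, silently converting a subsystem run into a full-system run.
Convergence is defined on scaled derivatives rather than state
differences to cope with the slow transients near transcritical
(exclusion) boundaries, where the losing competitor decays at a rate that
can be arbitrarily close to zero.

Invasion is evaluated at the resident equilibrium with frozen resources
(standard adaptive-dynamics practice): an invader succeeds when its
Liebig growth rate there exceeds a. Assembly experiments inoculate
arrivals at 1e-6 μM N — small enough not to perturb residents, large
enough to stay clear of the extinction floor — and re-equilibrate between
arrivals. Multistability detection runs a canonical battery (each
subsystem member first with the rest in index order, plus an all-at-once
start at 1e-3 μM N each), clusters the final states first by the identity
of the persistent set and then by relative state distance (1e-4), and
verifies mutual non-invasibility of distinct states. The battery is a
pragmatic stand-in for exhaustive order enumeration; it is guaranteed to
probe first-arrival asymmetry, which is the mechanism at play here.

## Supply-space sweeps

Regime maps run `find_equilibrium` from the all-present start on a grid
of (s₁, s₂). The default axes are 61 points, log-spaced over
[0.05, 30] μM N in both supplies. Log spacing is a deliberate choice:
community regimes are organized by the supply *ratio* (the coexistence
wedges sit between consumption vectors 5.0–13.6), so even sampling in
log supply samples ratios evenly, and it resolves the subsistence corner
at low joint supply where the qualitatively distinct low-density regimes
live. Linear spacing over the same ranges is available via configuration
(`spacing: linear`). Axes store inflow concentrations s_j; the
corresponding supply rate is a·s_j, a pure rescaling. Gas fluxes below
1e-10 μM N d⁻¹ count as zero for classification. Nitrogen-loss labels:
`conserved` (no gas), `N2_only`, `N2O_no_consumption` (N₂O produced, no
persistent consumer — the accumulation-potential regime), and
`N2O_cycled_with_N2` (production balanced by consumption en route to N₂).
Per-cell bistability screening (the assembly battery at ~8× cost) is off
by default.

## What the model does and does not reproduce

The following are robust across grid spacing and resolution (21×21 and
61×61, log and linear), and are exercised by the test suite:

* the R* trade-off structure and the published subsistence column;
* the baseline {B1,B2} succession B1 → coexistence → B2 with rising
  OM:NO₃⁻ supply;
* consortium consumption-vector algebra: at simulated feeder–recipient
  equilibria the community NO₃⁻:OM uptake ratio equals
  c₁₃ = 5.124 ({B1,B3}) and c₂₄ = 5.024 ({B2,B4}) to well under 1%;
* genuine priority effects for {B1,B2,B3} in the band of supply ratios
  between c₁₃ and c₂ (mutually non-invasible {B1,B3} vs {B2});
* no supply point supports all seven types, and the weakest NO₂⁻
  competitor (B6) is excluded everywhere;
* the complete denitrifier dominates only OM-rich conditions and loses
  to specialists as NO₃⁻ supply rises.

Two structural expectations about the full system do **not** hold under
this parameterization, and the corresponding acceptance checks are left
failing rather than weakened:

1. **Anammox niche breadth.** Anammox needs ~77 mol NH₄⁺-N per mol
   biomass-N (y = 0.013) while heterotrophs regenerate only ~5.7 mol
   NH₄⁺-N per mol of their own biomass-N. The NH₄⁺ pool therefore caps
   anammox well below its nitrite-limited potential nearly everywhere,
   and at the low-OM margin of the domain (s₁ ≲ 0.06 μM) it sits below
   anammox's subsistence value (0.029 μM) entirely, leaving {B1,B3}
   communities without anammox. Anammox does hold an exclusive advantage
   region (outcompeting B3 for NO₂⁻ where nitrite is scarce, e.g. in
   B1+B2+B4+B5 communities), but on the default domain its niche breadth
   (0.243) falls ~3% short of B3's (0.251). A wider anammox niche would
   require either more NH₄⁺ regeneration or domains excluding the
   ultra-low-OM margin.
2. **Size of the N₂O accumulation regime.** The regime where N₂O is
   produced but no consumer persists exists (e.g. supply
   (0.056, 0.30) μM: a B2+B7 community producing N₂O with no B4), but it
   is a sliver: B4 invades as soon as the N₂O pool B̂₂/y₂₂ exceeds its
   subsistence value, i.e. at feeder biomass ≈ 9e-4 μM N, so the
   B2-present/B4-absent band is only ~0.01 μM of supply wide and falls
   between grid points at practical resolutions. Its extent scales
   directly with the extinction floor: a model with a coarser numerical
   floor (or demographic stochasticity culling sparse populations) would
   widen it substantially. With the 1e-9 μM floor used here, the
   regime is real but nearly measure-zero in supply space.

These points matter for interpretation: passing tests show the
deterministic, well-mixed, steady-supply idealization with exact
nitrogen-balance remineralization — they do not show how finite
populations, supply variability, or transport (all absent here) would
reshape the marginal regimes, and the two failing checks mark exactly
where those idealizations bind.

## Numerical conventions

Liebig ties report the lowest resource index and set a co-limitation
flag. Negative solver excursions below 1e-14 are clipped to zero.
Single-species equilibria have a closed form (limiting resource at R*,
biomass y(s − R*), byproducts at s + B·E/a) used as an independent test
oracle against the integrator (agreement to 1e-4 relative across all
types and seeded random feasible supplies). Trait CSVs round-trip
bit-identically for inputs with ≤ 6 significant digits via repr-based
float formatting. All sweep, assembly and CLI outputs are deterministic
given their configuration; runs archive a config hash and trait hash.
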
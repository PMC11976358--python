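# Methods

This note records the model equations as implemented, the numerical
choices, the defaults and their provenance, and what the tests do and do
not establish.

## Model family

Two populations on a periodic interval [0, L): followers u = u⁺ + u⁻ and
leaders v = v⁺ + v⁻, each split into right (+) and left (−) movers.
Transport is at fixed speeds (γ for followers; β₊ rightward / β₋ leftward
for leaders), and mass moves between orientations at turning rates

    λ(y) = λ₁ + λ₂ f(y),   f(y) = ½ + ½ tanh(y − y₀),

with control variable y = Q_a + Q_l per subpopulation:

- attraction (all subpopulations): Q_a± = −q_a ∫₀^∞ K_a(s) [p(x±s) −
  p(x∓s)] ds with p the total density — turning away from the crowd is
  discouraged;
- follower alignment: compares left- vs right-moving neighbours, leaders
  weighted by conspicuousness α⁺ (rightward) and α⁻ (leftward);
- leader alignment: M2 uses only the cue, Q_l^{v±} = ∓q_l η κ_l; M3 adds
  the same social comparison as the followers to that cue term. κ_l is
  the *discrete* kernel mass (below).

Model M1 prescribes the leaders as a rigid Gaussian pulse of speed β and
evolves only the followers, whose alignment weights the (rightward-only)
leaders by a single factor α.

Kernels are translated Gaussians K_i(s) = N(s; s_i, m_i²) on s ∈ (0, ∞)
with m_i = s_i/8, which puts Φ(8) ≈ 1 − 6·10⁻¹⁶ of the mass on the
positive half-line — comfortably above the 98% design constraint.

## Parameters, units, defaults

| parameter | meaning | default | provenance |
|---|---|---|---|
| γ | follower speed | 0.1 | precursor-literature value |
| β₊, β₋ | leader speeds | 0.1, 0.1 | bias scenarios raise β₊ |
| λ₁, λ₂ | random/directed turning rates | 0.2, 0.9 (spatial runs); 0.8, 3.6 (bifurcation studies) | scenario values |
| y₀ | turning shift | 2 | chosen so f(0) ≈ 0.018 ≪ 1 |
| s_a, s_l | attraction/alignment half-ranges | 1, 0.5 | precursor-literature values |
| m_a, m_l | kernel widths | s_i/8 | 98% half-line-mass rule |
| L, n_cells | domain, grid | 40, 800 | desk-scale resolution |
| M_u, M_v | peak initial densities | 12.61 | scenario value |
| x₀ | initial pulse center | 6.5 (M1), 5 (M2/M3) | scenario values |

The source describing the original studies fixes γ, s_a, s_l, y₀, L and
the observation horizon in an appendix that is not available to us; the
defaults above are declared package choices, documented here and fully
overridable, not claimed to reproduce the original runs bit for bit. One
visible consequence: the alignment strengths at which follower equilibria
multiply depend on y₀ — with y₀ = 2 the unbiased equilibrium count goes
1 → 5 at q_l ≈ 1.89 and 5 → 3 at q_l ≈ 3.40, and the conflicting-cue
hysteresis loop lives at q_l ≳ 1.5 rather than at the q_l = 0.8 of the
original figures. The qualitative structure (count sequence {1, 3, 5},
existence of hysteresis) is what the tests assert.

The M2/M3 spatial scenarios use an observation horizon t_end = 400,
fixed once so that leaders at β = 0.1 traverse one domain length; M1
scenarios observe until the leaders have covered 100 space units
(t = 100/β), except where noted below.

## Discretization

- **Kernels**: midpoint rule at cell offsets s_j = j·dx, j = 1..J,
  truncated at s_i + 8 m_i (error of the trapezoid-type sum for a
  Gaussian is O(exp(−2π²(m_i/dx)²)): ~10⁻¹⁴ at the default dx = 0.05,
  so the discrete mass matches the erf integral to well below 10⁻⁶).
  Kernels are *not* renormalized after truncation; the discrete mass κ_l
  is used wherever ∫K_l appears, keeping discrete identities exact.
  Caution: at dx ≳ m_i (coarse grids, e.g. 64 cells on L = 40 with the
  default ranges) the quadrature overestimates κ by several percent —
  operators remain exact w.r.t. their own weights (oracle tests), but
  quantitative comparisons should use n_cells ≥ 400.
- **Nonlocal sums**: periodic index wrap (gather matrices), exactly
  translation-equivariant; a truncation reach ≥ L/2 is a configuration
  error.
- **Transport**: conservative first-order upwind per field at its own
  speed; turning exchange by explicit Euler on the pre-step state. Mass
  of each species is conserved to roundoff by construction.
- **Time step**: positivity of the update requires the *combined* bound
  dt·(v_max/dx + λ₁ + λ₂) ≤ 1, since the diagonal update coefficient is
  1 − c·dt/dx − dt·λ. The default is dt = 0.9/(v_max/dx + λ₁ + λ₂).
  (Applying CFL and rate bounds separately, which looks natural, admits
  negative densities — found the hard way.)
- **Convergence**: first order; halving dx (800 → 1600 cells) changes
  mean speed and cohesion index of a reference guided run by < 5%.

## Non-spatial analysis

Conservation (the turning exchange preserves A_u and A_v) reduces the
four-variable homogeneous system exactly to two variables (u*, v*) with
u** = A_u − u*, v** = A_v − v*. Steady states are roots of the residual
pair (h_u, h_v); stability is read from the 2×2 central-difference
Jacobian of that reduced system (step 10⁻⁶, eigenvalue real parts < 0).
In the non-spatial formulas the kernel mass is idealized to 1.

Root finding: M2's leader equation is affine in v* (closed form, unique);
follower roots by 400-bracket scanning + Brent to xtol 10⁻¹⁴. M3's
coupled pair is solved by polishing the local minima of the residual norm
on a 100×100 seed lattice with a Newton-type solver (hybr); seeds that do
not converge are dropped, never fabricated. Roots deduplicate at 10⁻⁸
and must satisfy |h| < 10⁻¹⁰. Sweeps re-seed each parameter value with
the previous value's roots so thin branches survive; `continue_branch`
does natural continuation of a single stable branch and falls to the
nearest remaining stable equilibrium when a fold is passed — running it
up then down a parameter exposes hysteresis.

## Growth probe

In place of an analytic dispersion relation, `probe_growth` seeds every
probed Fourier mode of the uniform state with amplitude ε ≤ 10⁻⁴ × the
smallest density (independent random phases per field), runs the full
nonlinear model briefly, and fits log mode-amplitude against time. Fits
stop at the first sign of saturation (amplitude > 100 ε). Rates are
ε-independent to ~2% in the linear regime; only the sign and ordering of
rates should be interpreted, not their third decimal.

## Metrics

All positional metrics work in an unwrapped frame centered on the
population's circular center of mass, so they are invariant under rigid
translation and grid rotation. Extension d = x₈₀ − x₂₀ (inter-decile,
cell-interpolated CDF); cohesion index d₀/d_end; mean speed = net
displacement rate of the mass median, tracked across snapshots by
minimal-image unwrapping (the median is used rather than the centroid
for robustness to splitting); detachment when ∫u·v dx first falls below
5% of its initial value; covered fraction = follower median displacement
over leader center displacement.

Regime labels use invented, configurable thresholds
(`RegimeThresholds`): at-rest means |speed| < 0.1 γ; dispersion means
cohesion < 0.25; "success" means positive speed and cohesion ≥ 0.75;
pulsating requires ≥ 3 alternating extension extrema of > 20% relative
amplitude *persisting into the final quarter of the record* (a settling
transient is not a pulsation). After a detachment, a sustained leftward
late-time median marks counter-directed motion; otherwise whichever
population ends up ahead distinguishes splitting-I (followers ahead)
from splitting-II (leaders ahead).

Because the domain is periodic, a prescribed M1 leader pulse laps the
domain every L/β time units and re-encounters the followers; regime
labels for the strong-attraction M1 scenario are therefore evaluated on
a horizon (t = 300) that ends before the first re-encounter. This is a
property of the periodic idealization, not of the physical system, where
leaders would simply leave.

## What the synthetic world does and does not establish

Initial conditions are Gaussian pulses with an iid-uniform (±0.05)
per-cell orientation perturbation from a seeded generator (the
correlation structure of the original perturbations is unspecified; iid
is the simplest reading). Runs are deterministic given the seed. Green
qualitative tests establish that the implemented equations reproduce the
documented regime phenomenology at the documented parameter values on
this 1-D periodic desk-scale world; they do not establish quantitative
regime boundaries (first-order scheme, unknown original discretization),
behaviour in 2-D/3-D, with repulsion, with boundaries other than
periodic, or at parameter values outside the tested neighbourhoods.

## Known limitations

- First-order upwind is diffusive; sharp fronts are smeared at coarse dx.
- The steady-state seed lattice can in principle miss roots with basins
  smaller than the lattice spacing (mitigated by sweep re-seeding).
- The growth probe measures the slowest-decaying/fastest-growing linear
  combination actually excited; degenerate modes with equal rates are
  reported as one.
- `alpha` (M1) and `alpha_plus`/`alpha_minus` (M2/M3) are distinct
  fields; M1 ignores the latter, M2/M3 ignore the former.
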
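# Methods

## The model

The vitamin C iodine clock is a substrate-depletion clock without
autocatalysis. Two effective reactions drive it. A slow oxidation of
iodide by (excess) hydrogen peroxide produces iodine,

    2A -> B,        rate k0 * a^2,

and a fast reduction by ascorbic acid sends iodine back to iodide,

    B + C -> 2A,    rate k1 * b * c,

where `a`, `b`, `c` are the molar concentrations of iodide (A), iodine
(B) and ascorbic acid (C). Because peroxide is held in great excess its
concentration is absorbed into `k0`, and the iodide oxidation is modelled
with quadratic mass-action kinetics in `a` alone. The well-mixed,
isothermal law-of-mass-action ODEs conserve the total iodine-atom
concentration `a + 2b = m0`, which reduces the system to two variables.
With `beta = b/m0`, `gamma = c/c0`, `tau = k1*c0*t`,

    dbeta/dtau  = -beta*gamma + eps*rho*(1 - 2*beta)^2,
    dgamma/dtau = -rho*beta*gamma,
    beta(0) = phi,  gamma(0) = 1,

governed by three dimensionless groups:

| group | meaning | typical value |
|---|---|---|
| `rho = m0/c0` | iodine atoms per ascorbic acid molecule | O(1) |
| `eps = k0/k1` | slow/fast rate ratio | << 1 (default 1e-3) |
| `phi = b0/m0` | fraction of iodine atoms supplied as I2 | in [0, 1/2] |

The unique equilibrium is `(beta, gamma) = (1/2, 0)`: all iodide
converted to iodine, inhibitor exhausted. Its linearization has
eigenvalue 0 along `(1, 0)` (the slow manifold `gamma = 0`) and
`-rho/2` along `(1, rho)`; the closed forms are returned directly rather
than through numeric linear algebra, since they are exact.

## Matched asymptotics

For `eps << 1` and `rho*phi < 1` the dynamics split into four regions,
glued by matching constants `c1 = 1 - rho*phi`, `c2 = 1 + 2*phi - 2/rho`,
`c3 = 0`, `c4 = 1`:

* **Region I** (`tau = O(1)`): the slow production is negligible;
  `rho*beta - gamma` is conserved and beta follows a logistic-type decay
  from `phi` towards 0 while gamma settles at `1 - rho*phi`.
* **Region II** (induction, `tau = O(1/eps)`): quasi-steady balance
  `beta*gamma = eps*rho`, with `gamma = 1 - rho*phi - rho^2*eps*tau`
  draining linearly. The solution blows up at
  `tau_sw = (1 - rho*phi)/(rho^2*eps)` — the switchover time. In
  dimensional variables `t_sw = (c0 - phi*m0)/(m0^2 * k0)`, independent
  of `k1`.
* **Region III** (corner, width `O(eps^-1/2)` around `tau_sw`): both
  variables are `O(sqrt(eps))`; the layer equation is a Riccati equation
  solved by a Gaussian over an error function.
* **Region IV** (`tau = O(1/eps)` after switchover): gamma vanishes
  beyond all algebraic orders and
  `beta = 1/2 - 1/(2*(1 + 2*[phi - 1/rho + rho*eps*tau]))` rises
  algebraically to 1/2.

Two formula-level choices deserve a note. First, the region III closed
forms are evaluated from the corner-layer derivation, in which **both**
variables carry the same Gaussian factor
`exp(-(rho*eps*tau - [1/rho - phi])^2 / (2*eps))` and the error-function
argument is that quantity over `sqrt(2*eps)`; quotations of these
formulas elsewhere sometimes drop the factor 1/2 in one exponent, which
the derivation does not support. The evaluation uses the scaled
complementary error function (`erfcx`), giving a form that neither
overflows nor hits 0/0 anywhere on the real line (a naive
`exp(-x^2)/(1 + erf(x))` underflows already for arguments around -6).
Second, region IV is the plain-reciprocal solution above: the
occasionally-seen variant with a square root in the denominator does not
satisfy `dbeta/dtau = eps*rho*(1 - 2*beta)^2` and misses the numerical
solution by an order of magnitude more.

### Accuracy against the stiff numerics

At the reference point `(rho, eps, phi) = (2, 1e-3, 0.2)` (switchover at
`tau = 150`), sup absolute errors against the numerical solution on each
region's own window are, as computed by `analysis/02_asymptotics_vs_numeric.py`:

| region | window | max error beta | max error gamma |
|---|---|---|---|
| I | `tau <= 5` | 2.9e-3 | 1.05e-2 |
| II | `10 <= tau <= 100` | 2.0e-3 | 2.7e-2 |
| III | `|tau - 150| <= 30` | 1.6e-2 | 1.3e-2 |
| IV | `tau >= 200` | 1.0e-2 | 8.6e-4 |

These magnitudes are structural, not numerical artefacts (they are
identical against an independent fixed-step RK4 integration): region I's
gamma error is the `O(eps*rho^2*tau)` induction drain its leading order
omits; region IV's gamma agreement is beyond all algebraic orders, while
its beta keeps a persistent `O(sqrt(eps))` offset inherited from the
corner-layer matching that decays only algebraically. Next-order
corrections in regions I and III are deliberately out of scope.

### Region boundaries for the piecewise composite

`composite_eval` selects region I until its solution sits within 1e-6 of
its long-time limit, region III on a band of half-width `3*sqrt(eps)/rho`
in the slow time `eps*tau` around the switchover, region II between and
region IV after. No additive (van Dyke) uniform composite is formed: the
piecewise presentation keeps each region's error structure visible.
Jumps at the seams are below `5*sqrt(eps)` at the reference point. The
degenerate case `rho*phi = 1` is rejected everywhere (a region-I
denominator vanishes); `rho*phi >= 1` is allowed for simulation — the
ODEs remain valid — but flagged as outside the asymptotic regime.

## Numerics

Integration uses the reduced two-variable system exclusively, so
`a + 2b = m0` holds exactly by construction (`a` is reconstructed as
`m0*(1 - 2*beta)`). The stiff path is `scipy.integrate.solve_ivp` with
LSODA, `rtol = 1e-8`, `atol = 1e-12` and dense output; the tight absolute
tolerance is needed because gamma must be resolved down to `O(sqrt(eps))`
in the corner. States within 10x the absolute tolerance below zero are
clipped; anything worse raises.

Switchover detection returns the first up-crossing of beta through a
threshold, refined by Brent root-finding on the dense interpolant; any
initial transient in which beta starts above the threshold is excluded by
starting the search at beta's sampled minimum. The default threshold is
`sqrt(2*eps/pi)` — the leading-order value of beta at the centre of the
corner layer — so that detection lands on the switchover itself to within
the `O(eps^-1/2)` corner width (4.96% of `tau_sw = 150` at the reference
point, 0.64% at `eps = 1e-4`). A fixed O(1) threshold such as 1/4 would
instead be crossed during the slow post-switchover relaxation (at
`tau = 900` at the reference point, six times `tau_sw`) and measures
nothing about the clock. Trajectories without a dense interpolant (e.g.
noisy synthetic samples) fall back to linear interpolation between
samples.

## Stoichiometry

Recipes are converted with: Lugol's 3% w/v carrying
`1 + 2*126.9/166 = 2.5289` g of iodine atoms per 100 ml (the
5-significant-figure rounded value is used downstream, which reproduces
the benchmark m0 column at its quoted precision); vitamin C molar mass
176.12 g/mol; reaction volume = water + stock aliquot + peroxide +
Lugol's (back-solving the benchmark m0 values confirms this convention;
145-150 ml across the table). `m0` counts iodine **atoms** (I2
contributes two), matching `m0 = a0 + 2*b0`. The quoted c0 column is
reproduced only to ~3e-4 relative — it carries rounding noise from the
stock concentration — so the packaged table ships the quoted values
verbatim rather than recomputed ones. Peroxide and starch never enter
the model (both in excess).

## Inference

`fit` minimizes the unweighted sum of squared residuals *in seconds* of
`t_sw = (c0 - phi*m0)/(m0^2 * k0)` over `(k0, phi)`, each timed repeat an
independent record. The objective is exactly linear in
`theta = (1/k0, phi/k0)`, so the global optimum is computed by linear
least squares; a Levenberg-Marquardt multistart from a coarse `(k0, phi)`
grid serves as an independent stability check feeding the `converged`
flag. `phi` is unconstrained — a slightly negative estimate is a
legitimate noise outcome — with a warning outside `[0, 1/2]`. The
condition printed in both benchmark series with identical repeat times is
treated as one physical experiment and deduplicated by default
(`deduplicate=False` keeps all 20 records); the fitted `k0` rounds to
0.57 M^-1 s^-1 either way (0.5741 vs 0.5736). `k1` is not identifiable
from switchover times (the formula contains only `k0`); dimensional
simulation therefore takes `k1` as configuration, defaulting to
`1e3 * k0` so that `eps = 1e-3`.

Choosing unweighted absolute residuals has a statistical cost the package
reports rather than hides: with multiplicative timing noise the long-time
conditions dominate the objective, and the delta-method relative standard
error of `k0` on the benchmark design at cv = 0.08 is 7.2%. The
recovered `k0` therefore falls within 10% of truth in about 84% of seeded
replicates (`analysis/05_parameter_recovery.py`), which is the intrinsic
efficiency of this estimator on this design, not an optimizer artefact;
relative-error weighting would roughly halve the SE but would no longer
be the estimator used for the headline fit.

## Synthetic data

`generate_switchover_dataset` draws
`t_obs = t_model * exp(sigma*Z - sigma^2/2)` with `sigma = noise_cv`
(mean-preserving log-normal), two repeats per condition by default, all
randomness from one seeded `numpy` Generator. The defaults encode the
bench protocol: the benchmark's nine unique `(c0, m0)` conditions, two
repeats and cv = 0.08, the scale of the printed repeat-pair spread
(observed times 20-500 s scatter proportionally to their size, which is
what the multiplicative model captures and an additive one would not).
What the generator does **not** emulate: colour-judgement and human
reaction-time components of the measurement, temperature drift between
runs, and any systematic error in the recipe volumes — so passing
recovery tests demonstrate estimator correctness under the assumed noise
law, not robustness to those effects. `generate_trajectory_dataset` adds
i.i.d. Gaussian noise to a subsampled trajectory for detector-robustness
checks, emulating a future quantitative (e.g. absorbance-based) trace.

## Problem sizes

Default runs integrate to `2*tau_sw` on 2001-point grids; the recovery
study uses 200 replicates of the 18-record design; the comparison grids
use a few hundred points per window. These sizes hold every quoted
number to three significant figures while keeping each analysis script
in seconds.

## Known limitations

* Leading order only in regions I and III; region IV's beta is accurate
  to `O(sqrt(eps))`, not beyond, for the matching reason above.
* The excess-peroxide reduction makes `k0` an effective constant at the
  peroxide concentration used; no Arrhenius/temperature dependence.
* No confidence intervals from profile likelihood; uncertainty is
  assessed by synthetic-data resampling instead.
* `detect_switchover` assumes a single induction-then-rise shape; it is
  not a general event detector.
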
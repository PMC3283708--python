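# Methods

## Model structure and assumptions

The channel is a single gating unit with one *effective* FKBP site.  Real
RyR2 tetramers carry four FKBP sites; how many must be occupied for a
functional response is unknown, so the scheme deliberately collapses
stoichiometry to single-site effective binding.  Cytosolic and luminal Ca²⁺,
phosphorylation and redox state are held implicitly constant (the activating
cytosolic Ca²⁺ is assumed fixed at its experimental 10 µM); there is no
Ca²⁺-dependence term, no subconductance state and no multi-channel coupling.

Occupancy states: `Free`, `12` (FKBP12 bound), `12*` (bound + activated
conformation), `12.6`, `12.6*`.  All transitions are mass-action; the scheme
is a tree, so its stationary law satisfies detailed balance edge-by-edge and
is written in closed form from the ratios `c12 = [FKBP12]·k1/k_m1`,
`r12 = k2/k_m2`, `c126 = [FKBP12.6]·k3/k_m3`, `r126 = k4/k_m4`.  The
open-driving fraction is `nu = x_12* + x_12.6*`.

Gating is a two-state chain C ⇌ O.  The opening-rate law ties the chain's
equilibrium to the occupancy:

* **rational law (default):** `k_O = kC·(alpha+nu)/(1−(alpha+nu))`, so
  `Po_eq = alpha + nu` exactly.  Domain: `alpha + nu < 1`.
* **linear law (sensitivity alternative):** `k_O = kC·(alpha+nu)`, so
  `Po_eq = (alpha+nu)/(1+alpha+nu)`.

The rational law is the default because it is the unique form (given the
two-state chain) under which the equilibrium open probability equals the
summed probability of the two activated states plus the spontaneous
background `alpha` — the two constraints that define the model.  The linear
law is kept selectable (`law="linear"`) for sensitivity checks.

## Default calibration

Shipped in `src/ryrgate/data/default_rates.yaml` (units: per-µM per-s for
associations, per-s otherwise):

| parameter | value | meaning |
|---|---|---|
| k1 / k_m1 | 29 / 6.11e-6 | FKBP12 on/off (bare Kd ≈ 0.21 pM; residence ~45 h) |
| k2 / k_m2 | 0.03 / 0.18 | FKBP12-branch activation (r12 = 1/6) |
| k3 / k_m3 | 3.3e5 / 4.2e-4 | FKBP12.6 on/off (bare Kd ≈ 1.3 pM) |
| k4 / k_m4 | 0.001 / 0.25 | FKBP12.6-branch activation (r126 = 0.004, near-zero efficacy) |
| kC | 480 | closing rate (≈2 ms open dwell) |
| alpha | 0.005 | spontaneous background Po |

Useful derived quantities: saturating-FKBP12 `nu = r12/(1+r12) = 1/7`
(Po ≈ 0.148); FKBP12 half-rise at `(k_m1/k1)/(1+r12) ≈ 0.1806 pM` (the bare
dissociation constant sharpened by the conformational equilibrium); at 3 µM
FKBP12 + 200 nM FKBP12.6 equilibrium Po ≈ 0.022.

## Stochastic simulation

The joint (occupancy × gate) process is sampled with the Gillespie direct
method — statistically exact.  Concentration protocols are piecewise constant
(perfect perfusion); at each segment boundary the pending waiting time is
discarded and redrawn, which is exact by memorylessness.  One master seed
spawns per-trial child seeds through `numpy.random.SeedSequence`, so every
result is bit-reproducible.

**State-wise gating.** The analytic `nu` is an ensemble probability; a single
channel is in a definite occupancy state, so the gating law is applied with
the nu-indicator of that state (1 in `12*`/`12.6*`, 0 otherwise).  Under the
rational law the indicator value 1 saturates the law (`alpha + 1 > 1`); its
well-defined limit is an always-conducting channel.  The simulator therefore
treats the activated occupancy states as conducting (they are the model's two
open states), while the background flicker chain C ⇌ O runs with
`k_O = kC·alpha/(1−alpha)`.  The resulting ensemble open fraction is
`nu + (1−nu)·alpha = alpha + nu − alpha·nu`, i.e. the analytic `alpha + nu`
up to the cross-term `alpha·nu ≤ 7.2e-4` at the default calibration — far
inside Monte-Carlo resolution at the trial counts used anywhere in the
package.  Under the linear law the activated opening rate is finite
(`kC·(1+alpha)`, per-state Po ≈ 0.5) and the state-wise simulation is *not*
ensemble-consistent with the analytic equilibrium; the linear law is for
analytic sensitivity checks only.

**Steady-state averaging.** Binding at sub-picomolar FKBP12 equilibrates on
the 10⁵–10⁶ s scale, far beyond any feasible per-trial duration.  Steady-state
quantities (dose–response points) therefore draw the initial state of each
trial from the analytic stationary law and time-average over the trial —
exact for a stationary process — with 600 s per trial and 100 trials per
point by default.  Protocol simulations (pre-/post-treatment, washout)
instead start FKBP-free with the gate closed, matching the FKBP-depleted
experimental preparation, and report Po in 10 s windows.  Trial-averaged
protocol predictions use 10 replicate channels per run: a single channel's
5–9-minute time-averaged Po still fluctuates by ±0.05–0.06 (SD) through slow
conformational toggling, and averaging a small ensemble estimates the mean
trajectory the model predicts.

Named protocols (concentrations in µM, 20 simulated minutes):
`pre_fkbp12_6` — control 2 min; +200 nM FKBP12.6; FKBP12 steps 1 nM → 200 nM
→ 1 µM.  `post_fkbp12_6` — control 2 min; +200 nM FKBP12 for 9 min; +200 nM
FKBP12.6 for the final 9 min.  Washout default: 1 µM FKBP12 for 5 min, then
zero ligand for 9 min.

## Dose–response and EC50

Curves are computed analytically (closed-form equilibrium) or by the
Monte-Carlo pipeline above.  The default grid is 13 log-spaced points; the
Monte-Carlo reproduction uses 10 points spanning 0.001–1000 pM.  EC50 comes
from a four-parameter log-logistic fit on log₁₀ concentration (floor bounded
below at 0, Hill slope free), with the half-maximum defined on the fitted
span (ceiling − floor), i.e. on the Po *increase* — concentration-response
data for these channels are conventionally baseline-subtracted because
control Po varies widely between channels.  Zero-concentration points cannot
enter a log fit and are excluded (the floor absorbs the baseline).  Flat or
sub-decade curves raise an error instead of extrapolating.

The closed-form half-rise `(k_m1/k1)/(1+k2/k_m2) ≈ 0.1806 pM` serves as the
deterministic anchor; one run of the stochastic pipeline scatters around it
with log₁₀ SD ≈ 0.065 (±16%), dominated by binomial sampling of the bound
fraction across 100 trials.  A printed model EC50 near 0.12 pM is within this
pipeline's ordinary scatter of the anchor (factor ≈ 1.5).

## Synthetic single-channel records

`synthesize_trace` renders a gating path as a two-level current (defaults:
closed 0 pA, open 30 pA — an arbitrary but realistic amplitude; no target
depends on it), low-pass filters it and adds white Gaussian baseline noise
(default SD 3 pA, SNR 10).  Defaults mirror the acquisition chain the model
is calibrated against: 20 kHz sampling, 800 Hz (−3 dB) low-pass.  The filter
is Gaussian — the conventional stand-in for an analog recording filter
specified only by its −3 dB point — with `sigma_t = sqrt(ln 2)/(2*pi*fc)`;
it preserves DC and attenuates rectangular events shorter than ≈ 0.179/fc
(0.22 ms at 800 Hz) below the 50 % level, reproducing the truncation of very
brief events seen in filtered records.  Noise is added after filtering, so
the noise floor is white; drift, capacitance transients and multi-channel
superposition are not emulated.  Passing round-trip tests on these records
shows the analysis chain is correct for two-level, stationary-noise data; it
does not certify performance against drifting baselines or subconductance
gating.

`generate_modal_path` adds slow modal switching: a hidden mode chain with
exponential dwells (default scale tens of seconds) multiplies the opening
rate, producing the 10-s-window Po fluctuations characteristic of long RyR2
records.  `generate_dwell_sample` draws directly from exponential mixtures,
optionally left-truncated (truncated components are sampled as
`cutoff + Exp(tau)` with weights `a_i·exp(−cutoff/tau_i)` — exact by
memorylessness).  Control-like mixtures are packaged: open (0.7, 2.5) ms with
areas (0.75, 0.25) (mean ≈ 1.2 ms), closed (1.2, 12, 110) ms with areas
(0.5, 0.3, 0.2) (mean ≈ 26 ms) — two open and three closed components with
the time-constant spread and means typical of control recordings.

## Idealization and dwell analysis

Idealization uses the 50 % threshold rule: threshold at the midpoint of the
closed/open levels, state by threshold side, durations resolved to the
sampling interval.  Levels come from acquisition metadata or explicit
arguments; when estimated, a two-component Gaussian mixture is fitted to the
amplitude histogram and an effectively unimodal histogram (separation
< 3 SD) is an error, not a guess.  Idealization assumes at most one channel.

Whole-record Po warns below 180 s of recording (the conventional minimum).
Windows with no event boundary inherit the spanning state.

Dwell extraction drops events shorter than 1 ms (unresolved at 800 Hz
bandwidth).  Excluded events are *omitted*, not bridged — flanking events are
left untouched — because exclusion, not concatenation, is the stated
convention; a `merge_flanking` option exists but is off by default.

Mixture fitting maximises the truncation-corrected log-likelihood: each
component density is renormalised over `[cutoff, ∞)`, which is required for
unbiased time constants when the sample is left-truncated.  Optimisation is
L-BFGS with analytic gradients over `(log tau, logit area)` (the softmax
parametrisation keeps areas on the simplex), with ≥ 8 starts from log-spaced
sample quantiles; the best converged start wins and total failure raises with
diagnostics.  The single-component case uses the closed form
`tau = mean(t) − cutoff`.  Component count: sequential likelihood-ratio test,
2·Δlog L against chi-square with 2 df per added component at p = 0.05
(stops at the first non-significant addition; the boundary-case LRT is
conservative, so spurious components are added at below the nominal rate);
BIC is available as an alternative.  A log-binned chi-square goodness-of-fit
helper (default 10 bins/decade, sparse bins merged) accompanies the fits.

## Numerical choices and degenerate inputs

* Concentrations are µM internally; `to_micromolar` converts pM/nM/etc. at
  the boundaries (CLI accepts a `--unit` flag).
* Occupancy closed form is exact (no matrix solve); the long-time integration
  of the mass-action equations exists only as an independent test oracle.
* `alpha + nu ≥ 1` under the rational law raises a domain error
  ("occupancy-driven Po saturation exceeded") rather than clamping.
* Equilibrium draws of the initial simulation state use the exact stationary
  occupancy law and the per-state stationary gate probability.
* Windowed Po discards a trailing partial window.
* All validation (probability bounds, alternating events, strictly positive
  durations, strictly increasing grids) happens at construction time of the
  result dataclasses.

## Known limitations

* The state-wise rational gating makes activated sojourns continuously
  conducting; per-event open dwell statistics under strong FKBP12 activation
  are therefore dominated by conformational dwell times (seconds), not by the
  millisecond flicker — adequate for Po and occupancy questions, coarse for
  open-time distributions under activation.
* No missed-event correction beyond truncation renormalisation; no burst
  analysis; no amplitude analysis.
* The Hill fit assumes a single sigmoid; biphasic curves are out of scope.
* Parameter estimation from experimental traces is out of scope: the default
  rate constants are a hand calibration, not a fit produced by this package.
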
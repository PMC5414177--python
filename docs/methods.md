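# Methods

## Model

A cell is described by its outer surface area `A` (μm², the standard
proxy for cell volume in the L1 layer of the shoot apical meristem), a
relative growth rate `g` (h⁻¹) fixed at birth, a division ratio `d`
(percent of the parent's area given to the first daughter) fixed at
birth, and one or two CDK activity accumulators.

Per time step `dt` (hours), in this order:

1. **Growth** — `A ← A·exp(g_eff·dt)`, the exact exponential update;
   `g_eff = g + s·(A − A_ref)` where the optional slope `s`
   (`rgr_size_slope`, default 0 h⁻¹μm⁻²) adds a weak size dependence of
   the growth rate itself.
2. **CDK accumulation** — `CDK ← CDK + r(A₀)·dt` with the rate `r`
   evaluated at the start-of-step area `A₀` (explicit Euler).
3. **Trigger** — if `CDK` *strictly* exceeds the effective threshold
   the transition fires. Ties wait one more step; this makes the
   calibrated rates land on well-defined plateaus instead of a knife
   edge.

Size feedback can be placed on the rate, `r = pCDK·(A/A_ref)^α` with
α ∈ {1, 0.67, 0.34} (activator accumulation), or on the threshold,
`T_eff = T·A_ref/A` (inhibitor dilution); the reversed forms
(`pCDK·A_ref/A`, `T·A/A_ref`) are available to show that they invert
the size/cycle-length relationship. `A_ref` (default 20 μm², the
wild-type birth size) keeps `pCDK` in a.u. h⁻¹ for every α; only the
ratio of rate to threshold is meaningful, so the threshold default
(100 a.u.; 100/200 for the two thresholds) is arbitrary and the
calibration absorbs the scale.

In the **one-transition model** the single threshold triggers mitosis.
Mitosis lasts `mitosis_steps` steps (default 1) during which growth
continues but CDK is frozen; the cell then splits into daughters of
`d%` and `(100−d)%` of its area (they sum exactly — mass conservation).
Each accumulator resets to zero at birth. In the **two-transition
model** CDK_S accumulates toward T_G1/S during G1; crossing it records
the G1/S event, resets the accumulator, and starts CDK_M toward T_G2/M,
whose crossing triggers mitosis. The reset at G1/S is required for
cyclic behaviour. Each phase has its own rate (pCDK_S, pCDK_M) and its
own flag for whether the size feedback applies, giving G1/S-only,
G2/M-only, and dual-sizer variants.

In the continuous limit the α = 1 activator sizer is an **adder**: the
area added between birth and threshold crossing is
`ΔA = g·T·A_ref/pCDK` independent of birth size, so a birth-size
deviation halves each generation (multiplier `2^{−α}` in general — the
origin of the slower convergence at α = 0.67 and 0.34). With symmetric
division the steady state doubles from `ΔA` to `2ΔA` per cycle and the
cycle length equals the doubling time `ln 2 / g`.

## Noise

`g` and `d` are drawn once per cell at birth, independently:
`g ~ Normal(g_mean, g_sd)` truncated to positive values and
`d ~ Normal(d_mean, d_sd)` truncated to [5, 95]%. Defaults for "observed
variation" runs are `g_mean = ln2/24 ≈ 0.0289 h⁻¹`, `g_sd = 0.2·g_mean`,
`d_mean = 50`, `d_sd = 5`. The division-ratio spread was chosen so the
mean share of the larger daughter is `50 + d_sd·√(2/π) ≈ 54%` of the
parent area, the level reported for tracked meristem divisions.

## Populations

Runs start from 100 asynchronous cells: progress `u ~ Uniform(0,1)`
through the cycle, area `A_ref·2^u`, and the accumulator set to `u`
times the (phase-appropriate) threshold. Cells advance in lock-step;
daughters join at division; whenever the census exceeds the cap (100)
uniformly random cells are culled back down, after all of the step's
divisions. Every completed cycle is logged (identifiers, birth/G1-S/
division times and areas); a per-timepoint series of the population
mean size is kept. Summaries exclude cycles of cells born before a
burn-in (default 72 h, three nominal cycles) to remove initialisation
transients. One integer seed drives initialisation, per-birth draws and
culling through a split `numpy` SeedSequence; identical config + seed
reproduces the lineage table bit for bit.

## Calibration

`calibrate_one_transition` holds `T` fixed and bisects on `pCDK` until
the noiseless, symmetric-division steady state (consecutive birth sizes
within a relative tolerance, default 10⁻³) divides at the 40 μm²
target; the search is seeded by the adder closed form
`pCDK = g·T·A_ref/ΔA`. `calibrate_two_transition` nests two bisections
— outer on `pCDK_S` for the G1 fraction (target 0.60), inner on
`pCDK_M` for the division size — seeded by the analogous continuous-
limit expressions; when an outer candidate makes the inner target
unreachable the inner solver returns its best-effort endpoint so the
outer loop can keep steering. A cell that fails to divide within 20
doubling times reports an infinite division size, which the searches
treat as "rate too low".

Two-transition work uses `dt = 0.1 h` rather than the 1 h default of
the one-transition model: the wild-type G1 target (60% of a 24 h cycle
= 14.4 h) does not lie on a 1 h grid, and phase lengths are quantised
to whole steps. The engine is identical at any `dt`; calibrated rates
converge to the closed forms first-order in `dt`.

## Stability classification

"Loss of cell size control" is operationalised on the population
mean-size series (which must span ≥ 10 reference cycles): the run is
LOST if the log-linear trend over the final half exceeds 5% size change
per reference cycle length, or if the mean size ever reaches 10× its
initial value; otherwise STABLE. The 5%/cycle drift threshold is this
package's choice of cut-off between re-equilibration at a new size
(e.g. larger cells after a moderate rate reduction — still homeostatic)
and unbounded drift.

## Fold scans

Starting from a calibrated wild type, one phase's production rate is
divided by each fold in a discrete grid
({1, 1.2, 1.5, 2, 2.5, 3} for pCDK_M, {1, 1.2, 1.4, 1.7, 2, 3} for
pCDK_S); each fold runs a noisy 100-cell population for 600 h (burn-in
200 h). Reported boundaries are the largest scanned fold that is STABLE
with mean cycle length within 5% of the fold-1 run, and the smallest
scanned fold classified LOST — scanned values, never interpolated. The
expected boundary is analytic: control fails once the size-blind
(timer) phase alone lasts longer than the doubling time `ln2/g`, i.e.
near fold `1/0.4 = 2.5` for pCDK_M (S-G2-M is 40% of the wild-type
cycle) and `1/0.6 ≈ 1.67` for pCDK_S; growth-rate noise erodes the
margin slightly below these limits. The discrete step provides the
G1-length floor (one `dt`) — no extra minimum-phase parameter exists.

## Lineage statistics

RGR is `(ln A₁ − ln A₀)/(t₁ − t₀)`; cycle and phase lengths are
inferred by inverting it on mean areas (birth→division, birth→G1/S,
G1/S→division). Sister pairs qualify when both daughters completed a
cycle; differences are signed larger-at-birth minus smaller; pairs
differing by more than 5 μm² at birth count as asymmetric, and pairs
dividing within one recording interval as synchronous (both
configurable). The convergence test counts asymmetric pairs closer in
size at division than at birth and evaluates the exact binomial tail
`P(X ≥ k)` under p = ½ by direct summation of the pmf.
`binomial_tail_greater(k, n, p)` itself exposes the strictly-greater
tail `P(X > k)`. On the benchmark count of 72 converging pairs out of
105, the exact strict tail is 3.904×10⁻⁵; the reported value of
3.885×10⁻⁵ for that statistic is 0.49% away and is not reproduced
exactly by any standard convention (≥-tail 8.9×10⁻⁵, two-sided
1.8×10⁻⁴), so exact computation agrees with it to two significant
figures only.

Marker-based phase calls follow the reporter logic (EdU⁻/reporter⁻ →
G1, EdU⁺/reporter⁺ → S, EdU⁻/reporter⁺ → G2-M, EdU⁺/reporter⁻ →
INCONSISTENT). Zone summaries are grouped means/sds per zone label.

## Synthetic lineage generator

The generator runs the real engine (calibrated two-transition wild type
for "sizer" dynamics; a size-blind 24 h-cycle model for "timer") over
founders spread across developmental zones with increasing growth rates
(defaults CZ 0.024, PZ 0.029, P 0.036 h⁻¹), then emulates the
measurement process: event times are snapped up to the recording grid
(default 3 h) and recorded areas get additive Gaussian noise (default
sd 6 μm², chosen by Monte-Carlo so that with the default
division-ratio spread ~60% of recorded divisions differ by more than
5 μm² at birth, matching tracked-tissue observations). The latent
dynamics are exact, so with noise 0 every table invariant holds to
machine precision and analysis-formula error can be isolated from model
error.

What the generator does **not** emulate: spatial neighbour effects and
mechanics, segmentation-error structure (noise is i.i.d. additive,
not correlated along tracks), censoring by cells leaving the field of
view, and zone reassignment as primordia grow. Tests passing on
synthetic tables therefore validate the statistics' arithmetic and
their sizer/timer discrimination, not robustness to those real-data
artefacts. Note one consequence of measurement noise: selecting pairs
on a noisy >5 μm² birth difference regresses toward the mean at
division, which adds to the genuine adder-mechanism signal in the
convergence test; the timer control table (where the true difference
doubles over the cycle) stays non-significant, so the discrimination
stands.

## Problem sizes and determinism

Default analyses use 100-cell populations, 600 h simulated (400 h after
burn-in, ≈ 1,100 completed cycles), single-lineage calibrations of a
few hundred cycles, and 100–120 synthetic sister pairs — sizes at which
every reported contrast is far from its decision boundary while a full
fold scan runs in seconds. All stochastic entry points take one integer
seed; fixture and scan seeds in the test suite are fixed.

## Limitations

- No spatial context: culling stands in for cells leaving the meristem,
  and there is no neighbour coupling or mechanical constraint.
- Euler accumulation is first-order; quantities quantised by `dt`
  (phase lengths, G1 floor) should be interpreted at the chosen grid.
- The G1/S:G2/M threshold ratio (default 1:2) is an assumption, not a
  measured value; only rate/threshold ratios matter, and the
  calibration re-solves rates for any chosen ratio.
- Mutant comparisons are directional (size up/down, phase longer/
  shorter); measured effect sizes in real genotypes are outside the
  model's reach.
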
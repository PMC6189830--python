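# Methods

## Model and assumptions

The package models a droplet-microfluidic screen in which a clonal
bacterial library is amplified in droplets, merged 1:1 with droplets of
target mammalian cells (single cells or N-cell aggregates), and sorted
on an apoptosis stain.

**Encapsulation** is Poisson with intensity λ per droplet. Occupancy is
1 − e^(−λ), the monoclonal fraction of occupied droplets is
λe^(−λ)/(1 − e^(−λ)), and `lambda_for_occupancy` inverts the occupancy
map (−ln(1 − target)). The stated design constraint is an *occupancy*
bound ("fewer than 10% of droplets occupied"), not a bound on λ; the
default design λ saturates that bound (λ = −ln 0.9 ≈ 0.1054, ~94.8%
monoclonal) and is flagged as a calibrated choice wherever it is
emitted, since the loading actually used is not recorded anywhere.

**Geometry.** Droplets are treated as perfect spheres (V = πd³/6;
1 μm³ = 1 fL, so 75 μm → 220.9 pL, 110 μm → 696.9 pL); channel
deformation is ignored. Reports round volumes to three significant
figures. Whether a quoted 700 pL cell-droplet volume refers to the
droplet before or after fusion with the 220 pL bacterial droplet is
ambiguous in this kind of protocol description; `lb_dilution` exposes
both conventions and defaults to pre-merge, under which the growth
medium is diluted (220+700)/220 ≈ 4.18-fold — consistent with the
platform's "more than 4-fold" characterization. The post-merge reading
gives 700/220 ≈ 3.18-fold and fails that characterization, which is why
pre-merge is the default.

**Readout.** Given its clone, each cell in a unit is apoptotic
independently with probability p_bg (null) or p_hit (hit), so the
apoptotic count is Binomial(N, p). The classical Poisson(N·p)
approximation is selectable (`count_model="poisson"`) because it is the
natural description at small p — at 10% background a ten-cell aggregate
averages one apoptotic cell — and is the form used for enrichment-curve
illustrations; the binomial is the exact finite-cell model and the
package default. The approximation error is negligible in the regimes
of interest (total variation < 0.01 at N=1000, p=0.001, tested).
Background apoptosis is assumed i.i.d. per cell; droplet-correlated
background (e.g. a locally toxic droplet) is not modeled.

**Sorting threshold.** "Mid-size" is mapped from geometry to count
space as T = ⌈N/2⌉ — at least half the cells apoptotic — because
large-particle sorters gate on integrated fluorescence, which scales
with the apoptotic count. An explicit integer T is accepted for
sensitivity analysis. Note an intrinsic parity effect: T jumps only at
odd N, so quantities like the fold improvement of aggregates over
single cells zigzag between adjacent even/odd sizes while growing
strictly along every N → N+2 step. The qualitative claim "larger
aggregates enrich better" is therefore asserted (and tested) per parity
class, not per unit step.

**Enrichment analytics.** With spike fraction f and per-unit sort rates
S_hit, S_null, the post-sort hit fraction is f·S_hit/(f·S_hit +
(1−f)·S_null) and fold enrichment divides by f.
`fold_improvement_vs_single(N, ...)` is that enrichment at size N and
mid-size threshold divided by its value at N = 1, T = 1; it equals 1 at
N = 1 by construction.

## Simulator

`run_screen` draws, in fixed order from one `numpy` PCG64 generator:
bacterial counts ~ Poisson(λ); clone identity (a droplet with k
founders is hit-dosed if any founder is a hit — compound delivery from
one hit clone suffices, so polyclonal droplets take the hit phenotype);
merge pairing (Bernoulli with the configured efficiency, failures
dropped); cell counts (fixed N for condensed aggregates, or
Poisson(N)); apoptotic counts ~ Binomial(n_cells, p); the sort call;
and colonies ~ Poisson(colony_recovery_rate) per assayed unit,
violacein-positive iff the clone is a hit. Identical (config, seed)
yields bit-identical event tables.

Two deliberate simplifications: (1) sampling always uses the binomial
count model even when the Poisson approximation is selected for
analytics, because untruncated Poisson draws could exceed the cell
count and violate the event invariant 0 ≤ n_apoptotic ≤ n_cells;
(2) intra-droplet bacterial growth is not simulated dynamically —
growth to saturation is treated as deterministic and absorbed into the
infection probabilities. An optional `null_survival_penalty` scales the
null-clone colony rate down to probe differential bacterial survival
during recovery; it defaults to 0 (off).

Event tables hold one row per *assayed unit* (occupied, merge-paired
droplet). Empty and unpaired droplets carry no readout and are tallied
only in the summary, whose counts satisfy n_sorted_positive +
n_sorted_negative + n_unpaired + n_empty = n_droplets; writing them as
rows would multiply table sizes ~10× at the default loading with no
information content.

## Synthetic experiments and what they do (not) show

Two named fixtures reproduce the platform's spike-in validation runs as
generative configurations:

| parameter | hela_single_cell | p19_aggregate | status |
|---|---|---|---|
| spike fraction f | 0.001 | 0.001 | printed |
| N (cells/unit) | 1 | 12 (fixed) | printed |
| p_bg | 0.0964 | 0.10 | printed (cytometry) |
| p_hit | 0.3548 | 0.90 | printed / **modeling choice** |
| threshold | 1 | 6 (mid-size) | rule as stated |
| sorter rate | — | 50 events/s | printed |
| colony rate | 0.03/unit | 0.04/unit | calibrated (300/10,000; ~20/~500) |
| n_droplets | 1.1 × 10⁶ | 3.5 × 10⁶ | calibrated to sorted counts |

The aggregate p_hit = 0.9 encodes "most cells of a hit-dosed aggregate
are affected"; no per-cell rate was measured for aggregates, so this
number is a modeling choice and every emitted fixture config lists it
(with the colony rates, droplet counts and design λ) under
`"calibrated"`. Droplet counts were chosen so the default runs land on
the reported scale of the wet experiments — ≈10,000 sorted cells and
≈500 positive-sorted aggregates — which also keeps full-scale
simulation under a few seconds.

The generator emulates the *statistical* structure of the screens:
Poisson loading, binomial readout, threshold sorting, Poisson colony
recovery. It does not emulate droplet coalescence or shrinkage,
compound leakage between droplets, infection kinetics, aggregate size
heterogeneity beyond the optional Poisson cell count, or correlated
background. Passing tests therefore validate the model's internal
consistency and its analytic limits, not the wet-lab counts themselves:
the observed 9/300 and 3/~20 colony outcomes are experimental inputs
used for inference examples, not quantities the simulator is tuned to
emit.

## Inference

All interval estimates default to the exact Clopper–Pearson
construction (`statsmodels` `proportion_confint(method="beta")`)
because every observed positive count in these screens is small (9, 3,
0); Wald/Wilson alternatives are selectable via `method=`. Two-arm
comparisons use Fisher's exact test on the 2×2 positives table — the
underlying report claims a "significant improvement" without naming a
test, so the choice is ours and is stated here. The enrichment ratio of
two arms is undefined when both arms saw zero positives (returned as
`None`) and infinite when only the reference arm did.

## Numerical choices

- Occupancy/clonality use `expm1`/`log1p` forms, stable at small λ.
- Tail probabilities P(K ≥ T) are computed as survival functions
  (`scipy.stats.binom.sf`/`poisson.sf`), never as 1 − cdf sums.
- The mid-size threshold uses integer ceiling division; ties in the
  Fisher test and interval endpoints follow the scipy/statsmodels
  conventions.
- Degenerate inputs fail fast: λ < 0, f = 0 enrichment, thresholds
  outside [1, N], zero-denominator post-sort fractions
  (`NoPositivesError`), inconsistent event rows (error names row and
  column).
- CSV event tables are UTF-8, LF, header required, integer counts,
  `True`/`False` flags; `"null"` is a clone label and is protected from
  missing-value coercion on read. Configs are versioned JSON with
  unknown keys rejected.

## Problem sizes used in the checks

The test suite runs simulator-vs-analytic agreement at 10⁶ droplets,
the fold-improvement Monte Carlo cross-check at 10⁷ draws per arm,
interval coverage at 100–1000 replicates, and replication-scaling at
100 fixed seeds × (2–4) × 10⁴ droplets; the acceptance script runs both
fixtures at their full default scales. These sizes make every
stochastic check pass or fail by a wide margin under its stated
standard-error bound while the whole suite stays fast.

## Known limitations

- Background correlation within droplets, merge volume variation, and
  sorter misclassification (gate impurity) are not modeled.
- The single-cell comparator in the fold-improvement statistic uses the
  same per-cell rates as the aggregate arm; if a published curve used
  different comparator assumptions, absolute fold values will differ
  even where the qualitative behavior matches.
- Colony recovery is memoryless (Poisson) per sorted unit; clumping or
  plating saturation would break that.
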
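# Methods

## Problem and model

Clinical laboratories need reference intervals — the central 95% range
(2.5th–97.5th percentiles) of an analyte in a healthy population — but
recruiting healthy cohorts is expensive, ethically restricted in children,
and unrepresentative of older patients. Indirect methods instead estimate the
physiological distribution from routine laboratory data, which mix
physiological and pathological results.

`ksref` models the physiological component as a *power-normal* distribution:
after a Box-Cox transform with parameter λ ∈ [0, 1],

    y = (x^λ − 1)/λ   (λ > 0),    y = ln x   (λ = 0),

the physiological results are Gaussian with parameters (μ, σ). λ = 1 is a
plain Gaussian, λ = 0 a log-normal; the family covers most right-skewed
clinical analytes. Left-skewed shapes (λ > 1 or λ < 0) are out of scope. No
assumption at all is made about the distribution of pathological results.

A truncation interval T = [t1, t2] is assumed to contain a negligible
proportion of abnormal results. The estimator minimizes, over λ, (μ, σ)
and T,

    KS = sup_{x ∈ T} |D_T(x) − F_T(x)| / √n  +  p1 + p2

where D_T is the conditional (renormalized) empirical CDF of the transformed
data inside T, F_T the conditional Gaussian CDF, and n the number of samples
inside T. Reference limits are the back-transformed μ ∓ z·σ with
z = 1.959964 (kept at full precision rather than the display value 1.96).

## Scaling of D vs F, and the penalty terms

Inside T both CDFs are conditioned on T, so the comparison is well defined
regardless of how much pathological mass lies outside. Outside T, with
q = Φ(t2) − Φ(t1) and the implied physiological fraction of the dataset
c = (n/n_total)/q, the penalties charge only model-implied impossibilities:

    p1 = max(0, sup_{x < t1} [c·Φ(x) − D(x)]) / √n
    p2 = max(0, sup_{x > t2} [D(x) − (1 − c·(1 − Φ(x)))]) / √n

i.e. the scaled physiological CDF may not exceed the observed cumulative
mass below T, and the scaled physiological survival may not exceed the
observed survival above T. Negative suprema are ignored. Pathological tail
mass is therefore penalty-free — necessary for robustness to contamination —
while a fit claiming more physiological mass than was observed is penalized.
This scaling convention is a design choice of this package (the defining
equations do not pin it down); it is validated empirically by the
recovery/robustness suites.

## Histogram representation and bin-edge evaluation

Values are rounded to a fixed decimal precision (user-supplied; the CLI
infers the maximum number of decimal digits among the first 1000 parsed
tokens, capped at 4) and histogrammed at distinct rounded values. The ECDF is
the right-continuous cumulative histogram with ties aggregated at the rounded
value.

A value rounded to k at precision h = 10^(−decimals) represents the bin
[k − h/2, k + h/2), so the ECDF at k carries the continuum mass up to the
*upper bin edge*. The Gaussian CDF is therefore evaluated at transformed
upper bin edges, and the truncation interval is anchored at the lower edge of
its first bin. This matters for coarsely reported analytes: with center
evaluation, integer-rounded γ-GT simulations (n = 25,000, no contamination)
recover an upper limit of ≈46.2 against a true 50 — a half-bin shift of the
whole fit — while edge evaluation recovers ≈49.3.

## The nested search

1. **λ** — brute-force grid: coarse 0, 0.1, …, 1.0, then a fine 0.01-step
   pass spanning one coarse step around the coarse winner. Brute force is
   used because the objective has unpredictable local minima in λ.
2. **T** — brute-force over all pairs of candidate limits. Candidates are
   distinct values whose percentile rank lies in the configured bands
   (defaults: 5th–30th for t1, 70th–95th for t2). Ranks are invariant under
   the monotone Box-Cox map, so the same sample subsets are examined at every
   λ and objective totals are comparable across λ. Sides denser than
   `max_candidates_per_side` (default 40) are thinned to evenly spaced
   quantile ranks; pairs holding fewer than `min_n_inside` (default 50)
   samples are dropped.
3. **(μ, σ)** — one Nelder-Mead fit per (λ, T) candidate, minimizing the
   penalized KS total. Start: μ0 = weighted median, σ0 = IQR/1.349 of the
   transformed values inside T; if the run ends on the iteration cap
   (default 500; convergence tolerance 1e-7 on the objective spread), one
   restart from (mean, SD) inside T is attempted. When `nm_warm_start` is on
   (default), the previous candidate's optimum is used as the start instead
   whenever it evaluates better than the robust initializer; candidates are
   visited in a fixed order, so this is deterministic. Disabling it roughly
   triples run time and changes results only within optimizer tolerance.

Ties across (λ, T) within 1e-12 of the best total prefer the wider truncation
interval (larger n), then the smaller λ. Wide-interval preference also
matters statistically: σ is only weakly identified by the renormalized
within-window comparison when T is narrow.

## Numerical implementation

The scan (≈30 λ values × up to 1600 truncation pairs × one 2-parameter
Nelder-Mead fit each) is JIT-compiled with numba. Inside the kernel the
standard normal CDF is read from a dense lookup table (2048 steps per unit on
[−10, 10], linear interpolation, absolute error < 1e-8 — an order of
magnitude below the optimizer tolerance); the publicly documented
`objective()` uses the exact `scipy.special.ndtr` and is the reference the
kernel is tested against (agreement to 1e-7 absolute; the reported objective
of a final estimate is always recomputed exactly). Degenerate configurations
(σ ≤ 0, or a truncation interval carrying Gaussian mass < 1e-6) evaluate to
+∞ so the simplex can step through them.

A fitted limit with λ·y + 1 ≤ 0 cannot be mapped back to analyte units; this
raises an error flagging an implausible fit rather than clamping.

## Bootstrap confidence intervals

Percentile bootstrap (not BCa): each replicate resamples the n_total input
values with replacement — from the raw value multiset, so rounding is
re-applied per replicate — and re-runs the complete estimation, λ grid
included. CI bounds are the ((1−level)/2, (1+level)/2) empirical percentiles
of the replicate limits (default level 0.90, 100 replicates). Replicate RNG
streams are keyed by (seed, replicate index); results are independent of
execution order and thread count. Replicates that fail to estimate are
logged and excluded; more than 20% failures abort with an error.

## Synthetic data generator

The generator emulates mixed routine-laboratory datasets for three archetypal
analytes, at the sizes and parameters of the underlying simulation design:

| analyte     | physiological distribution            | n_total | precision   |
|-------------|----------------------------------------|---------|-------------|
| hemoglobin  | Gaussian μ=14.0, σ=0.98 (12.0–16.0)    | 10,000  | 2 decimals  |
| TSH         | log-normal, 2.5th/97.5th pct 0.25–4.0  | 50,000  | 3 decimals  |
| γ-GT        | log-normal, percentiles 10–50          | 25,000  | integers    |

Component distributions may be specified by percentiles: Gaussian
μ = (p2.5 + p97.5)/2, σ = (p97.5 − p2.5)/(2·1.959964); log-normal the same
on logs. When explicit (μ, σ) are stated (hemoglobin), they take precedence
over the rounded interval. A scenario mixes in a fraction (0–30%) of
"abnormal" results from a second distribution while keeping n_total fixed;
the shipped hemoglobin grid uses an abnormal-low Gaussian with 95% interval
8.0–12.0 at fractions 0, 0.05, …, 0.30. Draws that would round nonpositive
are resampled (clipping would distort the shape near zero); more than 1000
resampling rounds for a component is an error. Per-cycle RNG streams are
keyed by (seed, cycle). The rounding precisions are our choice of realistic
reporting precision per analyte (config-overridable); they were fixed before
any acceptance measurement.

What the generator does *not* emulate: analytical measurement error and
drift, batch/instrument effects, age/sex structure, repeat measurements per
patient, and heavier-tailed or multimodal pathological mixtures. A green
simulation suite therefore establishes correct recovery under the stated
mixture model, not performance on any particular hospital's data.

Cross-cycle summaries report median limits, the 5th–95th percentile range of
per-cycle estimates (the only percentile reading of a "90% interval"
consistent with 100 cycles), and the fraction of cycles whose limits fall in
stated narrow margins.

## Known limitations

- Left-skewed analytes are outside the λ ∈ [0, 1] family; upper limits of
  right-skewed analytes are intrinsically more volatile than lower limits
  (a physiological-plus-high-abnormal mixture resembles a log-normal).
- Age- or sex-continuous reference intervals require external stratification;
  the package estimates one homogeneous population at a time.
- Run time grows with the number of distinct values and truncation
  candidates; the candidate cap (40/side) bounds it, at the cost of a
  slightly coarser T grid on very dense histograms.
- With fewer than `min_n_inside` samples in every admissible truncation
  interval (very small or very discrete datasets), estimation refuses to run.
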
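# Methods

## Conversion model

Paired measurements (xᵢ, yᵢ) of the same samples on two insulin immunoassays
are related by a monotone regression

    yᵢ = β₀ + Σⱼ βⱼ Iⱼ(xᵢ) + εᵢ,    βⱼ ≥ 0 ∀j,

where the Iⱼ form an I-spline basis on the training range of x.  An I-spline
is the running integral of an M-spline (a polynomial spline basis function
that is non-negative and integrates to one over its support); each I-spline
therefore rises monotonically from 0 at the lower boundary knot to 1 at the
upper one.  Any non-negative combination of I-splines plus a non-negative
intercept is a monotone non-decreasing, non-negative function — the two
physical constraints an inter-assay conversion must satisfy (more analyte
never reads as less, and concentrations cannot be negative).

All coefficients, intercept included, are solved in one non-negative
least-squares problem (Lawson–Hanson active set, via `scipy.optimize.nnls`)
on the design `[1 | I-spline basis]`.  Constraining the intercept to be
non-negative is a deliberate choice: it keeps the entire predicted curve
non-negative rather than only the spline part.

Each conversion direction is a separate regression.  X→Y and Y→X are fitted
independently from the same pooled data, so back-conversion does not return
exactly to the starting value; the tests bound this non-reciprocity by the
forward interval half-width on low-noise data.

### Basis defaults

- **Degree 3** M-spline pieces (cubic, so the I-splines are quartic): the
  standard choice for smooth monotone regression.
- **Boundary knots** at the minimum and maximum of the training inputs.
- **Internal knots** at the 5/25/50/75/95% quantiles of the training inputs,
  deduplicated and dropped when coincident with a boundary.  The quartile
  knots track the bulk of the data; the two tail knots are load-bearing:
  insulin concentrations are strongly right-skewed, and without a knot in
  each sparse tail a single wide polynomial piece spans it, letting curve
  error there exceed 1 µIU/mL even on noiseless data.  With the tail knots
  the noiseless recovery error of a curved truth (5 + 1.2x + 8√x, n = 500)
  stays below 0.5 µIU/mL across grid, uniform and log-normal input designs.
  Nine basis functions plus intercept still leave the smallest real
  comparison (n = 16) enough degrees of freedom (the fitter requires
  n ≥ max(8, n_basis + 2)).

### Prediction intervals

Intervals condition on the selected active set Aₓ (coefficients > 1e−10;
the intercept column is always retained in the interval design):

    ŷ(x₀) ± t(1 − α/2, ν) · σ̂ · √(1 + b₀ᵀ (XₐᵀXₐ)⁻¹ b₀),

with ν = n − (number of strictly positive coefficients, intercept included),
σ̂² = RSS/ν, and b₀ the `[1 | active basis]` row at x₀.  The lower limit is
floored at 0.  This is the classical Gaussian linear-model prediction
interval applied after model selection by the non-negativity constraints; it
ignores the selection step, so coverage is approximate near constraint
boundaries.  The calibration simulation (constant Gaussian noise,
20 × 200-train/2000-test replicates) measures pooled coverage of
94.7–95.3% at the nominal 95% across seeds, and stays within 2 percentage
points of nominal at the 50% and 80% levels.  Under strongly heteroscedastic
noise the constant-variance assumption is violated and coverage degrades
(locally too wide where noise is small, too narrow where it is large); this
is reported by the simulation tools but not asserted.

### Range gating

A model refuses inputs outside `[input_min, input_cap]` where `input_min` is
the smallest and `input_cap` the largest training input **minus one
µIU/mL** — the final spline piece near the extreme observation is supported
by almost no data and can bend sharply, so the last µIU/mL is sacrificed
rather than trusted.  Fitting errors out entirely when the cap does not
exceed the minimum ("training range too narrow").  Both ends are gated: the
spline is never evaluated outside its data, in either direction.

Chained conversion (X→Z→Y when no direct X→Y model exists) is implemented
but disabled unless explicitly requested: the reported interval comes from
the final hop only and understates the accumulated uncertainty.  No
error-propagation formula is applied, because composing prediction intervals
across separately fitted regressions has no exact closed form; the result is
flagged and a warning logged instead.  Cut-off tables are converted by
converting the cut-off value itself (point estimate of the direct model to
the reference assay), never the patient's measurement.

## Sample curation and merging

Samples containing exogenous insulin are excluded (exogenous insulin differs
from equine insulin in sequence and immunoreactivity, so those measurements
do not reflect the inter-assay relationship for endogenous hormone).
Samples with either value outside the respective assay's quantification
limits are removed; diluted samples whose values lie within limits are kept.
The shipped default assay registry leaves quantification limits unset —
vendor limits are not available in citable form, and inventing them would
silently discard data — so limit-based curation only activates with a
configured registry (the synthetic fixture configures 0.5–1500 µIU/mL).

Sources measuring the same unordered assay pair are pooled with equal weight
(no per-source weighting), orientations normalised to lexicographic pair
order, and samples sorted before fitting so source order can never affect a
fit.  Repeated measures per animal are treated as independent.  The declared
per-source sample counts can be checked against loaded data: strict mode
errors on mismatch, default mode warns.

The original visual inspection of every fit is replaced by automated
diagnostics: a monotonicity/non-negativity grid check at fit time, a
standardised-residual report flagging |z| > 4, and per-model n, r²,
input range and active-coefficient counts in the fit diagnostics table.

## Synthetic data

The real paired measurements are not deposited, so the generator emulates
them.  True curves are monotone by construction (identity, affine,
affine-plus-square-root, saturating); inputs are log-normal with median
20 µIU/mL and log-sd 0.8, clipped to [1, 300] — most mass in the
diagnostically relevant range, a tail to a few hundred µIU/mL.  Noise is
constant-sd, proportional, or mixed (default fixture regime:
σ(x) = 2 + 0.08·g(x) µIU/mL with a per-source offset sd of 3 µIU/mL
emulating inter-laboratory shifts).  Negative simulated measurements are
clipped to zero.  The registry fixture reproduces the real study layout
field-by-field — 11 sources, 13 unordered assay pairs, the exact declared
per-source sample counts, a shared truth per pair, an independent offset per
(source, pair) — and is byte-reproducible from its seed (default 20230824).

What the fixture does **not** emulate: the actual shapes of the real
inter-assay curves, real per-assay noise magnitudes, assay-specific
non-linearities near quantification limits, dilution-recovery effects, and
within-animal correlation.  Passing tests therefore demonstrate that the
machinery is correct under the stated statistical assumptions, not that any
specific real assay pair is converted accurately.

## Numerical choices

- I-splines are evaluated exactly via the tail-sum B-spline identity
  (`scipy.interpolate.BSpline.design_matrix` of degree d+1); M-splines via
  the Ramsay recursion.  Both are cross-checked against Simpson quadrature
  (1e−6) in the tests.
- Inputs outside the basis support are clamped for basis evaluation; range
  gating happens upstream in the conversion engine.
- Active-coefficient tolerance 1e−10; the Gram inverse uses a pseudo-inverse
  for robustness against collinear active columns.
- NNLS solutions are verified in tests against exhaustive active-set
  enumeration (all column subsets, ≤ 5 columns) to 1e−8.
- Degenerate inputs error early: all-identical predictor, fewer than three
  distinct inputs, n below max(8, n_basis + 2), or a cap at or below the
  minimum.
- Model bundles serialise every quantity needed for prediction (knots,
  coefficients, σ̂, ν, active indices, Gram inverse, range) as JSON;
  re-importing reproduces estimates and intervals bit-for-bit, and refitting
  identical inputs yields a byte-identical bundle (the bundle's `created`
  field defaults to null for this reason).

## Problem sizes

The shipped simulations use 20 replicates of 200 training / 2000 test pairs
for interval calibration, n ∈ {50, 200, 800} with 5 replicates for the
recovery trend, and the full 13-pair fixture (1561 samples) for end-to-end
runs; each completes in seconds on one CPU.

## Known limitations

- Intervals are conditional on the selected active set; coverage is
  approximate, and anti-conservative coverage is possible near constraint
  boundaries and under heteroscedastic noise.
- No errors-in-variables treatment: x is treated as fixed although it is
  itself a noisy measurement, so fitted curves are attenuated relative to
  the underlying structural relationship (as in any regression-based method
  comparison; Deming or Passing–Bablok address this but cannot produce the
  monotone spline form used here).
- No automatic knot selection or cross-validation beyond the stated default;
  no bootstrap or Bayesian intervals; no simultaneous bands.
- Chained conversions understate uncertainty by design and must be opted
  into.
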
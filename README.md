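# insulinconv

Convert equine blood insulin concentrations between immunoassays, with
prediction intervals and strict no-extrapolation gating.

## The problem

Blood insulin is central to diagnosing insulin dysregulation (ID) in horses
and ponies — a common endocrinopathy and the leading driver of laminitis.
The catch: chemiluminescent immunoassays (CLIA), radioimmunoassays (RIA) and
ELISAs report systematically different concentrations on the same sample, so
every diagnostic cut-off is assay-specific.  A practitioner whose laboratory
runs the Immulite 1000 cannot directly use a cut-off established on the
Mercodia equine ELISA.

`insulinconv` is for veterinary clinicians, clinical pathologists and equine
endocrinology researchers who need to move measurements — or, better,
cut-offs — from one assay's scale to another.  It fits directed conversion
models between assay pairs from paired method-comparison measurements and
converts values with honest uncertainty.

## The model

For a pair of assays X and Y, the conversion Y ≈ f(X) is estimated as

    f(x) = β₀ + Σⱼ βⱼ Iⱼ(x),      βⱼ ≥ 0 for all j (intercept included)

where Iⱼ are cubic I-splines (running integrals of M-splines, each rising
monotonically from 0 to 1 over the data range).  The coefficients are solved
jointly by non-negative least squares (Lawson–Hanson), so the fitted curve
is monotone non-decreasing and non-negative by construction — a physical
requirement for inter-assay relationships that unconstrained regression does
not guarantee.  Each direction (X→Y and Y→X) is a separate model; the two are
deliberately not exact inverses.

Converted estimates carry 95% prediction intervals,

    f(x₀) ± t(0.975, ν) · σ̂ · √(1 + b₀ᵀ(XₐᵀXₐ)⁻¹b₀),

conditioned on the selected active set.  Every model is range-gated: no
conversion below the smallest training input or above the largest training
input **minus one** (the cap keeping the spline away from its extrapolation
edge).  Out-of-range queries are refused with the permitted range, never
silently extrapolated.

The package ships registries of the 8 covered assays (4 CLIA, 3 RIA,
1 ELISA) and of the 11 data sources providing 13 assay-pair comparisons, a
published basal-insulin cut-off table, and a synthetic-data module that
emulates the full study layout (monotone truths, heteroscedastic noise,
per-source laboratory offsets) because the original paired measurements are
not publicly deposited.

## Worked example

Generate the study-shaped synthetic dataset, fit all models, and convert a
Mercodia equine ELISA (assay `G`) measurement of 45 µIU/mL:

```
$ insulinconv make-fixture --seed 20230824 --out-dir fx
wrote 18 sample files (1561 samples, 11 sources) to fx

$ insulinconv fit --data-dir fx --assays fx/assays.json --out bundle.json
wrote 26 models to bundle.json

$ insulinconv convert 45 --from G --to C --bundle bundle.json
from_assay,to_assay,input_value,estimate,pi_lower,pi_upper,level,chained,hops
G,C,45.0,31.400617013949972,21.283354584438264,41.51787944346168,0.95,False,[]
```

Reading: 45 µIU/mL measured on the Mercodia equine ELISA corresponds to an
estimated 31.4 µIU/mL on the Immulite 1000 scale for this synthetic fixture,
with a 95% prediction interval of 21.3–41.5 µIU/mL — the range expected to
contain a single new Immulite 1000 measurement of the same sample.
`insulinconv convert-all 45 --from G --bundle bundle.json` fans the value out
to every assay with a direct model (6 of the 7 others here; Immulite 2000 is
reachable only by explicitly requested chained conversion, whose interval
understates the accumulated uncertainty).

Converting a cut-off table to a common reference scale:

```
$ insulinconv convert-table src/insulinconv/data/cutoffs_basal_insulin.csv \
      --bundle bundle.json --reference G
```

keeps reference-assay rows unchanged (a 9.5 µIU/mL Mercodia cut-off stays
9.5) and annotates rows whose assay lacks a direct model to the reference.

The same functionality is available as a library; the core fitter is a
scikit-learn-style estimator:

```python
from insulinconv import MonotoneSplineRegressor
reg = MonotoneSplineRegressor().fit(x, y)       # x, y paired, in uIU/mL
est, lo, hi = reg.predict_interval(x_new)       # 95% prediction intervals
```

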
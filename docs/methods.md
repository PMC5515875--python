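# Methods

## The assay and what the package models

Wheat seedlings are germinated on well-watered soil plates, selected at a
uniform developmental stage 30 h after imbibition (coleoptile plus roots
1–3 emerged, root 1 near 10 mm), and transplanted eight per plate into
three well-watered (WW) and three water-stressed (WS) plates — 24
replicates per treatment. WS is imposed osmotically (20 % PEG-8000,
soil water potential ≈ −0.65 MPa, verified by dewpoint hygrometry; the WW
control sits near −0.02 MPa). Plates are photographed through the lid on
days 0, 1 and 2; structures are traced and exported as labelled lengths.
`rootplates` operates entirely downstream of tracing: its inputs are the
CSV exports, its outputs are compiled tables, contrasts and figures.

## Length extraction and calibration

Tracings are polylines of (x, y) node positions in image pixels
(sub-pixel reals; y grows downward). Length is the straight-segment sum —
no spline or arc smoothing, since anything beyond the traced nodes would
be unverifiable embellishment. Every plate photograph contains a 16 mm
white plastic strip; tracing it yields `mm_per_pixel = 16 / strip_pixels`,
and measuring the strip under its own calibration returns 16 mm to
floating round-off. Lengths are invariant under translation and rotation
of the node set (relative tolerance 1e-9 in tests) and monotone
non-decreasing under node appends.

## Missing-data semantics

The central bookkeeping rule distinguishes *why* a value is missing:

| situation | status | mean / n |
|---|---|---|
| usable tracing | measured | counted |
| roots 1–3/shoot with no record | occluded | excluded from both |
| late root (4–6) with no record | absent (length 0) | **counted**, as 0 |
| any structure traced with `_NA` | occluded | excluded from both |
| seedling wholly missing from an image | occluded (all structures) | excluded |

Absence is biology (the root has not emerged — a true zero that belongs in
the mean); occlusion is photography (the root exists but cannot be
measured — removing it must not bias the mean or affect any other
structure's n). A late root measured at a nonzero length that later has no
record is a consistency error, not an absence. Measured lengths that
decrease between days are flagged with a warning and kept: they reveal
tracing errors and must stay visible. Occluded values are never imputed.

The sixth root, present only in some cultivars/seedlings, is included in
plots, summaries and statistics only when strictly more than 3 of the 24
seedlings ever show one (measured or `_NA`). The threshold is
configurable; the strict inequality is deliberate. The rule is applied
uniformly — reporting statistics on a structure hidden from plots would be
misleading. For the WS-vs-WW difference table the rule passes if either
condition passes it; the model then uses the other condition's
absent-zero rows as data.

## The treatment-contrast model

Per structure, on the pooled WW+WS rows (occluded dropped, absent as 0):

    length_mm ~ condition × day        (fixed; day categorical, 3 levels)
    + (1 | plate) + (1 | seedling within plate)   (random intercepts)

Day is categorical because per-timepoint contrasts are the deliverable,
not a growth-curve slope. The seedling intercept reflects repeated
measures on the same plant; the plate intercept shared soil batches and
positions. The WS − WW contrast at day *d* is the condition main effect
plus the condition:day interaction for *d*, with standard error from the
fitted covariance.

*Degrees of freedom.* P-values use a between-within (containment)
approximation: df = (number of seedlings in the fit) − 2. On balanced
designs this equals the two-sample-t df for a between-seedling contrast
and is what a Satterthwaite approximation converges to there; it is
mildly conservative when occlusion unbalances the data. The mixed-model
machinery is statsmodels MixedLM (REML, L-BFGS); the contrast
construction, df policy and fallback ladder are this package's.

*Singular fits.* Simulated or real data can put a variance component at
zero (e.g. roots 4–5, identically 0 through day 1). A fit is singular
when it fails to converge or any variance component falls below 1e-6 ×
the residual variance; the ladder then deterministically refits without
the seedling term, then without the plate term (plain OLS). The rung used
is recorded in the results and the run log.

*Multiplicity.* No correction across structures or days by default,
matching the flat per-timepoint 0.05 cutoff the difference plots use; a
per-structure Holm option exists but is off.

## Plots

Root-plot bars are ordered anatomically — `root4, root2, root1, root3,
root5 (, root6)` downward, centered on root 1 with the first-emerging
roots 2/3 flanking it, shoot upward; the order is configurable aesthetics.
Stacked segments are differences of per-day condition means, so the stack
always sums to the day-2 mean (conservation is asserted to 1e-9).
Negative increments are rendered as hatched overlays, never dropped.
Difference-plot error bars show ± one standard error of the contrast (the
interval type is a package choice). Plot specs are pure frozen data
structures; rendering is separate, and PDFs are written without a
creation timestamp so identical specs give identical bytes.

## The synthetic experiment generator

The generator's defaults are the study conditions, not tuning knobs:
2 conditions × 3 plates × 8 seedlings, days 0/1/2 at 24 h spacing,
cultivar label "Zak".

- **Baselines (day 0, mm):** root 1 = 10 (the transplant-stage criterion),
  roots 2/3 slightly shorter (8.5, 7.5), shoot 9; roots 4–5 at 0.
- **Growth:** piecewise linear between observation days. Rates (mm/day)
  for roots 1–3 are higher over day 0→1 than day 1→2 (15/12, 13/10.5,
  12/9.5), reproducing the early growth-rate peak; shoot 7/7. A logistic
  curve was rejected: only between-timepoint rates are observable at this
  sampling, so the simplest shape consistent with them is used.
- **Emergence:** roots 4 and 5 emerge at 1.25 and 1.5 days — later than
  24 h after transplant — then grow at 8 and 6 mm/day. Root 6 appears
  with probability 0 by default (a cultivar-dependent trait).
- **Stress:** WS multiplies growth rates (never the pre-treatment
  baseline) by 0.6 for roots and 0.4 for the shoot — shoot growth is the
  more inhibited. Nominal water potentials (−0.02 / −0.65 MPa) are
  carried as metadata only; no PEG chemistry is modelled.
- **Random effects:** Gaussian plate (sd 0.3 mm) and seedling (sd 0.5 mm)
  intercepts shared across a seedling's structures — the same family the
  contrast model assumes, so recovery tests are fair. Measurement noise is
  additive Gaussian (sd 0.5 mm) truncated at 0.
- **Occlusion:** each day-1 structure is hidden with probability 0.05,
  doubled for the outward-facing roots of the edge seedlings (root 2/4 of
  position 1, root 3/5 of position 8), which are the likeliest to grow
  around the plate edge. Hidden roots 1–3/shoot are omitted from the
  file; hidden emerged late roots are written with `_NA` labels — exactly
  the convention the compile stage decodes.

Emitted file sets follow the filename grammar (one file per plate on days
0/1, one per seedling on day 2, 3+3+24 per condition) and are
byte-deterministic per seed. `emit_tracings` additionally produces
node-coordinate polylines whose calibrated lengths match the tabulated
lengths to 1e-6 mm, plus a 16 mm strip per plate, exercising the geometry
stage end to end.

What the simulator does **not** emulate: real tracing error structure
(operator bias, node-placement autocorrelation), root curvature (polylines
are synthetic two-segment paths), non-Gaussian or heteroscedastic growth
variation, germination failures, and within-day growth dynamics. Passing
tests therefore validate the bookkeeping, the statistical calibration and
the determinism of the pipeline under its own model family — not the
biology of any particular cultivar, whose true growth rates must come
from real experiments.

## Numerical and scale choices

- Test-scale calibration runs use 200 null experiments (type-I band
  [0.02, 0.09] at α = 0.05, the 99 % binomial band around 0.05) and 100
  seeded effect-recovery runs; both complete in well under a minute on one
  core.
- The day-0 contrast of identically initialised conditions is the
  built-in negative control (gray points at transplant).
- Exports are UTF-8 comma CSVs; lengths are written with six decimals.
- Degenerate inputs: empty folders, mixed condition/day merges, duplicate
  labels within a file, negative lengths, labels off the grammar, `_NA`
  on roots 1–3/shoot, and all-occluded structures are all hard errors
  naming the offending file/token; an all-occluded cell yields a missing
  mean (never 0).

## Known limitations

- The random-effects structure and df method of the original R analysis
  stack are a modelling choice here; exact p-values from any particular
  historical experiment are not a reproduction target.
- With heavy occlusion the between-within df is conservative.
- The CLI replaces the original point-and-click gadget; there is no GUI.
- Root area/diameter/hair traits and image processing itself are out of
  scope; extra exported columns (angle, diameter, …) are carried through
  but not analysed.
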
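# Methods

## Scope and model structure

`apopkpd` implements a simulation-only analysis: no parameters are estimated
from data. The shipped typical values (see
`src/apopkpd/data/default_parameters.yaml`) come from previously published
population models for each formulation:

| parameter | SC | SL | units |
|---|---|---|---|
| CL/F | 191 | 80.7 | L/h |
| V/F | 153 | 438 | L |
| ka | 14.9 | 6.58 | h⁻¹ |
| k12 / k21 | — | 0.613 / 0.0048 | h⁻¹ |
| F | 1.0 | 0.206 | — |
| ke0 | 5.36 | 5.36 | h⁻¹ |
| EC50 | 10.7 | 10.7 | ng/mL |
| B0 / Emax / g | 24.3 / 1 / 3 | same | points / — / — |
| MCIC | 3.25 | 3.25 | points |

Dose-entry convention: the amount placed in the depot (SC) or the first
transit compartment (SL) at t=0 is `dose·F` in ng, and plasma concentration
is the central amount divided by the listed apparent volume. This is the
only reading that reproduces the expected concentration scales (SC 1 mg
peak ≈ 5.2 ng/mL; SL 30 mg peak ≈ 9.2 ng/mL). Internal computation uses
hours and ng; reported times are minutes and concentrations ng/mL.

Both PK systems and the appended effect-site state form constant-coefficient
linear ODE systems, so they are propagated **exactly** with one matrix
exponential per distinct grid step — there is no integration truncation
error at the grid points. The SC plasma profile is additionally available in
closed form (Bateman equation); when `|ka − kel| < 1e-8·kel` the removable
singularity is replaced by its `ka = kel` limit `(D·F/V)·ka·t·e^(−ka·t)`
(this cannot occur at the typical values but can under sampling). Fixed-step
RK4 and closed-form convolution oracles in the test suite confirm agreement
to 1e-6 relative, and the SL system conserves mass (compartments plus an
elimination accumulator equal `dose·F`) to the same tolerance.

`effect_site_profile` also accepts an arbitrary tabulated plasma profile; it
then integrates the link equation exactly for a piecewise-linear input,
which differs from the fully coupled solution only by interpolation error
(~1e-4 of the peak on the default grid).

## Time grid and endpoint numerics

The default grid is 0–90 min at 0.25-min resolution (361 points), matching
the clinical evaluation window for on-demand therapy. Cmax/Tmax are read at
grid points (earliest argmax); threshold crossings for time-to-response and
response duration are linearly interpolated between grid points, so those
endpoints are accurate to well under the grid step (4× grid refinement moves
them by < 0.25 min). AUC and AUEC use the composite trapezoid on the grid;
for SC the closed-form integral agrees to 0.1%. AUEC is defined as the
positive integral of the score improvement, `∫(−ΔUPDRS)dt` over 0–90 min, in
points·min.

A responder is a subject whose change reaches −MCIC at least once in the
window; equivalently (by inverting the Hill function) whose peak effect-site
concentration reaches `EC50·(MCIC/(B0·Emax − MCIC))^(1/g)` ≈ 5.74 ng/mL at
the default parameters.

## Virtual population

Inter-individual variability is median-preserving lognormal,
`θ_i = θ·exp(η)`, `η ~ N(0, ln(1+cv²))` — the standard population-PK
convention; the CV of the sampled parameter then equals the requested `cv`
exactly in distribution. Draws are independent across parameters and
subjects (no correlation structure, no truncation) and reproducible from a
per-cell seed derived as a CRC32 hash of (master seed, formulation, dose,
cv), so adding cells never perturbs existing ones.

The default varied set is all PK parameters (CL/F, V/F, ka, and k12/k21 for
SL) plus the drug-sensitivity parameters ke0 and EC50. Held fixed:
bioavailability (a formulation property), Emax and g (structural constants
of the source effect model), the MCIC (a clinical definition), and the
baseline score B0 — all endpoints are changes from each subject's own
baseline, and the reference summary statistics this choice was checked
against are consistent with a fixed baseline. The set is configurable
(`IivSpec.varied_parameters`).

One subtlety found by property testing: at 45% CV a sampled subject can (at
~1e-6 probability) realize an effect model whose maximum attainable change
`B0·Emax` falls below the MCIC. Such a subject is a valid guaranteed
non-responder; only a *typical* vector with that property is rejected.

## Summary conventions

Per cell (formulation × dose × CV), 500 subjects by default. Exposure
endpoints (AUC0-90, Cmax, Tmax) are summarized mean ± SD over **all**
subjects. Response endpoints (time to response, duration, AUEC, maximal
change, its time) are summarized over **responders only**: time-to-response
is undefined for non-responders, and the conditional convention is the one
the published response summaries for these formulations follow — it is what
reconciles low-dose cells, where the typical subject does not respond at
all, with their distinctly non-trivial published mean responses. The
responder fraction is reported on every summary row and the per-subject
tables (duration 0, time-to-response empty for non-responders) allow any
other convention to be recomputed. Mean profiles are pointwise means across
subjects; the typical-subject profile is emitted alongside, since the two
differ (mean of per-subject maxima ≥ maximum of the mean profile).

## What the generator does and does not emulate

The virtual population emulates between-subject parameter variability only.
It does not include residual (within-subject/assay) error, parameter
correlations, covariate effects, dropout, or placebo response; profiles are
smooth model curves. Passing tests therefore demonstrate correctness of the
simulation machinery and of the stated population assumptions — not
predictive accuracy for any real trial.

## Known limitations

- **SL dose linearity.** The SL model is linear in dose, while the product
  is known to show less-than-proportional exposure at higher doses; SL
  results are therefore a best case for that formulation at 40–50 mg.
- **SL exposure scale.** With the tabulated SL bioavailability (20.6%), the
  simulated SL concentrations run ~7–8% above the published mean exposure
  summaries for these scenarios; the published values are consistent with
  the ~17–18% effective bioavailability described for the product. The
  shipped defaults keep the tabulated value, and the acceptance tests that
  compare SL exposure-driven means to published values document the residual
  gap rather than adjusting parameters to close it.
- Single-dose only (no 2-h redosing), no safety/tolerability modelling, no
  between-formulation statistical testing — the outputs are descriptive
  summaries.
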
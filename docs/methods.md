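# Methods

## Problem setting

Enzyme yield from a submerged fermentation depends on several interacting
factors (temperature, pH, agitation, carbon source, nitrogen source,
phosphate).  The workflow implemented here treats the yield surface as an
unknown smooth function over a six-dimensional box, samples it with a
central composite design (CCD), fits a small feed-forward network as a
surrogate, and optimizes the surrogate with a genetic algorithm (GA).  The
package deliberately separates those stages behind typed interfaces
(`DesignTable`, `SurrogateModel`, `OptimizationResult`) so each can be
validated on its own.

## Design construction

A CCD over k factors combines a two-level factorial core, 2k axial points
at coded distance ±α, and replicated center points.  Factor bounds are
interpreted as the *axial* levels, so natural units follow
`natural = center + coded · (high − low)/(2α)`.  For the packaged six-factor
design, α = 2 and the core is the half fraction 2^(6−1) with defining
relation I = ABCDEF — the highest-resolution (VI) choice, and the one whose
sign pattern matches the packaged 50-run dataset row for row (the last
factor's column equals the product of the other five).  Run order is
factorial block in standard order (first factor slowest), then axial pairs
in factor order (low before high), then center replicates.  The K₂HPO₄
bounds (0.5–1.5 g/100 mL) are taken from the design's own axial runs.

## Scaling

Inputs and output are mapped to [−1, 1] by per-variable min–max scaling,
`y = 2(x − min)/(max − min) − 1`.  Scalers are fitted on the training rows
only and applied unchanged to test rows and to optimizer queries, so
held-out metrics are leakage-free.  Points outside the fitted range (e.g.
GA proposals beyond the training span) extrapolate linearly.

## Network and training

The surrogate is a single-hidden-layer perceptron, 6-h-1, with tansig
(≡ tanh) hidden units and a linear output.  Training minimizes the
full-batch sum of squared errors by Levenberg–Marquardt: solve
`(JᵀJ + λI)δ = −Jᵀr` with the analytic Jacobian, accept a step only if it
reduces the SSE, multiply λ by 10 on rejection and divide by 10 on
acceptance (λ₀ = 10⁻³, λ capped at 10¹²).  Stopping: 1000 accepted epochs
(the study's setting), SSE < 10⁻¹², or gradient max-norm < 10⁻¹⁰.  Initial
weights and biases are i.i.d. uniform on [−0.5, 0.5]; because a single run
is a lottery over local minima, training restarts from 10 seeded
initializations and keeps the lowest-SSE fit.  A finite-difference Jacobian
exists only as a test oracle.

With 81 free parameters against 40 training rows the fit is
over-parameterized by design: on the packaged data every restart reaches the
same SSE floor, which equals the spread of the replicated center
observations about their mean (no function can fit different observations
at the same input).  Training R² is therefore capped at ≈ 0.99949 on these
data, and the fitted surface should be read as an interpolant of the
design's distinct points, not as a generalizing model.

Hidden width can be swept over 3–18 with identical configs and restart
seeds per size; the winner has the lowest held-out RMSE, ties broken by
lower MAPE, then fewer neurons.  The packaged default (10 hidden units) is
the width the original study selected; we keep the fixed 40/10 split for the
sweep rather than k-fold cross-validation.

## Error metrics

MSE, RMSE, MAE and MAPE are the standard definitions with MAPE kept as a
fraction (no ×100).  R² is reported two ways: squared Pearson correlation
(the headline, matching calibration-plot practice) and residual-based
1 − SSE/SST.  MAPE is flagged undefined when an observation is zero; the
other metrics are still computed.  Metrics are emitted on both the scaled
and the natural (U/mL) scale, since the scale used for a given published
error figure is often ambiguous.

## Genetic algorithm

Candidates are 36-bit chromosomes, six bits per factor, MSB first, decoded
linearly onto each factor's [low, high] — the search can therefore never
propose conditions outside the experimental box, on a 64-point lattice per
factor.  Fitness is the surrogate's inverse-scaled prediction (U/mL); by
construction it is exactly the network forward pass written out in terms of
the weight matrices, and a test enforces that identity to 10⁻¹².  Defaults
follow the study: population 36, crossover 0.8 (single point), per-bit
mutation 0.01, 500 generations.  Selection is roulette on min-shifted
fitness (uniform when all fitnesses tie), with one elite copied unchanged,
which makes the best-ever trace non-decreasing.  The reported shortlist is
the top-k (default 4) distinct decoded conditions over the archive of every
evaluated individual.  Encoding choices (plain binary rather than Gray,
roulette rather than tournament) are the simplest scheme consistent with a
36-bit chromosome over six factors.

## Interaction surfaces

A surface evaluates the surrogate on an equally spaced grid (default 25×25)
over two factors' full ranges with the remaining factors fixed at their
center settings — the response-surface convention.  Six conventional pairs
are exported by default; all 15 are available.

## Synthetic ground truth

`SyntheticSurfaceSpec` defines a concave quadratic in coded units,
`f(x) = peak + Σ cᵢ(xᵢ−oᵢ)² + Σ_{i<j} B_ij(xᵢ−oᵢ)(xⱼ−oⱼ)`, observed with
additive homoscedastic Gaussian noise (negative draws floored at zero with
a warning).  Defaults: optimum at the design center (a CCD is normally
centered on the experimenter's best prior guess), curvature −0.5 per coded
unit² (comparable to the axial-run drop-off seen in the real data), peak
7.5 U/mL, noise 0.2 U/mL.  This emulates the smooth single-optimum premise
of the analysis; it does not emulate heteroscedastic assay error, batch
effects, or non-quadratic ridges, so passing recovery tests show the
pipeline can find a well-behaved interior optimum — not that the real
fermentation surface is quadratic.

### Optimum-recovery studies and the extrapolation caveat

End-to-end recovery tests simulate a 50-run CCD from a known truth
(noise 0.1 U/mL, peak 10 U/mL), run the full pipeline, and require the GA
optimum to land within 0.5 coded units of the truth per factor (median over
5 seeds).  Two findings shaped the design here:

* A near-interpolating 6-10-1 fit constrains the response only near the
  sampled points.  The corners of the factor box (|coded| = 2 in every
  factor) are far outside the CCD's sampled region, and tanh interpolants
  frequently develop spurious corner peaks that a box-wide GA will find.
  An independent fitter (scikit-learn's MLPRegressor, tanh/LBFGS) shows the
  same pathology at the same training error, so it is intrinsic to
  unregularized least-squares fitting of this design, not an artifact of
  the LM implementation.  Practitioners should treat GA optima that sit on
  box edges far from sampled runs with suspicion.
* Holding out design runs makes this materially worse: each axial run is
  the only sample along its half-axis, so a held-out axial run leaves an
  entire direction unconstrained.  The recovery studies therefore train on
  the complete 50-run design — nothing needs to be held out when the truth
  is known — and with all axial directions pinned the pipeline recovers the
  optimum to ≤ 0.2 coded units (median) and the peak to well within 5%.
  The 40/10 split is retained wherever the packaged dataset is analyzed,
  since it is part of that dataset's published structure.

## Pipeline and reproducibility

`run_pipeline` chains the stages and derives independent training and GA
sub-seeds from one master seed via numpy's `SeedSequence`; identical
configurations produce identical reports.  The headline `improvement_percent`
is `100·(best_predicted − best_observed)/best_observed` and is always
recomputable from fields present in the report.

## Known limitations

* The surrogate is trusted over the whole box by the GA, but is only
  supported near the design points (see above); no uncertainty estimate or
  trust region is attached to predictions.
* MAPE and Pearson-R² are undefined for zero observations and constant
  vectors respectively; they are flagged rather than silently imputed.
* The GA's 6-bit lattice limits resolution to 1/63 of each factor range;
  results are reported on that lattice, not refined by local search.
* Published error metrics for this kind of study are often not
  reproducible from printed tables at printed precision; this package
  recomputes all metrics from data it can see and reports both scales
  rather than matching any particular printed value.
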
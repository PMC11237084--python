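# Methods

This note documents the models, estimators and numerical choices behind the
package, what the synthetic-data generator does and does not emulate, and the
known limitations.

## Signal model and trace processing

A raw fluorescence trace is modelled as
`f(t) = F0 · (1 + drift(t) + s(t) + ε(t))`, where `s(t)` is a sum of transient
kernels, `drift` a slow multiplicative baseline wander, and `ε` white Gaussian
noise. Processing follows standard two-photon practice:

* **Low-pass filter.** Zero-phase (forward–backward) 4th-order Butterworth,
  10 Hz for calcium at 40 Hz sampling, 40 Hz for glutamate at 120/200 Hz.
  Filtering twice squares the magnitude response and would pull the −3 dB
  point of a filter designed at f_c down to ≈ 0.90 f_c, so the design cutoff
  is pre-warped numerically (scalar root-find on the digital response) until
  the *net* zero-phase response has half power exactly at the nominal cutoff.
  Zero-phase filtering is used so event peak times, which feed rates and AUC
  windows, are not delayed. Cutoffs at or above Nyquist are rejected rather
  than clamped.
* **df/f normalization.** `df/f = (f − f0)/f0` with f₀ > 0 enforced. For
  calcium, f₀ is the 10th percentile of the entire trace; percentiles
  throughout the package use the *linearly interpolated inverted CDF* rule
  (`numpy` method `interpolated_inverted_cdf`), under which a sample whose
  lowest 10% of values are tied at x has exactly f₀ = x. For glutamate, f₀ is
  the mean of a pre-stimulus window (default 0.5 s ending at stimulus onset;
  the window length is a package choice, exposed in the API).
* **Time-dependent baseline.** Centred running 10th percentile (default
  window 30 s), evaluated on a 0.25 s grid and interpolated, then low-pass
  smoothed at 0.1 Hz. A centred running percentile lags a moving signal by
  ≈ (0.5 − q)·window·slope, so it tracks drifts that are slow relative to the
  window (relative RMS error < 10% requires drift period ≳ 25× the window);
  faster drift is attenuated but not removed. If the window exceeds the trace
  the global percentile is used and a warning is logged.

## Transient detection

The acceptance rule is the field's threshold criterion: a fluorescence change
is a transient iff its **peak amplitude strictly exceeds 3× the baseline
noise SD**. The implementation keeps that amplitude boundary exact while
rejecting the two dominant false-positive classes of threshold detectors:

1. **Noise floor.** Default estimator `residual-mad`: the trace is reduced to
   its residual about a 0.5 s running median and the SD is 1.4826× the median
   absolute deviation of that residual. Plain full-trace MAD (also available,
   estimator `mad`) is robust to sparse events but saturates once transients
   occupy the majority of samples — with a 0.5 s decay this happens at
   hyperactive rates (≥ 20/min), where plain MAD over-estimates the floor
   3–4× and detection collapses. The residual estimator stays within a few
   percent of the true filtered-noise SD at all simulated rates. A
   `quiet-window` plain-SD estimator over a user-marked event-free interval
   is also provided, and an explicit `baseline_sd` override exists for
   noise-free synthetic traces (where every estimator returns 0).
2. **Segmentation.** Candidate events are contiguous segments of the
   baseline-subtracted, median-re-centred signal above 3×SD; segments closer
   than `min_event_separation` (0.2 s) merge. The median re-centring matters:
   a 10th-percentile baseline sits ≈ 1.28σ below the noise centre by
   construction, which would silently lower the effective threshold to
   ≈ 1.7σ.
3. **Peak splitting.** Within segments, events are the local maxima of the
   full signal with height ≥ 3×SD, prominence ≥ 1.5×SD and separation ≥
   `min_event_separation` (prominence is measured on the full trace, not the
   segment, so a segment edge cannot truncate it).
4. **False-positive rejection, boundary-preserving.** Two criteria that are
   vacuous for an isolated transient rising from baseline — and therefore do
   not move the 3×SD amplitude boundary — but remove noise artifacts:
   a *sustained-excursion* test (the surrounding excursion above half the
   threshold must last ≥ 0.2 s for calcium / 0.05 s for glutamate; a noise
   spike grazing 3σ drops back within a few samples, a 0.5 s-decay transient
   does not) and a *local-upstroke* test (the peak must stand ≥ 3×SD above
   the median of the preceding 0.25 s; a ripple riding the decay shoulder of
   an earlier event measures against the elevated shoulder and fails).

On simulated 40 Hz traces at peak SNR ≈ 10 the detector achieves one-to-one
matched F1 ≈ 0.95–0.98 for rates between 10 and 40 transients/min, with
precision ≈ 0.99. The remaining losses are events closer than the 0.2 s
separation, which merge: peak-based detection at 40 Hz cannot resolve two
kernels whose summed signal has no interior minimum, and deconvolution is
out of scope. This produces a systematic rate undercount growing with rate
(≈ 3% at 10/min, ≈ 9% at 30/min under the default kinetics) — unbiased rate
recovery within Monte-Carlo error holds at low rates, while at hyperactive
rates recovered rates are conservative. Group contrasts are unaffected in
direction.

Rates are `60 × count / duration` (per condition epoch in sessions). AUC is
the trapezoidal integral of the baseline-subtracted df/f over 40 s (calcium)
or 0.5 s post-stimulus (glutamate); a window extending past the trace raises
an explicit error.

## Population statistics

A neuron is hyperactive iff its rate is strictly greater than 20
transients/min. Fractions are percentages of neurons per subject and
condition; cumulative distributions are right-continuous ECDFs. Condition
effects are expressed per subject as 100 × mean rate in condition / mean
baseline rate. Tests are all two-sided: Wilcoxon signed-rank for paired
designs (exact null for n ≤ 25 without ties or zero differences, normal
approximation with mid-ranks otherwise, noted on the result), rank-sum for
unpaired, Kruskal–Wallis for ≥ 3 groups with Dunn's pairwise z-tests under
Šidák correction (`p_adj = 1 − (1 − p)^m`, tie-corrected rank variance), and
two-sample KS for distribution contrasts. Dunn's test is implemented here
from the standard formula because no installed package provides it.

## Dose–response

Single-site occupancy with Hill coefficient fixed at 1:
`response(c) = floor + (1 − floor)·IC50/(IC50 + c)`, strictly decreasing and
scale-equivariant. Fitting minimizes Σ ((y − model)/SEM)², with IC50
parameterized on log₁₀ scale and multi-started on an 8-point geometric grid
over the dose range (sparse designs have local minima). The floor can be
fixed (0 for pure occupancy) or free in [0, 1); both fits are reported by the
analysis driver since the choice is not determined by the data model.
Designs with < 4 distinct doses or spanning < 2 decades are fit but flagged
wide-confidence. Solver tolerances are tightened to 1e−12 so reported
invariances (dose reordering, uniform SEM rescaling) hold to ≈ 1e−6.

## Biophysics

* **SEC.** K_av = (Ve − V0)/(Vt − V0), with a numerical tolerance of 1e−9
  column volumes at the void so peaks picked exactly at V0 do not raise.
  Calibration is the least-squares line log₁₀(mass/kDa) vs K_av — the
  standard SEC working model; the slope must be negative. Apparent masses
  outside the standards' K_av range are flagged extrapolated. Peak picking
  takes the maximum of a Gaussian-smoothed signal within an optional window.
* **SPR.** Langmuir 1:1: association `R(t) = Req(1 − e^{−(k_on C + k_off)t})`
  with `Req = Rmax·C/(C + K_D)`, dissociation first-order in k_off. Global
  fitting shares k_on, k_off, Rmax across a concentration series (rates on
  log scale for positivity); a single concentration cannot separate k_on from
  Rmax and raises an identifiability error. K_D = k_off/k_on exactly, by
  construction of the fit object.
* **ThT.** Normalization maps f(0) to 0 and the aggregation asymptote to
  100%; the asymptote defaults to the mean of the final 10% of samples and
  can be supplied externally (used to express scavenger curves as % of the
  free-aggregation plateau). A plateau warning is raised only when the final
  segment's trend is both material (> 2% of span over the record) and
  statistically resolvable (> 2 SE of the fitted slope), so assay-level noise
  does not trigger it.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical shape* of the experiments: Poisson
transient times (homogeneous per condition epoch, thinned so no two events
fall within one kernel rise time), a hyperactive minority (binomial
assignment, default 12%, rate 30/min vs 3/min), multiplicative condition
effects scoped to all neurons or to hyperactive neurons only, linear-rise /
exponential-decay kernels (50 ms / 500 ms calcium, ~5 ms / 100 ms glutamate,
0.4 df/f amplitude — indicator-literature regimes, not measured values),
sinusoidal drift (default 5% df/f, 60 s period), additive Gaussian noise
(default 4% df/f), movies whose ROI pixel means equal the neuron traces
exactly in the noise-free case (Poisson photon noise optional), 20 ms
inter-pulse stimulus trains with an optional supralinear disease gain for
trains of ≥ 5 pulses, mass-law titrations, closed-form Langmuir sensorgrams,
Gaussian elution peaks on a declining baseline, and logistic ThT curves whose
plateau collapses under stoichiometric scavenger co-incubation but is
untouched by late addition.

It does **not** emulate biophysical spike-to-calcium transduction, indicator
saturation or buffering, optics or point-spread functions, motion artifacts,
neuropil contamination, astrocyte signals, or heterogeneous per-neuron kernel
kinetics. Passing tests therefore demonstrate that the *quantification* is
correct under the stated statistical model, not that the pipeline is robust
to every pathology of real recordings.

Determinism: every generator is a pure function of (config, seed); identical
inputs give bitwise-identical outputs.

## Problem sizes

Test and analysis problem sizes are chosen for desk-scale reproducibility:
cohorts of 6–8 subjects with 12–16 neurons over three 60 s epochs, 50-odd
traces for detection-performance estimates, 200–500 seeds for moment
oracles, 2000 simulations for the type-I calibration (paired n = 14, where
the exact test's attainable level is 0.0494). These match the magnitudes of
the emulated experiments (6–13 subjects or slices per arm).

## Known limitations

* Rate undercount at high rates from the 0.2 s event-separation resolution
  (see above); quantified, conservative, direction-preserving.
* The running-percentile baseline is a documented stand-in for the original
  (unpublished) drift-correction of the source pipeline, and only tracks
  drifts slow relative to its window.
* The glutamate pre-stimulus window length (0.5 s) and the detector's
  duration/upstroke windows are package choices; all are config-exposed.
* The dose–response floor convention (fixed vs free) changes IC50 on real,
  noisy data; both are reported.
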
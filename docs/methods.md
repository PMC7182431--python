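# Methods

## Calcium-imaging classification

Traces are 340/380 nm excitation-ratio time series sampled nominally at 1 Hz;
all windows are defined in seconds and resolved against timestamps, so
irregular sampling is tolerated. The analysis baseline is the first 45 s of
the recording (the acquisition protocol holds the bath at room temperature
slightly longer, 50 s; both windows are configurable and kept distinct on
purpose). Thresholds are inclusive exactly as printed: baseline mean ≤ 0.7,
baseline SD ≤ 0.05, recovery |pre-High-K⁺ mean − baseline mean| ≤ 0.5,
High-K⁺ amplitude ≥ 0.5, classification amplitude ≥ 0.575 (all in
fluorescence-ratio units). All four QC criteria are always evaluated and
every violation reported, so simulated single-criterion failures are
attributable. The recovery criterion uses the absolute difference: drift in
either direction equally disqualifies a cell.

Percentages of sensitive cells use QC-passing cells as the denominator, per
coverslip; coverslips with zero passing cells yield NaN with a warning and
are dropped from group statistics. Collection-target selection ranks passing
cells by response amplitude and takes floor(0.07 n) from the top and
floor(0.14 n) from the bottom, each at least 1, disjoint, with stable
tie-breaking by input order; n < 8 triggers a warning rather than an error.
The same amplitude threshold is applied to cooling and warming ramps.

The response window closes 10 s after ramp end (inclusive), accommodating
delayed peaks; the window-boundary behaviour is pinned by test.

## Channel thermodynamics

`arrhenius_transform` converts °C to Kelvin only at this boundary, requires
uniform current sign (instructing baseline subtraction otherwise), and bins
points onto a 0.5 °C grid by median so that dwell-time imbalance along the
ramp does not weight the fit. `fit_threshold` fits a continuous two-segment
line on (1/T_K, ln I) axes: a 0.1 °C grid search over interior candidate
breakpoints (1 °C edge margins) followed by bounded scalar polishing of the
best candidate. The segmented model is accepted only when its F-ratio over a
single straight line exceeds 4 (configurable); otherwise the trace is
reported monophasic with a single Q10 — data already fit perfectly by one
line short-circuit to monophasic.

The slope-to-Q10 conversion is Q10 = exp(slope · (1/T_K(T_ref−10) −
1/T_K(T_ref))), referenced at the segment midpoint and oriented so Q10 > 1
means the current grows on cooling. Because an exact Arrhenius segment has
constant activation enthalpy, not constant fold-per-10°, the realized
10-degree fold drifts a few percent with position inside a segment; the
midpoint convention makes the generator/analyzer round trip exact and is
pinned by test.

Fold activation is I_cold/I_warm at matched voltage (default comparison
22 °C vs 12 °C), with optional subtraction of matched no-ligand leak traces;
a warm current below resolution flags the fold undefined rather than
reporting a spurious ratio. Ramp currents at a requested voltage are linearly
interpolated. Maximum drug inhibition is measured on a gap-free annotated
trace as 100·(d_peak_cold − d_min_drug)/d_peak_cold, where d is the absolute
deviation from the pre-cold baseline mean; this uses the pre-cold current as
the reference (one defensible reading — the reference is not uniquely
determined by the figure legends), and values are clamped to [0, 100] with an
out-of-range flag.

## Hill fitting

The modified Hill equation I = I_min + (I_max − I_min)/(1 + (EC50/[cGMP])^H)
is fitted per patch by bounded least squares (I_min ≥ 0, free by default with
an option to pin at 0) with a deterministic multi-start: EC50 seeded at the
geometric mean of the concentrations and at the concentration nearest the
half-maximal response, H at 1 and 2; the best residual wins. Convergence is
honest: flat series and fits whose EC50 leaves the tested concentration range
are flagged non-converged instead of extrapolated. Normalization divides a
patch's paired series by its fitted warm I_max, leaving EC50 and H invariant
(tested). Saturating cGMP is ≥ 100 µM. Group summaries keep patches paired —
fits are never pooled across patches — and delegate to the stats layer
(paired t within species, non-paired tests across species).

## Statistics

Normality gate: Shapiro-Wilk for n < 50, Lilliefors-corrected KS otherwise;
"normal" requires every group's p > 0.05; constant samples are treated as
non-normal. Routing: normal two-group → Welch's t (or paired t); non-normal →
Mann-Whitney. All tests are two-sided. Mann-Whitney is exact for
min(n) ≤ 8 — scipy's exact distribution when the pooled sample is tie-free,
full mid-rank permutation enumeration otherwise — and a tie-corrected normal
approximation above that; the exact path is verified against an independent
brute-force enumeration. Paired t on zero-variance differences reports p = 1
with a degeneracy note rather than NaN. Dunnett's many-to-one comparison uses
the equicorrelated multivariate-t distribution (scipy) and is verified
against published two-sided 5% critical values (2.3987 at k = 2, df = 18;
2.5398 at k = 3, df = 20) to within 0.005 in adjusted p. Significance labels
follow the printed convention: ns (p > 0.05), * (p < 0.05), ** (p < 0.01),
*** (p < 0.001). Summaries are mean ± SEM (sample SD/√n; a single value
reports SEM 0 with a flag).

## Synthetic-data generators

**What they emulate.** Coverslip populations with a specified
cold/warm-responsive fraction, baseline level/noise distributions, High-K⁺
responses in every healthy cell, and a fraction of cells that each violate
exactly one QC criterion by a ≥ 20% margin (so per-criterion rejection is
attributable); biphasic temperature dependence of channel current with
specified threshold and segmental Q10s; Hill-type cGMP gating with
temperature-dependent EC50 and I_max plus per-patch variability. All
randomness flows from one named generator per call, so identical inputs are
byte-identical.

**Study conditions (defaults).** Mouse-like imaging populations: 10%
responsive, responder amplitudes 1.2 ± 0.15 FR (well above the 0.575
threshold), non-responders 0.10 ± 0.05, baseline 0.45 ± 0.05 with 0.01 FR
sampling noise, High-K⁺ amplitudes 1.5 ± 0.25 (floored at 0.65 for healthy
cells so QC failures remain attributable to the injected mode). Responder
and QC-failure counts use round-half-to-even of fraction × n; failing cells
are drawn uniformly across responders and non-responders so exclusion is
independent of class. The response waveform is a half-Gaussian rise (σ = 6 s)
peaking 5–10 s after the ramp midpoint with exponential recovery (τ = 18 s) —
response kinetics are not constrained by the imaging protocol beyond the
existence of delayed peaks, so these are chosen as typical of somatic
calcium transients at 1 Hz sampling. Channel model: EC50 21.8 µM (22 °C) →
3.5 µM (12 °C), H = 2 (unreported experimentally; treated as a nuisance
parameter in recovery tests), I_max cold fraction 0.75, threshold 22.4 °C,
Q10 6.5 below / 1.3 above threshold. Protocols: ~24 °C baseline for 50 s,
30 s cooling reaching ~10 °C (or warming to 48 °C), terminal High-K⁺ epoch;
broad 37 → 10 °C ramps for thermodynamics; 22/12/22 °C steps for paired
measurements. Recording noise defaults: 0.5 pA-scale current noise on nA
currents for ramp recordings, 1% of I_max for concentration-response points;
patch-to-patch CV 0.25–0.5.

**Thermal-gain model.** The temperature dependence of the simulated current
is log-linear in inverse absolute temperature within each segment (true
Arrhenius segments, continuous at the breakpoint), with slopes anchored so
the midpoint-referenced Q10 equals the requested value exactly. A
constant-fold-per-degree (log-linear in T) alternative was considered and
rejected: it is not self-consistent with Arrhenius-axis segment fitting — the
recovered Q10 would be biased by ~7% at Q10 6.5 purely by construction —
whereas the Arrhenius form makes the noiseless generator/analyzer loop exact.
Ligand dependence enters through the Hill equation at the reference
concentration; the implied EC50(T) is recovered in ground truth by exact
Hill inversion.

**Per-patch structure.** Each simulated patch draws two lognormal factors of
CV `patch_cv`, both shared by its two temperatures: an amplitude scale on
I_max and a ligand-sensitivity factor multiplying both EC50s. Sharing the
sensitivity factor preserves each patch's cold/warm EC50 ratio exactly,
which is what makes small paired changes detectable at n = 4.

**What passing tests do and do not show.** The generators reproduce the
statistical structure the analysis assumes — they do not model photobleaching
or focus drift in imaging, thermistor lag between bath and membrane
temperature, series-resistance or capacitance artifacts, channel rundown, or
temperature-dependent Hill slope. Because the per-patch sensitivity factor
cancels exactly in the paired design, the synthetic paired test is more
powerful than real paired recordings, where temperature-independent
measurement error does not cancel: closed-loop detection rates are an upper
bound on real-data power, and even modest generative EC50 shifts (e.g. the
squirrel-like 26.4 → 20.4 µM setting) reach significance here although the
corresponding experimental contrast does not. Classification recovery under
well-separated amplitude distributions says nothing about borderline cells
near the 0.575 threshold in real data.

## Problem sizes and numerics

Validation runs use desk-scale sizes chosen to keep the full suite fast while
leaving sampling error far below the tolerances tested: 50 coverslips × 200
cells for classification recovery, 20 replicate cells for noisy
threshold/Q10 recovery, 50 seeds for EC50 error, 100 replicates for paired
detection. Optimizer tolerances are 1e-14 (Hill least squares) and 1e-4 °C
(breakpoint polishing); the noiseless Hill round trip is exact to 1e-8
relative and Arrhenius recovery to 0.1 °C / 0.05 Q10. Ties in ranking and
selection break deterministically by input order; degenerate inputs (flat
series, zero-variance pairs, zero passing cells, sub-resolution warm
currents) are flagged, never silently propagated.
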
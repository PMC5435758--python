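# Methods

## Model

The BOLD response to a vasoactive stimulus is described by the Davis
model: with `f = CBF/CBF₀` and `r = CMRO2/CMRO2₀`,

```
b = ΔBOLD/BOLD₀ = M · (1 − f^(α−β) · r^β).
```

`M` (a fraction; reported in %) is the ceiling BOLD change at complete
deoxyhaemoglobin removal and absorbs baseline physiology and acquisition
parameters (field strength, TE). `α` couples venous blood volume to flow
and `β` relates venous deoxyhaemoglobin content to R2\*. Three exponent
conventions are built in and selectable by name:

| name       | α    | β    | intended use |
|------------|------|------|--------------|
| empirical  | 0.14 | 0.91 | simulation-optimized values for 3 T (default) |
| 3T         | 0.2  | 1.3  | widely used 3 T pairing |
| simplified | 0.06 | 1.0  | one-parameter (θ = 0.06) model written in α/β form |

Instead of forcing `r = 1` during hypercapnia (the iso-metabolic
assumption), the basal CMRO2 response is modelled as linear in the
end-tidal CO2 rise: `r = 1 + κ·ΔP_ETCO₂`, with `κ` in fraction/mmHg
(reported as %/mmHg). Measuring `(ΔP, b, f)` at two or more CO2 levels
gives one model equation per level in the two unknowns `(M, κ)`.

All internal quantities are fractions and ratios; percent appears only in
the I/O layer and in printed summaries. This avoids 100× errors inside
exponentiated expressions.

## Estimation

`HypercapniaCalibration.fit()` minimises the sum of squared BOLD-fraction
residuals over all levels with `scipy.optimize.least_squares` (trust
region reflective) under box constraints, defaulting to 1 % < M < 20 %
and −5 < κ < +5 %/mmHg — broad enough to contain plausible ROI-averaged
values, so a fit that reaches a bound is treated as noise-driven and
flagged rather than interpreted. Numerical choices:

- start at the interior iso-metabolic point (M₀ = 5 %, κ₀ = 0); an
  optional 3×3 multi-start grid guards against basin effects;
- convergence tolerances 1e−14; interior solutions get an unconstrained
  Levenberg–Marquardt polish (accepted only if it stays in bounds and
  lowers the cost), which brings noiseless two-level solutions to
  machine precision;
- a parameter counts as "at" a bound within 1e−6 (fraction units);
- positivity of `1 + κ·ΔP` is implied by the κ bounds whenever
  ΔP < 20 mmHg; for larger doses the lower κ bound is tightened to keep
  the ratio above 1e−6 — never silently clamped inside the objective.

With exactly two noiseless consistent levels the problem has an exact
solution; `solve_two_level_exact` computes it independently by
eliminating M and scanning the remaining 1-D equation in κ for sign
changes over the positivity domain (2001-point grid, Brent polishing,
1e−15 tolerance). When several roots exist the smallest-|κ| root is
returned along with the full root list; systems with more than one root
inside the fit bounds are genuinely ambiguous, and the least-squares fit
may legitimately settle on a different zero-residual root — equivalence
checks therefore restrict themselves to uniquely solvable systems. If no
root exists in the domain an explicit no-solution error is raised.

`fit_isometabolic()` fixes κ = 0, making the model linear in M; the
closed-form least-squares M (clipped to bounds) is used. With a single
level it reduces to `M = b / (1 − f^(α−β))`.

Generalisation beyond two levels is plain least squares over all levels
with equal weights, which preserves the two-level behaviour exactly.

## Group statistics

Subjects whose fit reached a parameter bound are excluded before any
group statistic (the bounds are wide, so hits indicate noise, not
physiology). Summaries report mean ± SEM (sample SD with n−1 denominator
over √n) and two-sided Wilcoxon signed-rank tests — κ against zero, or
the paired difference between two- and one-parameter M. The signed-rank
null is enumerated exactly for n ≤ 25 (dynamic programming over doubled
midranks, so ties are handled exactly); larger samples use the normal
approximation with tie correction. Zero differences are dropped
(Wilcoxon's original treatment). The implementation is cross-checked
against `scipy.stats.wilcoxon` in the test suite.

## Preprocessing

Interleaved tag/control dual-echo ASL volumes are separated into the two
label streams; each stream is linearly interpolated onto every TR and the
streams combined pointwise ("surround" combination, an exactly linear
operation):

- perfusion (CBF-weighted): control − tag at the short echo;
- BOLD: (control + tag)/2 at the long echo;
- R2\*: `ln(S(TE1)/S(TE2)) / (TE2 − TE1)` per volume within each stream
  (the exact two-point mono-exponential inversion), then surround
  averaged.

Block responses are means over *steady-state windows*: each block's first
`steady_state_offset` seconds (default 60 s of a 120-s block) are skipped
because manually targeted gas levels need tens of seconds to settle, and
a trailing `steady_state_guard` (default 4.5 s ≈ 2 TR) is trimmed because
surround interpolation adjacent to a condition transition mixes samples
of neighbouring blocks. A linear trend fitted to baseline steady-state
samples only is removed from the whole series; percent changes are
referenced to the stored baseline steady-state level. The CBF ratio is
taken directly from the perfusion-weighted difference signal's
steady-state means, assuming the difference signal is proportional to
perfusion (QUIPSS II conditions); no absolute quantification is
attempted. The end-tidal dose is the difference of pooled breath-wise
PETCO2 means between condition and baseline windows.

Sessions are handled by computing responses per session and averaging the
per-session levels (`average_level_sets`); ROI extraction from 4D NIfTI
images is an unweighted mask mean on the functional grid (masks are not
resampled).

## Synthetic data

The generator emulates the target experiment: 490 volumes at TR 2.2 s
(TE 3.3/29 ms), randomized 2-min blocks — three each of baseline, +4.8
and +8.4 mmHg — over 18 min, with ground truth defaulting to a
gray-matter-like state (M = 8.6 %, κ = −1.3 %/mmHg, CBF ratios
1.13/1.17, baseline R2\* = 31.7 s⁻¹).

Signal model per volume: the end-tidal dose follows a first-order
exponential settling (τ = 30 s) toward each block's target; CBF and the
BOLD fraction follow the *instantaneous* settled dose (CBF by linear
interpolation of the programmed dose-response points, BOLD through the
forward model), since CBF tracks arterial CO2 — with settling disabled
this reduces to an ideal step design. The BOLD fraction `b(t)` is
injected via `R2*(t) = R2*₀ − ln(1 + b(t))/TE2`, which makes the echo-2
control-signal fractional change equal `b(t)` exactly (asserted in
tests). The static signal carries a linear drift; the tag signal is the
control minus a perfusion difference signal of 1 % of the static signal
(typical gray-matter pulsed-ASL fraction) scaled by the CBF ratio.
Gaussian white noise (SD 0.3 a.u. per channel, i.e. 0.03 % of the static
signal) is added per channel; the value was calibrated once so that the
rate of boundary-hitting fits (~6–10 %) matches the incidence reported
for acquired data of this design (typically one subject in fifteen), the
only per-subject noise-attributable statistic available. Breath-wise
end-tidal samples every 4 s carry 0.5 mmHg jitter.

Two realistic echo-crosstalk nuisances are simulated by default and
jointly disabled by the `crosstalk` flag (CLI `--no-te1-bold`): the
echo-1 difference signal carries a small BOLD weighting (TE1 ≠ 0), and
the echo-2 average retains a small perfusion weighting. `exact()` returns
a copy with noise, drift, crosstalk, settling and jitter all off; in that
mode the full pipeline recovers `(M, κ)` to machine precision, giving
parameter-recovery tests a sharp target.

What the generator does **not** emulate: slice-profile and inversion
efficiency effects, transit-delay and QUIPSS II timing errors,
physiological (low-frequency, cardiac, respiratory) noise structure,
motion, task-evoked visual/motor responses, and inter-subject variance in
the true (M, κ). Passing recovery tests therefore demonstrates the
correctness and internal consistency of the estimation chain under the
stated signal model, not robustness to every property of acquired ASL
data.

## Known limitations

- **Finite-sample κ bias.** The (M, κ) estimator is strongly nonlinear in
  the measured CBF ratios, and with only two levels and three blocks per
  condition the κ sampling distribution at realistic noise is left-skewed:
  across 100 simulated sessions the mean κ error is of order −0.2 SD
  (about −0.3 to −0.5 %/mmHg at default noise), i.e. roughly 1–3 standard
  errors of the 100-session mean, varying with the ensemble seed. This is
  a property of the design, not the optimizer — the exact two-level root
  finder shows the same bias. Boundary-hit exclusion (which censors the
  heavy tail asymmetrically) reduces but does not remove it. Group means
  of per-subject κ should be interpreted with this skew in mind.
- Fitting group-mean responses is *not* equivalent to averaging
  per-subject fits; group-mean level tables can even have no interior
  solution (the fit then flags a bound hit). Fit subjects individually
  and average afterwards.
- Multi-rooted two-level systems exist (reported via
  `TwoLevelSolution.n_roots`); the smallest-|κ| root is returned by
  convention.
- The spoiled-gradient-echo contrast curve `TE·exp(−TE·R2*)` used by
  `relative_bold_contrast` is the standard single-compartment description;
  multi-compartment BOLD signal contributions are out of scope, as are
  voxelwise M/κ mapping, oxygen-extraction-based absolute CMRO2, motion
  correction, registration and activation mapping (ROI time series are
  inputs here).

## Problem sizes used in tests

Unit and property tests run on small constructed fixtures and on full
490-volume synthetic sessions (milliseconds each). The end-to-end checks
use 1,000 random two-level systems for oracle equivalence, 100 simulated
sessions per recovery ensemble and 30 per exponent pairing — sizes chosen
to make the stochastic assertions stable while keeping the whole suite in
the tens of seconds.
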
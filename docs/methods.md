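# Methods

## Scope and data flow

The package quantifies dynamic PET of orthotopic GL261-luc2 glioblastoma
with three ¹⁸F tracers. The chain is: whole-blood TAC from the inferior
vena cava → plasma conversion → metabolite correction → continuous input
function → compartment fits (1TCM/2TCM, optionally SRTM) and graphical
analysis (Logan/Patlak) → model selection → group statistics; in parallel,
semi-quantification (SUV, TBR, MTV), voxelwise 2TCM maps and ADC maps.

Units: time in minutes internally (TAC tables on disk use seconds and are
converted at the I/O boundary); activity in kBq/cm³; K1 in ml/cm³/min,
k2–k4 in 1/min, VT/Vs in ml/cm³, ADC in mm²/s. TAC values are taken as
frame-averaged, decay-corrected concentrations (the scanner convention for
reconstructed dynamic data); no decay correction is applied downstream, and
TACs are assumed decay-corrected to injection time.

## Input function

The vena-cava TAC is converted to plasma with a plasma-to-blood ratio —
constant 1.66 for the PSMA tracer, the literature series
(1, 5, 15, 30, 40, 55 min → 1.1, 1.1, 1.1, 1.1, 1.3, 1.4) interpolated
linearly (end values held) for FET, and 1.0 for fluciclovine, for which no
conversion data exist. Metabolite correction multiplies by a parent
fraction f(t): constant, one-exponential f = (1−A) + A·e^(−λt), or Hill
f = 1 − (1−floor)·tⁿ/(t50ⁿ + tⁿ). Defaults: f ≡ 1 for the metabolically
stable PSMA tracer and fluciclovine; a mild one-exponential (A = 0.2,
λ = 0.01/min) for FET. The measured parent-fraction curves are not public,
so these defaults are deliberately conservative and overridable per config.

The corrected samples define a continuous input with a fixed interpolation
contract: linear from (0, 0) to the first sample (a bolus starts at zero),
piecewise linear between samples, and a mono-exponential tail fitted
log-linearly to the last three samples (held constant if the tail is flat
or non-positive). The tail matters because frame averaging of the last
frame integrates past the last midpoint. No partial-volume, spill-over,
delay or dispersion correction is applied.

## Exact convolution and frame averaging

Compartment outputs are sums of exponential kernels convolved with the
input. Because the input contract is piecewise linear, each segment
integral of e^(−αt) ⊛ C_p has a closed form; a linear scan over the merged
grid (input knots ∪ frame boundaries ∪ midpoints) evaluates the
convolution exactly, with series expansions of the exponential integrals
for small α·Δt and an analytic t·e^(−αt) kernel at the degenerate
repeated-root boundary (α₁ = α₂, reached when k3 = 0 and k2 = k4; the
eigenvalue discriminant is computed in its cancellation-free algebraic
form). k3 = 0 itself short-circuits to the exact 1TCM kernel. A vanishing
rate (α < 1e−12/min) switches to the pure-integrator limit.

Frame values are exact frame-duration averages, obtained analytically from
the identity d/dt (e^(−αt) ⊛ C_p) = C_p − α·(e^(−αt) ⊛ C_p), which turns
the time-integral of the convolution into a difference of quantities
already on the grid. This removes all quadrature error from the fitting
surface; the unit tests pin the scans against adaptive numerical
quadrature at 1e−8 relative.

## Fitting

Weighted nonlinear least squares (scipy `least_squares`, trf, tolerances
1e−14) from multistart initial points: one fixed heuristic start plus
seeded log-uniform draws within bounds (K1 ∈ [0, 5], k2–k4 ∈ [0, 10],
vB ∈ [0, 0.2]; 20 starts by default, 5 for voxelwise maps). Weights are
uniform by default (frame-duration weighting available); vB is fixed at 0
unless `fit_vB` is set, since the reports do not quote blood-volume
fractions. Ties among starts (ΔSS ≤ 1e−12) resolve to the lowest K1, then
lowest k3, for determinism. Standard errors come from the
residual-variance-scaled Gauss–Newton curvature at the optimum and are
reported, never used for selection. Voxelwise maps derive per-voxel seeds
from the base seed plus the voxel's linear index, making maps
bit-reproducible.

SRTM (C_t = R1·C_r + (k2 − R1·k2a)·C_r ⊛ e^(−k2a·t), k2a = k2/(1+BPND))
is solved by basis functions — 200 log-spaced k2a in [0.005, 5]/min, linear
solve per basis — followed by a bounded local polish. Because SRTM is
invalid for high-grade tumors, a diagnostic fits a 1TCM to target and
reference against the blood input and flags violation when either region is
poorly described (R² < 0.95 by default) or the VT ratio exceeds 2 (the
3-fold mismatch constructed in the tests is flagged; a BPND of 0.5, ratio
1.5, passes).

## Graphical analysis

Logan coordinates use the trapezoidal tissue integral (anchored by a
virtual (0, 0) point) and the exact integral of the continuous input
contract; Patlak likewise. t\* defaults to 20 min on both schedules; the
auto mode scans candidate segment starts from late to early and keeps the
earliest start whose segment holds every |residual|/|fitted| ≤ 10%
(flagged, last-3-points slope if none). The Patlak "positive slope" test
requires the OLS 95% CI to exclude zero — this makes the qualitative
irreversibility claim testable. Logan's noise-induced negative bias is
documented but uncorrected (standard Logan, no multilinear variant).

A genuine limitation, asserted in the tests: the Logan slope equals the
compartmental VT within 2% only where the slowest kinetic eigenvalue
equilibrates well inside the scan (PSMA-tracer kinetics, α₁ ≈ 0.39/min,
agree to <0.1%). The amino-acid tumor truths have α₁ ≈ 0.02/min
(~50-minute equilibration), so even noiseless Logan slopes remain 9–14%
below VT within 90 min — the textbook Logan underestimation for slowly
equilibrating tracers, not a numerical artifact.

## Model selection

Least-squares criteria without Gaussian constants (they cancel between
models on shared data): AIC = n·ln(SS/n) + 2p, SC = n·ln(SS/n) + p·ln(n),
MSC = ln(ΣwΔ²_about-mean / ΣwΔ²_resid) − 2p/n (higher better). A perfect
fit maps to the appropriate infinite sentinel. The winner is lowest AIC;
ties (<1e−9) resolve by lowest SC, then fewest parameters, and the report
records the rule used.

## Semi-quantification and ADC

SUV = C/(dose/weight). TBR is the tumor/contralateral frame ratio at the
frame nearest the requested time (the contralateral mask is supplied
explicitly; mirroring would need registration and is out of scope). MTV
thresholds the duration-weighted mean image over a window — 15–60 min for
the amino-acid tracers, 2–30 min for the washout-kinetics PSMA tracer — at
50% (MTV50) or 75% (MTV75, used for the low-uptake PSMA tracer) of the ROI
maximum, ties included. ADC is the negated slope of the OLS regression of
ln(signal) on b (a log-linear fit, not a nonlinear mono-exponential fit),
so noiseless mono-exponential signals are recovered exactly for any ≥ 2
distinct b-values.

Group comparisons use Welch's unequal-variance t (cohorts of 3–6 animals;
a pooled-variance switch exists), two-sided, α = 0.05, no
multiple-comparison correction — one test per contrast, as in the study
design. Degenerate zero-variance samples return p = 1 (equal means) or the
p = 0 sentinel. Tracer cross-correlation is the Pearson matrix of mean
tumor TACs.

## Synthetic-study generator

Ground truths are the published 28-day rate constants; rate constants the
reports leave unprinted are solved from VT = (K1/k2)(1+k3/k4) (and checked
against the printed Vs) and flagged `derived` in the truth table:
tumor k2 for the PSMA tracer (3.2252 from VT = 0.24), its brain k2 (1.0553
from VT = 0.1, k4 assumed equal to the tumor value), fluciclovine k4
(0.01946 tumor from VT = 1.5; 0.02061 brain from VT = 0.5), FET tumor k4
(0.02545 from VT = 1.38) and an assumed FET brain set (K1 = 0.10,
k2 = 0.3, k3 = 0.02, k4 from VT = 0.71). Day-21 truths keep the 28-day
micro-rates and impose the printed day-21 values (tumor K1 0.1 for the
PSMA tracer, 0.55 for FET with VT 0.5, fluciclovine VT 0.84).

The plasma input is a Feng-form bolus
C_p = (A1·t − A2 − A3)e^(−λ₁t) + A2·e^(−λ₂t) + A3·e^(−λ₃t), sampled at
1-s spacing for the first 5 min and 30-s after. Per-tracer shapes and
amplitudes were calibrated once so the noiseless tumor SUVmean curves
reproduce the published dynamic ranges — PSMA tracer ~0.8 SUV at 2 min
washing out to ~0.33 at 60 min with TBR ≈ 2.4; FET accumulating to ~1.5
and fluciclovine to ~1.3 SUV at 90 min with TBR 2.1–2.8 and an
inter-tracer tumor-TAC Pearson r ≈ 0.95 — and are recorded as constants in
`petkin.simulate`. No fitted quantity depends on the input shape; it sets
only the realism of the curves.

Cohort sizes are those scanned (5/6, 6/4, 3/4 animals for the PSMA
tracer/FET/fluciclovine at 21/28 days), with mean injected doses 10.5, 8.0
and 11.5 MBq and 20 g body weight. Inter-animal variability is a lognormal
jitter on each rate constant (sd 0.10 in the analysis scripts; 0 by
default so that the default study is exactly the printed truths). Noise is
the standard count-statistics model ε_i ~ N(0, scale·√(max(C_i, floor)/Δt_i))
— variance proportional to activity over frame duration, so 5-s bolus
frames are appropriately noisy — with scale 0.05 for the noisy-study
conditions, negative values clipped at zero. All randomness flows from a
single seed.

Consistency contract: the generated vena-cava TAC stores midpoint samples
of the whole-blood curve, defined as parent-plasma/(PBR·f). Re-applying
the corrections to those samples reproduces exactly the piecewise-linear
input the tissue TACs were convolved against, so the full pipeline inverts
a noiseless study to the generating truths at optimizer precision (the
acceptance tests verify ~1e−10 relative for every region, tracer and
timepoint). The 8×8×8 phantom (0.42 mm isotropic, matching the
reconstruction voxel size) carries three labelled box regions with the
region TACs plus voxelwise noise.

What the generator does not emulate: scanner physics (scatter, randoms,
resolution, partial volume), motion, registration error, tumor growth
within a scan, or real inter-animal input-function variability (the input
is shared within a cohort). Passing tests therefore demonstrate
correctness of the quantification chain under the stated kinetic model,
not robustness to image-domain artifacts.

## Problem sizes and determinism

The shipped tests run the paper's own frame schedules (42/48 frames),
100-replicate model-selection power checks, 200-replicate noisy-recovery
checks and 500-replicate ADC simulations; voxelwise map tests use small
multi-voxel phantoms with 3–5 multistarts per voxel. These sizes keep the
whole suite in a few minutes on one core while leaving the statistical
assertions comfortably powered. Every stochastic component is seeded;
repeated runs are bit-identical.
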
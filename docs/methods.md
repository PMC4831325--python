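# Methods

## The estimation problem

Dynamic contrast-enhanced (DCE) MRI of the kidney records signal-intensity
time curves in the abdominal aorta and the renal parenchyma while a bolus
of a gadolinium tracer passes through. Because a freely filtered tracer
accumulates in the tubules in proportion to the glomerular filtration
rate, the renal curve carries quantitative information about GFR. `mrgfr`
estimates whole-kidney GFR (mL/min) from a pair of ROI-averaged curves,
the subject's hematocrit and the renal parenchymal volume, using a
subject-specific two-compartment (2C) uptake model: the uptake interval
over which the model is fitted and the hematocrit entering the plasma
correction are both taken from the individual subject rather than from
fixed literature values.

## Models

**Arterial input function.** The aortic plasma concentration is modelled
as a sum of two gamma-variate lobes,

    Ao_p(t) = sum_i a_i (t - t_i)^{b_i} exp(-(t - t_i)/c_i),  t >= t_i,

lobe 1 describing the first pass and lobe 2 the recirculation. The
convention 0^0 = 1 at onset makes b = 0 a valid boxcar-decay lobe. Aortic
signal enhancement is divided by (1 − Hct) to convert whole-blood to
plasma concentration.

**Renal plasma compartment.** The AIF reaches the glomerular capillaries
after an arterial delay δ and is dispersed by a first-order transit
compartment with time constant t_disp:

    dP/dt = (Ao_p(t − δ) − P)/t_disp,  P(0) = 0.

**Kidney curves.** With plasma volume fraction v_p and filtration rate
per parenchymal volume GFR_V (min⁻¹):

* uptake model (valid to the end-of-uptake point):
  C_k(t) = v_p P(t) + (GFR_V/60) ∫₀ᵗ P dτ;
* inflow–outflow model (tubular mean transit time t_tub):
  dT/dt = (GFR_V/60) P − T/t_tub, C_k = v_p P + T.

Whole-kidney GFR = GFR_V × parenchymal volume. Renal plasma flow per
volume, RPF_V = 60 v_p / t_disp, is computed as a secondary output and is
not validated against any reference.

Internally all times are seconds; GFR_V is carried in min⁻¹ and divided
by 60 inside the kinetics because the curves are sampled at 1.7 s.

## Numerical evaluation of the compartments

Both first-order compartments are advanced on a uniformly refined grid
(default 10× the sampling rate) with exact exponential-kernel stepping:
within each refined step the input is interpolated linearly and the ODE
is solved exactly, i.e.

    P[n] = α P[n−1] + w₀ u[n−1] + w₁ u[n],  α = e^{−h/τ},

with weights chosen so the update is exact for piecewise-linear input
(series expansions guard small h/τ against cancellation). The recursion
is evaluated as a first-order IIR filter. The tubular accumulation
integral uses the trapezoid rule on the same refined grid. At the default
10× refinement the discretization error is ~1e−4 relative — far below
the fitting noise — and the scheme converges to better than 1e−6 against
a brute-force adaptive ODE integration at 300× refinement, which is how
the oracle-equivalence test runs it.

## Curve conditioning and end-of-uptake detection

Enhancement curves are the raw signals minus the mean of the 10
precontrast samples; the precontrast SD is retained. The postaortic rise
is the sample *before* the first aortic enhancement above
`rise_sigma_k` × baseline SD (default 3) sustained for `persistence`
samples (default 3); with a noise-free baseline any strictly positive
value counts.

The renal curve is smoothed with a centered moving average (default
window 5 samples, edges truncated) before the end-of-uptake search. On
the smoothed derivative after the postaortic rise, the filtration phase
begins after the vascular first-pass peak where a distinct one exists (a
local maximum followed by a sustained renewed rise); `d_max` is the
maximum filtration-phase slope. Outflow takes precedence: a run of
`persistence` samples with slope ≤ −θ·d_max (θ = `plateau_fraction`,
default 0.1) marks a descent, and the sample of maximum enhancement
before it is the end-of-uptake point. Otherwise a run with |slope| <
θ·d_max marks a plateau and its first sample is returned, since a plateau
already implies tracer is leaving the parenchyma. θ and the persistence
count are this package's operationalization of "significant outflow";
both are exposed in `DetectionConfig`. A caller may override the
automatic choice with a hand-picked index.

## Fitting

All fits are Levenberg–Marquardt least squares (lmfit; bounds enforced by
parameter transform) with seeded multi-start initialization (default 5
starts) to avoid local minima from the delay/dispersion trade-off; ties
are broken by lowest residual norm, then lowest delay. R² = 1 −
SS_res/SS_tot over the fit window.

The AIF fit runs from the postaortic rise to the end of acquisition. It
is parametrized by each lobe's *peak value* rather than the raw gamma
amplitude a_i (which spans many orders of magnitude across shapes and
makes the raw parametrization numerically intractable); the first-pass
lobe is seeded at the curve argmax, the recirculation lobe 25 s later
and at any late secondary hump. On noise-free curves from the model
family the fit recovers all eight parameters to machine precision; every
converged start is polished by re-minimizing from its own optimum, and a
`tol` knob (default 1e−12) controls the Levenberg–Marquardt step and
residual tolerances.

Kidney fits run over [postaortic rise, end index] with end index chosen
per method: the detected end-of-uptake (subject-specific model), rise +
round(90/dt) or round(110/dt) samples (fixed-interval models), or the
last sample (inflow–outflow, using the full 217 s postcontrast series).
Free parameters and bounds: v_p ∈ [0, 1], GFR_V ∈ [0, 2] min⁻¹, δ ∈
[0, 10] s, t_disp ∈ [0.5, 30] s, and t_tub ∈ [10, 10⁴] s for the
inflow–outflow model. The optimizer's initialization, bounds and
tolerances are this package's choices; they are not part of the model.

Because the kidney models are linear in the AIF amplitude, the estimated
GFR is exactly proportional to (1 − Hct): a relative hematocrit error of
1% induces a relative GFR error of Hct/(1 − Hct) %, i.e. 0.72% at
Hct = 0.42. This identity is exercised directly by the tests.

## Agreement statistics

Cohort comparison against a reference GFR uses ordinary least squares of
the MR estimate on the reference (two-sided p for slope ≠ 0, via
`scipy.stats.linregress`) and Bland–Altman bias with limits of agreement
bias ± 2·SD of the differences. The ±2 SD convention (not ±1.96) and the
n−1 SD denominator are deliberate reporting choices. Summary tables hold
one row per method × hematocrit mode with range, mean ± SD and the
agreement statistics; cells with fewer than three subjects report ranges
only.

## The synthetic cohort

No patient data ships with the package; every pipeline stage is
validated on a seeded simulator that emulates the study acquisition
(Δt = 1.7 s, 135 time points, 10 precontrast) and cohort heterogeneity:
hematocrit ~ U(30%, 49%), parenchymal volume ~ N(241, 52²) mL truncated
to [158, 333], GFR_V ~ U(0.20, 0.60) min⁻¹ (whole-kidney GFR spanning
roughly 44–160 mL/min), uptake intervals spanning the physiologic
64–141 s band. The stored aortic signal is the plasma AIF scaled by
(1 − Hct) plus a baseline; Gaussian noise (default SD 2% of each curve's
peak enhancement) is added to every sample. The reference GFR is the
true GFR_V × volume plus N(0, 5²) mL/min noise emulating a reference
measurement taken days apart from the MRI.

Ground truth uses the inflow–outflow forward model, so uptake-model
fitting is a genuine approximation, and the true end-of-uptake point is
defined as the argmax of the noise-free kidney enhancement. Three design
constraints must hold simultaneously: the interval band, near-exact
noise-free recovery by the uptake model, and a decisive post-maximum
descent for automated detection. They cannot all be met by tubular
outflow alone — an outflow-driven maximum inside the acquisition window
requires a transit time short enough to bias the uptake fit by far more
than 2% — so the simulator draws t_tub long (4000–9000 s, uptake-model
bias ≲ 1.5%) and lets vascular washout of the late AIF terminate the
uptake phase. Concretely, the washout ratio φ = (GFR_V/60)·c₂/v_p is
drawn in [0.12, 0.20], a per-subject target interval is drawn with a
mild negative coupling to GFR_V (faster-filtering kidneys peak earlier),
and the recirculation lobe scale (b₂, c₂) is solved from the target;
v_p = (GFR_V/60)·c₂/φ then falls in ≈0.12–0.40. Draws whose realized
interval leaves 64–141 s are rejected and redrawn (GFR_V is drawn
outside the rejection loop so the filtration distribution is not
distorted). The resulting recirculation lobe is a broader, later hump
than a textbook recirculation peak; it is a deliberate synthetic
construction that gives the renal curve the well-defined three-phase
morphology the detector is specified against.

What the simulator does *not* emulate — and hence what passing tests do
not demonstrate about real data: signal-saturation and T1 nonlinearity,
water exchange, respiratory motion, ROI misregistration, structured
(non-Gaussian, correlated) noise, genuinely short tubular transit in
impaired kidneys, and AIF inflow enhancement. Real-data behaviour such as
the systematic GFR underestimation reported for patient cohorts arises
from exactly these effects and is outside the simulator's reach.

## Observed estimator behaviour

On the default noisy cohort the subject-specific pipeline's GFR errors
have a median of a few percent with worst cases near 12% — driven by
v_p/δ/t_disp trade-offs and end-point detection scatter under noise —
while noise-free recovery is within 2% per subject. With a truncated
217 s window and long tubular transit the inflow–outflow fit is weakly
identified in (GFR_V, t_tub); because t_tub is bounded above while GFR_V
can compensate downward-biased transit estimates, its cohort mean
overestimates the truth, mirroring the known failure mode of
inflow–outflow fitting on short acquisitions.

## Reproducibility

Every stochastic component — cohort draws, fit multi-starts — derives
from explicit integer seeds; per-fit streams are derived by hashing the
base seed with the subject id and method so results are independent of
evaluation order. Identical configuration and seed reproduce cohorts
bit-exactly and fits deterministically.
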
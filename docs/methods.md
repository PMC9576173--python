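# Methods

## Signal model and pipeline

### Pressure

Raw LA pressure is sampled (nominally 977 Hz) with ECG R-wave annotation
times supplied by the recorder; no QRS detection is performed. Filtering
is a rectangular band-pass applied in the discrete Fourier domain: bins
with |f| in [0.4, 10] Hz (inclusive) are retained together with the 0 Hz
bin, everything else is zeroed symmetrically over positive and negative
frequencies, and the inverse transform is taken at the same length. No
window or taper is applied; tests use integer-period tones so that
spectral leakage never clouds a pass/fail decision, while real recordings
accept leakage as-is. Retaining DC preserves the mean pressure exactly;
the filter is idempotent and linear by construction.

Cycle segmentation maps each R-wave to its nearest sample; a segment runs
from one R-wave's sample to one sample before the next. Composite
averaging is *time-referenced*: `composite[k]` is the mean over all
segments long enough to reach offset `k`, with the per-offset count kept
as a support curve. This variable-denominator superposition is what makes
irregular (AF) rhythms averageable; its cost is that late offsets rest on
few cycles, so feature extraction truncates the composite at a support
floor (default: offsets backed by at least half the cycles).

Features: LAP mean/max/min over the truncated composite; the v-wave peak
is the global maximum over offsets in [25%, 90%] of the mean RR interval
(the window excludes a late a-wave in sinus rhythm and early systolic
artifact); time-to-v-peak is that offset (reported in ms and as % of mean
RR); filling dP/dt is the ordinary-least-squares slope from the last
local minimum preceding the peak (window start if the limb is monotone)
to the peak. A two-point slope is available via `dpdt_method="two_point"`.

### Volume

Echo volume curves are sparse (~20 samples/s) and beat lengths vary, so
beats are aligned by *phase*: each beat's time axis is mapped to
(t − t₀)/(t_end − t₀), linearly interpolated onto N = 200 equally spaced
phases on [0, 1), and averaged. N = 200 is roughly ten times the samples
per beat at typical volume rates — fine enough that interpolation error
is negligible after PV resampling. The asymmetry with the pressure
module's absolute-time averaging is deliberate: pressure is dense and
R-wave-anchored, volume is sparse and shape-stable.

Indices are V_max, V_min, TEV, TEF from the composite. The reservoir
(filling) segment runs from the V_min phase to the V_max phase in cycle
order, wrapping across phase 0 when V_min falls near the R-wave boundary,
with times scaled by the mean beat duration. The exponential
V = A·e^{Kt} is fitted log-linearly (OLS of log V on t) — deterministic,
initialization-free; `method="nonlinear"` refines by volume-domain
Levenberg–Marquardt when residuals in mL matter. On exact exponential
data both routes agree to machine precision.

### PV loop and stiffness

Both composites are linearly interpolated onto n points spanning one
cycle; the default n is one point per millisecond of the mean
volume-acquisition cycle (a ~1 s cycle gives ~999 points per loop).
Because each echo volume is really acquired over a finite sweep, the
pressure–volume pairing has an unknown offset; it is resolved by
circularly shifting the pressure cycle so that the v-wave peak (searched
in the same 25–90% window) lands on the volume maximum — both events
immediately precede mitral valve opening. The minimal-magnitude signed
shift is recorded on the loop in ms.

Stiffness is the two-point slope between the filling-limb endpoints: the
volume-minimum point (mitral closure) and the volume-maximum point.
Endpoints were chosen over a regression because measured PV limbs do not
exhibit one consistent curvilinear shape; a least-squares-through-limb
option (`method="regression"`) and a pressure-minimum limb start
(`limb_start="pressure_min"`) exist for sensitivity analyses. Loops with
TEV under 1 mL are rejected as unanalyzable. ΔdP/dV is simply
post − pre for the same patient.

## Statistics

Everything is nonparametric. Wilcoxon signed-rank and Mann–Whitney ride
on scipy with explicit exactness policy: exact null distributions for
tie-free samples up to n = 25 (signed-rank) and n₁+n₂ = 16
(Mann–Whitney), tie-corrected normal approximations beyond; zero paired
differences are dropped (Pratt handling available). Confidence intervals
are percentile bootstrap (10,000 resamples by default, seeded); BCa was
not used because the estimand is a median and percentile intervals are
transparent and adequate at the cohort sizes involved (coverage is
measured, see below). Bonferroni gating reproduces the P < 0.0125
threshold used for four paired volume comparisons. Spearman's rs uses
mid-ranks with an exact permutation p for n ≤ 10 (full n! enumeration,
vectorized in chunks) and the t-approximation otherwise; two-tailed
throughout. Median splits assign the middle patient of an odd cohort to
the lower group — a convention that yields 13/12 splits at n = 25 — and
resolve boundary ties by patient id with a warning.

ICC is computed from the two-way ANOVA mean squares directly:
ICC(2,1) = (MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n) (random raters,
absolute agreement) and ICC(3,1) = (MSR − MSE)/(MSR + (k−1)MSE) (fixed
raters, single measure), each with the standard F-based 95% interval.
With a systematic rater offset ICC(3,1) ≥ ICC(2,1), as expected, since
only the latter charges rater variance to the denominator.

## Synthetic data: what it emulates, and what it does not

The generator exists so every stage has ground truth. A pressure cycle
is a baseline plus Gaussian bumps — v-wave (default 11 mmHg before
stiffness coupling, centered at 54% of the mean RR, width 0.09 s) and,
in sinus rhythm only, an a-wave (4 mmHg at 88% RR) — with additive
respiration (0.2 Hz, 3 mmHg: mechanically ventilated patients),
a 60 Hz/0.5 mmHg powerline tone, and white noise (1 mmHg). AF cycle
lengths are gamma-distributed (mean 0.999 s, CV 0.2); wave centers sit at
fixed fractions of the *mean* RR in absolute time, reflecting that the
v-peak tracks ventricular systole rather than the preceding RR, and
making truncated-waveform averaging recover the template exactly in the
noise-free limit. R-wave annotations are quantized to the sample grid, as
a recorder's would be.

Volumes are built *from* the clean pressure template: over the filling
phase (5% to 54% of the cycle) V(t) = V_min + (P(t) − P_start)/s with the
v-wave amplitude solved in closed form so the limb's pressure rise equals
s·TEV exactly — the ground-truth dP/dV is embedded by construction, which
is the only way parameter recovery is a well-posed test. Emptying
descends monotonically (smoothstep; sinus rhythm gets a passive phase,
diastasis, and a late active-emptying component). Beats are sampled at
20 volumes/s with *bounded* multiplicative measurement error (uniform
±2% by default), so generated volumes provably stay within
[0.98·V_min, 1.02·V_max].

Cohorts draw per-patient latents with marginals centered on a typical
LAAO population: baseline stiffness log-normal (median 0.41 mmHg/mL,
log-sd 0.703 matched to the interquartile range), stiffness change
normal (mean +0.22, sd 0.17 mmHg/mL), indexed LAA depth log-normal
(median 1.38 cm/m², log-sd 0.1595), with a Gaussian copula of
correlation ρ (default 0.7) coupling indexed LAA depth to the stiffness
change; the copula-implied Spearman correlation is (6/π)·asin(ρ/2)
≈ 0.683 at ρ = 0.7. Baseline stiffness shares a latent factor with mean
LAP (ρ = 0.5). The change is floored so post-occlusion stiffness stays
above 0.05 mmHg/mL; the floor binds rarely (≪1% of draws under the
default shift) and measured consequences — null rejection ≈ 4.7%, mean
sample Spearman within 0.02 of the copula value — are part of the test
suite rather than assumed away.

What the generator does **not** emulate: catheter damping and zero
drift, beam-sweep artifacts in the echo volumes, atrial ectopy, the
interatrial shunt's volume effects, or any biophysical (elastance-chain)
atrial model. Passing tests therefore demonstrate that the *pipeline*
recovers what the data contain under plausible noise — not that the
morphology model is physiologically complete.

## Problem sizes and numerical choices

Monte-Carlo sizes used by the test suite and the acceptance script are
chosen for stable estimates at desk scale: 100 replicates per condition
for stiffness recovery (six conditions: sinus/AF × dP/dV ∈ {0.2, 0.4,
0.8} mmHg/mL), 200 shifted and 1,000–2,000 null cohorts for power and
calibration, 500 cohorts per ρ for correlation recovery, and 1,000
replicates (2,000 resamples each) for bootstrap coverage of the median
at n = 25 from a log-normal population. The noise-free pipeline-identity
check runs at 2,000 Hz pressure sampling, 200 volumes/s, and regular
rhythm, where recovered dP/dV agrees with truth to < 0.5%.

Interpolation is linear everywhere (monotone, no overshoot at the
v-peak). Peak alignment rejects plateaus wider than 5% of the cycle as
degenerate. Delimited files are comma-separated UTF-8 with one header
row; floats are written with 17 significant digits and read back with
round-trip parsing, so write∘read is the identity. BSA enters as a
measured field — no height/weight formula is imposed.

## Known limitations

- The composite support floor (50%) and the v-peak search window
  (25–90% of mean RR) are conventions; extreme tachycardia or very wide
  v-waves may need different settings.
- The exact Spearman permutation p is O(n!) and capped at n = 10.
- ICC confidence intervals assume the standard two-way ANOVA normal
  theory; with k = 2 raters and few subjects they are wide and
  approximate.
- Stiffness is a two-point endpoint slope by design; it inherits the
  endpoints' noise, which the composite averaging — not the slope
  estimator — is responsible for suppressing.
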
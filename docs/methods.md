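# Methods

`mirffl` models how microRNAs embedded in incoherent feed-forward loops
(FFLs) shape the mean and cell-to-cell variability of target protein
expression, and provides the flow-cytometry-style statistics used to
quantify that variability in single-cell intensity data. This note
documents the models, the parameter choices, the synthetic-data
assumptions, and the numerical decisions.

## Stochastic circuit simulation

### Simulator

Reaction networks are simulated with the exact Gillespie direct method:
at each step the waiting time to the next event is drawn exponential with
rate equal to the total propensity, and the firing reaction is chosen
with probability proportional to its propensity. States are integer copy
numbers, non-negative by construction (validation requires every consumed
species to contribute a count factor to its reaction's propensity, which
therefore vanishes at zero copies). No approximate accelerations
(tau-leaping etc.) are used; the per-event loop is numba-compiled.

A propensity is `rate x count factors x Hill factors`:

* count factors: falling factorials x(x-1)...(x-m+1) for a reactant of
  multiplicity m (mass-action combinatorics); zero-order productions have
  none;
* Hill activation `x^n / (K^n + x^n)` or repression `1 / (1 + (x/K)^n)`
  evaluated on a regulator's current copy number.

Ensembles run `n_runs` independent realizations; run *i* is seeded with
the *i*-th 32-bit child of `numpy.random.SeedSequence(base_seed)`, so
ensembles are reproducible and extending an ensemble preserves earlier
runs. By default only the endpoint state is kept (the across-runs
endpoint distribution plays the role of a distribution across cells);
event-resolved trajectories are available behind `record=True`.

The deterministic (mean-field) rate equations `dx/dt = S^T a(x)` of any
network are integrated with LSODA to obtain steady states; these serve as
oracles for calibration checks and for the stochastic ensemble means.

### Circuit variants

Both variants share an upstream backbone: a transcription factor (TF)
gene is transcribed constitutively (rate 0.06), its mRNA decays (0.006),
is translated (0.04 per mRNA), and the TF protein decays (0.002) — giving
mean-field steady states of 10 TF mRNAs and 200 TF proteins. The TF
activates, with Hill coefficient 2 and dissociation constant 200 (i.e. at
its own steady state it half-saturates both promoters), transcription of
a microRNA (base rate 0.5, decay 0.006) and of a target mRNA (base rate
0.8, decay 0.006). Time units are arbitrary; all rates are per unit time.

* **Translational repression**: target protein is produced per mRNA at
  base rate 0.04, multiplied by Hill repression by the microRNA
  (dissociation constant 60, coefficient 2); protein decays at 0.002.
  5 species, 10 reactions (11 when the microRNA leak is enabled).
* **mRNA degradation**: translation is unrepressed (0.04 per free mRNA);
  instead microRNA and mRNA form a complex (on/off rate constants 0.0001)
  in which the mRNA is degraded at 0.02, releasing the microRNA. Free
  plus complexed microRNA changes only through microRNA production and
  decay. 6 species, 13 reactions.

### CD69 calibration

The CD69 instance of the translational circuit is anchored on measured
copy numbers: ~0 *Cd69* mRNAs per resting cell and ~6 per activated cell
(from ~25,000 *Cd69* per 10^6 *B2M* and ~215 *B2M* copies per cell), and
miR-17/miR-20a at roughly 6–12 copies per resting cell rising to 30–60
after activation. The working values are 9 resting and 42 activated
microRNA copies; 42 equals the resting level plus an induced component of
33 and is consistent with the downstream repression ratios this package
reproduces (the printed ranges are carried in `CD69ModelSpec` for
sensitivity analyses).

Rate balance at the activated TF steady state (TF_ss = 200, where the
Hill activation is exactly 1/2) maps targets onto rates:

* target mRNA transcription `k_tx_target = 6 x 0.006 / 0.5 = 0.072`;
* constitutive microRNA leak `k_leak = 9 x 0.006 = 0.054`, so the resting
  state (TF absent) holds 9 microRNA copies;
* TF-activated microRNA component `k_mir = (42 - 9) x 0.006 / 0.5 =
  0.396`, so the activated steady state holds 42;
* protein translation 0.44 per mRNA with decay 0.002, which places the
  unrepressed activated protein mean near 1.3 x 10^3 and hence the
  repressed mean near 0.9 x 10^3 (the ratio is set by Hill repression at
  42 vs 9 microRNA copies: 0.671 / 0.978 = 0.686).

Calibration is verified by mean-field steady states (5% tolerance) in
both the activated and resting conditions.

### Scenarios

* `resting` — TF input off (`k_tx_tf = 0`): no target transcription,
  leak-only microRNA; protein mean ~0.
* `activated_with_FFL` — full calibrated circuit.
* `activated_without_FFL` — TF on, but the TF-activated microRNA
  component silenced (`k_tx_mir_base = 0`), leaving the resting leak.
  The microRNA is *held at its resting production rate*, not clamped to a
  constant copy number, preserving its stochasticity.

Each scenario runs 10,000 realizations (2,000 in the test suite) from
all-zero initial conditions to t = 5000, i.e. ten protein lifetimes at
degradation 0.002, long enough for the endpoint ensemble to sample
quasi-stationarity. The FFL effect is summarized as the difference of
protein means and of percent CVs, with a two-sided bootstrap p-value for
the CV difference (each ensemble resampled, add-one correction; smallest
reportable p is 2/(n_boot+1)) and a Welch t-test for the mean difference.

### What the model predicts, and a known limitation

With these parameters the microRNA arm lowers both the protein mean
(~875 vs ~1270 over 10,000 runs) and the protein CV (~22.4% vs ~24.7%),
with bootstrap p < 10^-4 for the CV difference; the same ordering holds
for the mRNA-degradation variant at its reference parameters (~12% vs
~14%). The *absolute* CVs of the calibrated model are dominated by
intrinsic target-mRNA noise: with only ~6 mRNA copies, that source alone
contributes a protein CV of about
`100 x sqrt((1/6) x tau_mRNA / (tau_mRNA + tau_protein)) ≈ 20%`, and
because the microRNA senses the TF rather than the target mRNA, the FFL
cannot cancel it. The FFL specifically buffers the *extrinsic* (TF-
propagated) component, which is why the CV reduction (~2.3 points) is
modest relative to the large mean reduction. Reported CVs should be read
with this decomposition in mind; the buffering direction and significance
are the robust predictions, the absolute CV level is a function of the
copy-number scale chosen.

## Copy-number arithmetic

Relative abundances anchor on a reference: `copies = per_1e6_ref x 1e-6 x
ref_copies_per_cell` (e.g. 25,000 x 1e-6 x 215 = 5.375 ≈ 6 *Cd69* mRNAs
per activated cell). Cloning frequencies first size the per-cell
microRNA pool from an anchor microRNA (miR-181a: 89,884 per 10^6 at
400–800 copies per cell), then scale by the target's frequency; miR-17 at
1,465 per 10^6 gives 6.5–13.0 copies per cell. qPCR CTs are normalized
as `2^-(CT_target - mean(CT_ref1, CT_ref2))`; the arithmetic mean of two
reference CTs implements the geometric mean of their expression levels.

## Synthetic cytometry data

Fluorescence intensities are log-normal (right-skewed, log-displayed in
practice), parameterized so the distribution's true mean and CV match the
specification: `sigma^2 = ln(1 + (CV/100)^2)`, `mu = ln(mean) -
sigma^2/2`. Generators:

* single populations (n, mean, CV);
* channel pairs sharing one unit-mean log-normal biological factor plus
  independent unit-mean technical factors per channel — emulating two
  antibodies reporting an obligate heterodimer (CD8a/CD8b), where the
  per-cell ratio cancels biology and exposes technical noise;
* multinomially allocated, labelled mixtures;
* dual-reporter events: mCherry from its spec, eGFP = slope x mCherry x
  unit-mean log-normal residual, plus an untransduced fraction near a low
  autofluorescence floor (default mean 5, CV 40%) to exercise gating.

Defaults emulate the study conditions: technical CV 5% per channel with
biological CV 30% for the heterodimer control; a 20%/80% mixture at a
2-fold mean difference with 20% component CVs; a 10% low-mean contaminant
for unmixing. The dual-reporter mCherry distribution defaults to CV 200%
(mean 1000): retroviral transduction spreads reporter intensity over
roughly two decades, and a wide control-channel distribution is also what
makes the orthogonal slope statistically identifiable (see below).

Not modelled: instrument saturation, spectral spillover/compensation,
doublets, or autofluorescence outside the dual-reporter generator.
Passing tests therefore demonstrate correctness of the statistics on
clean log-normal populations, not robustness to instrument artefacts.

## Noise statistics

* `cv`: percent CV with sample (n-1) SD.
* `technical_noise_bound`: CV of the per-cell channel ratio; with 5%
  technical noise per channel the expected ratio CV is the log-normal
  composition of two independent factors, ~sqrt(2) x 5% ≈ 7.1%, and is
  invariant to the biological CV.
* `peak_channel_skew`: histogram on log-spaced bins (default 256; the
  analog of logarithmic cytometer channels); the peak is the modal bin and
  events in it count in neither tail.
* `mixture_cv_analytic`: law of total variance; e.g. 20%/80% at 2-fold
  mean difference with 20% component CVs gives 30.2%.
* `unmix_cv_curve`: computational removal of a scaled reference density.
  Mixture and reference are histogrammed on shared log bins; for removal
  fraction f the remainder is `max(H_mix - f N_mix H_ref / N_ref, 0)`.
  The CV uses the mixture's per-bin first and second moments weighted by
  the remainder, so f = 0 reproduces the exact sample CV; f = 0 is also
  special-cased to the unbinned value so the identity is exact to the
  last bit. Negative bins clip to zero; if the remainder mass vanishes
  the curve truncates with a warning. The removal fraction achieving a
  requested CV reduction is linearly interpolated along the curve.
* `compare_cv`: two-sided Welch (unequal-variance) t-test on
  per-replicate CVs.

## Reporter quantification

Double positives are gated by explicit thresholds (both channels strictly
above). The relative eGFP level is the slope of the total-least-squares
(orthogonal) line: the principal axis of the 2x2 covariance of (mCherry,
eGFP) through the centroid. No variance standardization is applied — the
channels share intensity units and the TLS slope is
standardization-dependent — and the fit is on linear intensities by
default, with a log-space option (`log_space=True`) for users who prefer
fitting the log-log dot plot; neither mode is privileged. Slopes
normalize to the empty vector (which is exactly 1 against itself), and
the de-repression ratio is microRNA-deficient over control normalized
expression.

TLS accuracy caveat: the generator puts the residual noise
multiplicatively on eGFP only, so the orthogonal fit carries a small
upward bias that grows with slope and residual CV and shrinks as the
control-channel spread widens. At the default mCherry CV of 200% the
expected recovery error stays within 10% over slopes 0.25–2 and residual
CVs 10–30% at n = 5000, with the worst corner (slope 2, residual 30%)
around +9%; with a narrow control channel (CV ~40%) the bias can exceed
50% and the fit should not be trusted. Degenerate inputs (a channel with
zero variance, fewer than 10 events) raise errors rather than returning a
slope.

## Pipeline

A single validated configuration (YAML/JSON; typed defaults; errors name
the field path) drives three suites — `ffl`, `noise`, `reporter` — plus a
`copies` subcommand for cloning-frequency tables. Outputs are delimited
text and JSON carrying the config hash, base seed and package version;
reruns with the same config and seed are byte-identical.

## Problem sizes

Default run sizes are 10,000 SSA runs per scenario, 10^5 events per
synthetic population, and 20,000 bootstrap resamples. The test suite uses
2,000-run ensembles for the FFL ordering checks (with the significance
threshold relaxed to p < 0.01, as the bootstrap floor scales with
ensemble and resample size) and 10,000-run ensembles for the birth-death
oracle.
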
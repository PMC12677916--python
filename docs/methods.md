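# Methods

`bcifes` re-implements, as a tested pipeline, the quantitative-EEG biomarker
and brain-network analysis used in closed-loop BCI-FES stroke rehabilitation
studies, together with the adaptive controller that couples motor-imagery
decoding to functional electrical stimulation, and the longitudinal
effect-size analytics applied to clinical score tables.  Because such studies
rarely deposit patient EEG or score data, the package ships synthetic
generators whose parameters *are* the study conditions, so every stage can be
verified end to end against known ground truth.

## Montage and preprocessing

The recording montage is a 24-electrode 10-20 cap: frontal (F3, F4, Fz, FC3,
FC4, FCz, FT7, FT8), central (C3, C4, Cz), parietal (CP3, CP4, P3, P4, CPz,
Pz), temporal (T3, T4, TP7, TP8) and the reference set (A1, A2) plus Oz.
Although Oz is wired in the cap's reference region, it is retained as an
occipital analysis channel; the analysis set is therefore the 24 labels minus
{A1, A2} = 22 channels, which is the dimension of every global average.

Sessions consist of two 5-minute eyes-closed recordings.  The fixed
preprocessing order is: (1) drop the final minute of each recording
(terminal-phase fatigue drift inflates slow-wave power), (2) 0.5-60 Hz
band-pass plus 50-Hz notch, (3) common average reference over the analysis
channels, (4) amplitude-threshold artifact handling, (5) segmentation into
contiguous 2-minute epochs — four per complete session, indexed 1-4 across
the concatenated recordings.

Filtering uses a 4th-order Butterworth applied forward-backward
(`sosfiltfilt`), doubling the effective order and cancelling phase
distortion; zero-phase filtering is required because downstream connectivity
is phase-based.  Artifact handling is a deliberate simplification: instead of
ICA (whose settings are rarely reported and which is hard to make
deterministic), 1-s windows in which any analysis channel exceeds +/-100 uV
are excised (default) or linearly bridged (`mode="interpolate"`), with every
rejection logged.  A fully rejected recording is flagged, never raised.  The
rejector is a plain function, so a different artifact strategy can be
substituted without touching the rest of the chain.

## Spectral biomarkers

PSDs are Welch estimates with rectangular 20-s windows and 5-s overlap
(windows advance 15 s; a 2-min epoch gives 7 windows).  The native bin
spacing is 1/20 s = 0.05 Hz; `nfft` exposes zero padding when a finer nominal
grid is wanted.  Band edges are half-open: delta 0.5-4, theta 4-8, alpha
8-13, beta 13-30, gamma 30-60 Hz (configurable; gamma is computed but enters
no ratio).

* **Band power** — rectangle-rule integral of the PSD over bins in
  [low, high), in uV^2.
* **Relative PSD** — each band's share of total 1-60 Hz power per channel;
  band masks are intersected with the evaluation range so a full partition
  sums to exactly 1.  Zero-power channels are reported missing, not 0.
* **DAR, DTABR** — delta/alpha and (delta+theta)/(alpha+beta) power ratios.
  Lower values indicate a shift toward faster oscillations and better
  cortical function post-stroke.  Per-channel ratios are always emitted; the
  *global* value is the ratio of channel-averaged powers rather than the
  average of per-channel ratios, because a ratio of means does not blow up
  on channels with near-zero alpha.  Both conventions are available, since
  published channel-level statistics do not always say which was used.
* **pdBSI** — pairwise-derived brain symmetry index over the eight
  homologous left/right electrode pairs.  The normalized form
  `|(R - L)/(R + L)|` per pair and frequency bin, averaged over bins then
  pairs, is used so the index is amplitude-scale-free and bounded in [0, 1]
  (0 = perfect interhemispheric symmetry).  The evaluation range defaults to
  1-25 Hz and is configurable; per-band variants restrict the bins to one
  band (the delta-band variant is the one usually plotted).

## Connectivity and network metrics

Phases are extracted per band by zero-phase band-pass filtering and the
analytic signal, with 1 s of edge transients discarded at each end.
Pairwise phase consistency uses the unbiased estimator
`(|sum_j e^{i d_j}|^2 - N) / (N (N - 1))` over phase-difference samples
`d_j`; its expectation is 0 for independent phases at any N, unlike
phase-locking value.  The ensemble is formed by pooling each epoch into
non-overlapping 2-s segments and taking one circular-mean phase difference
per segment (the segmenting is configurable; 2 s gives 59 samples per 2-min
epoch after trimming).  Slightly negative estimates are kept in the raw
matrix but floored at 0 before graph construction, since edge weights must
be non-negative.

Graphs are thresholded proportionally by default: the top 30% of the
n(n-1)/2 possible edges by weight are retained (69 of 231 edges on the
22-channel montage), ties broken deterministically by (i, j) order; absolute
thresholding is available.  Group comparisons must use equal density, since
most graph metrics are density-dependent.

Metrics on the thresholded weighted graph: node strength (sum of incident
weights); Onnela weighted clustering (geometric mean of triangle weights,
normalized by the maximum weight); local efficiency (global efficiency of
each node's induced neighbour subgraph); global efficiency (mean inverse
shortest-path length); characteristic path length (mean over *connected*
pairs, with the excluded-pair count reported, rather than substituting
infinities); and the small-world index sigma = (C/C_rand)/(L/L_rand)
against 100 (configurable, seeded) degree-preserving rewired surrogates.
Rewiring uses double edge swaps on the binary structure with the weight
multiset randomly reassigned to the rewired edges, so the degree sequence
and weight distribution are both preserved.  Path lengths map weights to
lengths as L = 1/w.

## Closed-loop controller

Motor-imagery decoding is CSP + LDA, both implemented from their linear-
algebra definitions with a scikit-learn estimator surface.  CSP covariances
are trace-normalized per trial and shrunk toward scaled identity
(coefficient 0.05 by default) to guarantee full rank on short trials;
filters are the generalized eigenvectors of `eig(C_a, C_a + C_b)`, with the
top and bottom `n_filters` kept and log-normalized variances as features.
The LDA weight vector is `S_pooled^-1 (mu_1 - mu_0)`; a singular pooled
covariance is ridge-regularized with a logged coefficient.

Sessions have 50 trials, the first 10 of which are calibration: they
establish the maximum classifier output, frozen for the rest of the session
so within-session decisions are stationary.  Feedback-trial scores are
normalized to percent of that maximum (clamped to [0, 100]); FES triggers
when the score reaches the adaptive threshold.  Per-trial correctness is
trigger-vs-cue agreement, and session accuracy is computed over the 40
feedback trials.

The threshold starts at 70% with dynamic range [55, 85] and moves in
5-percentage-point steps (the point reading matches the range arithmetic:
70 + 3x5 = 85): up after two *consecutive* sessions above 75% accuracy
(the counter resets when the step is taken or the streak breaks), down
immediately after a session below 60%, unchanged in [60, 75].  "Weekly"
updates are mapped to one update per simulated session (a configuration
knob allows k sessions per update).  Error-correction policies: a false
positive raises the artifact-rejection sensitivity one level (capped at 3);
a false negative widens the personalized alpha band from 8-12 to 7-14 Hz
(idempotent).

FES channel calibration replays a 200-uV, 10-Hz sine through the recording
chain (notch on, low-pass off, sensitivity 100 uV/cm — recorded in the
result) and adjusts the per-channel gain by multiplicative secant steps
until the measured amplitude is within 5% of target; a linear channel
converges in one step, and a saturating channel yields a failure result
with the full measurement trace.

## Synthetic data

**EEG.**  Each channel is a sum of band-limited oscillators, a 1/f
background, common 50-Hz line noise, and frontal ocular transients.
Oscillator amplitudes are RMS in uV, so a lone component of amplitude `a`
contributes band power `a^2` uV^2 (equivalently, the peak-amplitude
`peak^2/2` sinusoid convention).  By default carriers are narrowband-
filtered Gaussian noise, so pairwise phase consistency between channels is
tunable through mixing ratios (mix 1.0 makes two carriers identical and
drives PPC to 1); `bandwidth = 0` gives a pure random-phase tone for
closed-form spectral tests.  Ocular artifacts are 0.8-s raised-cosine bumps
(~300 uV) on frontal channels — enough to exercise rejection logic, with no
claim to oculomotor realism.  Defaults: 250 Hz sampling (configurable;
every stage reads the rate from the recording, never a constant), 5-min
recordings, posterior alpha / frontal-midline theta / central beta over a
4-uV 1/f floor.  Identical (config, seed) pairs are bit-reproducible.

**Cohort.**  Three arms (BCI-FES, FES, control; 12 patients each by
default, sizes configurable) with baseline scores FMA ~ N(19.2, 10.1),
MBI ~ N(51.9, 12.3), MoCA ~ N(15.4, 4.0), and per-arm change-from-baseline
distributions at five follow-ups (G2: 1 month ... G6: 4.5 years).  The
BCI-FES arm's final FMA effect is mean 4.5 with SD 3.75 = 4.5/1.2, so the
configured truth has paired Cohen's d = 1.2; FES (1.7, SD 4.25) and control
(0.9, SD 4.5) are set the same way, as are MBI effects (5.4/d=1.1, 2.2,
1.3).  MoCA follows a rise-and-regress trajectory peaking at G4 (+1.6) and
returning toward baseline by G6.  Each patient draws one latent severity
per metric shared across time points (`delta_t = mean_t + sd_t * z`), so
trajectories are coherent while arm-level moments match the configuration
at every time point.  Scores are clamped to instrument ranges (FMA-UE 0-66,
MBI 0-100, MoCA 0-30) *after* noise addition and clamp events are counted,
because clamping biases extreme-effect recovery.  By default there is no
covariate-outcome coupling (`profile_effect = 0`), so arm-level delta
distributions are exactly the configured ones; setting it nonzero gives
patients matching the responder profile (age < 70, onset < 23 months,
baseline MBI > 40) a delta-FMA bonus, which is how responder classification
is exercised.

**EEG-outcome coupling.**  For each patient the true post-minus-pre Cz
theta power is `8 + 6 * (rho * z + sqrt(1 - rho^2) * eps)` uV^2 around a
pre power of 18 uV^2, where `z` is the patient's *realized* standardized
delta-FMA and `eps` is independent noise; the latent correlation is exactly
`rho` (default 0.68) regardless of clamping upstream.  The shipped coupling
configuration uses 60-s, 3-channel (C3/Cz/C4) recordings with a 2-uV
background: only Cz theta carries the outcome signal, the short duration
still allows three 20-s Welch windows, and the chosen power-change SD keeps
Welch estimation noise small relative to the signal so pipeline recovery
attenuates the correlation by only a few percent.

## Cohort analytics

Change scores are post minus pre, missing values excluded with counts.
Cohen's d is implemented in both flavors — independent (pooled SD,
(n-1)-weighted) and paired (SD of differences) — and every report carries
the flavor tag; arm-level longitudinal summaries default to paired
within-arm.  Correlations are Pearson or Spearman with a Shapiro-Wilk gate
in `auto` mode and Fisher-z confidence intervals.  Responder analysis
labels patients with delta-FMA >= 5 (inclusive) as high responders and
predicts response by the conjunctive threshold profile; the reported
headline is the profile's sensitivity on synthetic cohorts, since the real
covariate joint distribution is not available.  The Sobel mediation
statistic is `a*b / sqrt(b^2 se_a^2 + a^2 se_b^2)`.  Group comparisons are
normality-gated one-way ANOVA vs Kruskal-Wallis (scipy routines) with
pairwise follow-ups Bonferroni-adjusted as min(1, m*p) within each
metric x timepoint family.

## Numerical choices and problem sizes

Welch uses `detrend=False` so Parseval holds exactly; proportional
thresholding breaks ties lexically; PPC segment pooling uses circular
means; surrogate rewiring is seeded; the FES loop counts *adjustment*
steps, so a channel already in tolerance reports zero iterations.
Verification runs use sizes chosen to keep Monte-Carlo error well inside
the asserted tolerances: 10,000 patients for mean-effect recovery
(SE ~ 0.04 FMA points), 50 x 1,000 for paired-d recovery, 20 x 200
patients for full-pipeline coupling recovery, 500 random graphs of <= 8
nodes against brute-force metric oracles, and 100 x 200-sample ensembles
for the PPC null.

## What passing tests do and do not show

The generators emulate the *statistical structure* of resting EEG and of a
three-arm trial — band-structured spectra, tunable phase coupling, 1/f
background, configured effect sizes and couplings — not volume conduction,
electrode artifacts beyond ocular transients, non-Gaussian score
distributions, or real covariate-outcome joint structure.  Passing
parameter-recovery tests therefore shows the pipeline is correct and
unbiased under known ground truth; it does not validate the clinical
effect sizes themselves, which come from patient data the package does not
have.  The epoch labelling of published results ("epoch 1/epoch 3" of
5-min recordings) cannot be mapped unambiguously onto the four 2-min
session epochs defined here; this module's indices 1-4 are the documented
contract.  The c / gLoE / L / LocE excitation metrics and random-forest
outcome models are out of scope.
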
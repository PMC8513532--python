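# Methods

This note documents the models, parameter choices and numerical decisions
behind the pipeline, and what the synthetic-data tests do and do not show
about real recordings.

## Synthetic dual-brain generator

**Source model.** Each brain's 14 region series follow a stable order-2
vector autoregression. The condition-independent skeleton gives region *i*
a damped oscillator with poles at radius 0.85 and centre frequency
15 + 2·i Hz (15–41 Hz across regions), so the 13–50 Hz analysis band
carries genuine autoregressive power everywhere. Condition-specific
directed edges are added as lag-1 cross-coefficients (defaults: 0→13 and
4→13 at 0.25 in TeamFlow, making region 13 — the marker-region analogue —
an information sink). Stability (companion spectral radius < 1) is checked
before simulation; unstable configurations raise.

**Condition effects and their units.**

| effect | default | unit / meaning |
| --- | --- | --- |
| ERP attenuation | TeamFlow 0.3, FlowOnly 0.6, TeamOnly 1.0 | multiplies the evoked template during play; rest is always 1.0 (flow only exists during play) |
| band-power offset | +2 dB at (TeamFlow, region 13) | gain of a per-region band-limited (13–50 Hz) component, `band_component_amplitude` = 0.5 at 0 dB |
| intrabrain coupling | 0→13, 4→13 @ 0.25, TeamFlow only | lag-1 VAR cross-coefficient |
| interbrain coupling | TeamFlow 0.8, others 0 | amplitude of a shared band-limited component, in units of the receiving region's SD, added to every homologous region pair |
| noise | innovation SD 1.0, sensor noise SD 0.3 | — |

The shared interbrain component is added at zero lag by default: this
maximises both phase locking and integrated information of the coupled
pair (empirically, lagged variants weaken the φ effect because the
down-sampled binarized states lose the offset alignment); an optional lag
is exposed. The component is scaled by the receiving region's empirical SD
so the coupling knob reads as a fraction of signal amplitude.

Because the interbrain component touches every region pair, TeamFlow also
gains broadband 13–50 Hz power at every region; the +2 dB marker-region
offset rides on top of that. Recovery tests that need an isolated
band-power effect therefore switch the interbrain coupling off in their
study configuration.

**Evoked template.** Triphasic (negative–positive–negative) waveform built
from three signed Gamma-shaped bumps (shape 40) with modes near
130/230/330 ms; the ~100 ms deflection spacing confines its energy to the
θ band. Peak amplitude 1.0.

**Events.** Beep-train onsets start ~1–2 s into the trial and advance with
uniform 4–8 s gaps, labelled rest/play by phase; a train is 5 beeps at
5 Hz. All randomness flows from one root seed through named substreams
(`SeedSequence([seed, pair, song, condition])`), so any single trial is
reproducible in isolation and studies are lazily materialised.

**What the generator does not emulate:** scalp biophysics and volume
conduction (the sensor step is a fixed random mixing matrix with unit
diagonal for the 14 "central channels"), artifacts (blinks, EMG, line
noise), non-stationarity within trials, 2048 Hz acquisition (data are
generated at 256 Hz directly), and realistic inter-subject variability.
Passing recovery tests therefore demonstrates correctness of the analysis
chain under the stated generative model, not robustness to real-EEG
nuisance structure.

## Preprocessing

The 0.5–50 Hz band-pass is an equiripple (Parks–McClellan) design built as
a cascade of a high-pass at the low edge and a low-pass at the high edge
(a single band-pass exchange with a 0.5 Hz transition at a 256 Hz rate
does not converge reliably); tap counts follow the Harris rule for the
40 dB spec. Filtering is forward–backward, which squares the magnitude
response — each half-design then only needs half the stopband attenuation
in dB — and keeps evoked latencies unshifted. Epoch windows are half-open
`[start, end)`, so the 1.5 s AEP window is exactly 384 samples at 256 Hz
and the 3 s NC window exactly 768. A polyphase anti-aliased decimator is
provided for 2048→256 Hz reuse on real data but is outside the synthetic
path. θ-band (3–7 Hz) filtering for the evoked analysis is applied to the
continuous series before epoching (the 1.5 s epochs are shorter than the
zero-phase filter's settling length).

## Flow-depth statistic

Time–frequency maps use Morlet wavelets with frequency-adaptive width
(≈2.5 cycles at 3 Hz up to 7; the low end is trimmed so the 5σ support
fits the 1.5 s epoch). ERSP baseline is mean pre-onset (−0.3–0 s) power
per frequency. Channel selection keeps central channels with inter-trial
coherence not below mean − SE over the central set (SE = sd/√n, SE ≡ 0
for a single channel; ties at the threshold retained). Peak search
sub-windows are 0–180 / 150–300 / 280–450 ms; a flat response raises
rather than returning arbitrary latencies.

## Band power and topography

Welch segments are half the epoch with 50% overlap and a Hann taper,
detrended per segment. Normalization subtracts the per-song
three-condition mean on the per-bin dB spectrum before band-averaging;
since both operations are linear the per-bin and per-band orders give
identical values. The topography statistic is a per-unit one-way F across
conditions with a within-participant label-shuffling null (one shared
permutation per participant preserves the spatial correlation structure),
add-one p-estimates (floored at 1/(1+n_perm)), and Bonferroni correction
across units; 2000 permutations by default, seeded.

## Clustering and region groups

Complete-linkage agglomerative clustering on Euclidean distance over the
3-condition feature vectors; labels are canonicalised by order of first
appearance so the partition is input-order invariant. Family
classification scores each family by its defining margin — teamflow:
TeamFlow above the rest; flow: TeamOnly above the rest; team: FlowOnly
below the rest — and takes the largest positive margin (precedence
teamflow > flow > team on exact ties; no positive margin → unresolved).
This margin form is robust under noise near all three archetypes, where a
strict-maximum rule misclassifies about half the time. ROI subdivision
uses a ≥ 20% family-fraction rule (configurable); sub-threshold family
vertices are absorbed into the largest subdivision so subdivisions always
partition the ROI. The cumulative-composition curve this stands in for is
not algorithmically specified anywhere we could follow; the fraction rule
is the declared operationalisation.

## MVAR causality

The Vieira–Morf lattice (multichannel Burg with Cholesky-normalised
reflection coefficients) fits each 500 ms window, pooling same-condition
epochs (ensemble fitting); 25 ms steps round down to 6 samples at 256 Hz.
Order minimises AIC = N·ln|Σ̂| + 2pd²; with d = 14 channels the 2pd²
penalty makes spurious extra orders rare, and the default cap is order 3
for the short windows. Validation reports the companion spectral radius,
percent consistency (distance between data and model-simulated
auto/cross-covariance structure), and a multivariate Ljung–Box
portmanteau p-value (mildly conservative at these lengths: ~2–5%
rejections at α = 5% on true-model residuals).

Spectral measures from Ā(f) = I − Σₖ Aₖ e^(−i2πfk/fs), H = Ā⁻¹,
S = HΣH\*: nPDC is the squared column-normalised Ā entry (per-source unit
sum across targets); dDTF is the full-frequency DTF times the squared
partial coherence from S⁻¹; GGC is ln(S_ii / (S_ii − σ̃_jj|H_ij|²)) with
the partial residual-variance correction σ̃_jj = Σ_jj − Σ_ij²/Σ_ii. The
"top senders" rule retains edges above the (1 − 0.10) quantile of the log
to/from values, with lexicographic tie-breaks at the boundary and an empty
result for all-equal inputs; the retain fraction is configurable.

## Integrated information

Binarization is strict ("rising" = next sample strictly greater); ties
count as off. Down-sampling factors 5/10/15/20 at 256 Hz give the four
step rates (51.2–12.8 Hz); TPMs pool all shifts and all trials, and φ is
reported per factor and averaged over the four, since no combination rule
is otherwise fixed. The factorized model cuts both cross connections: each
node is conditioned on its own state with the partner marginalized under
the stationary conditional (uniform fallback on zero-mass margins). The
stationary weighting is canonical and deterministic: 64 burn-in power
iterations from the uniform distribution, then a 64-step Cesàro average —
defined for every row-stochastic matrix, including periodic and reducible
ones. Within rows of positive stationary mass the factorized distribution
dominates the joint, so the KL divergence is finite; rows of zero mass
contribute nothing. φ = 0 exactly for node-independent products, and φ
grows monotonically with cross-coupling in the parametric copy family.
Unvisited TPM rows get a uniform placeholder and mark the φ value
low-confidence. This operational φ is not claimed to equal IIT-3.0
toolbox big-Φ; the zero-iff-independent and monotonicity properties are
the contract.

Condition normalization is value − mean over the three conditions (so
larger raw values stay larger after normalization); the alternative
mean − value reading of the verbal description would invert every figure's
ordering, so the subtraction is fixed this way and shared between the II
and PLV stages.

## Phase synchrony

Morlet wavelets on a 13–50 Hz grid at 1 Hz, 5 cycles at 13 Hz scaling
linearly to 9 at 50 Hz; samples within one wavelet half-support of either
epoch edge are excluded from the time average. Single-trial PLV is the
modulus of the time-averaged phase-difference phasor, then the unweighted
band mean. Random pairings are seeded derangement permutations of the pair
indices (no participant keeps their actual partner), matched on condition
and song, 10 schemes by default; phase series are cached per trial so the
schemes reuse them.

## Statistics

Friedman uses the tie-corrected rank statistic with the χ² reference;
Conover post hoc compares rank sums with pooled rank variance on
(n−1)(k−1) df, Bonferroni-corrected, and degenerates gracefully (perfect
unanimous ordering → perfect separation; fully tied data → p = 1, and no
pair is ever declared significant when the omnibus saw nothing).
Repeated-measures ANOVA decomposes sums of squares by inclusion–exclusion
over factor subsets, testing each effect against its interaction with
subject — the standard univariate analysis, no sphericity correction by
default — and reports partial η²; it matches pingouin (one/two-way) and
statsmodels AnovaRM (three-way) to machine precision on balanced data.
Note the proper within-subject error df, (k−1)(n−1), is used throughout;
between-observation df formulations are not reproduced. Spearman CIs are
seeded percentile bootstraps (2000 draws); dependent-correlation
comparison bootstraps participants jointly. The psychometric team-flow
index defaults to the mean of the flow and team indices; the plain Q1–Q9
mean (which weights flow questions 2:1) is available by flag.

## Problem sizes

The committed test and reproduction runs use shortened studies — 2–3
pairs, one song, 15–40 s play phases — and the recovery experiment sizes
stated in their docstrings (100 causality seeds at n = 2000; 20 study
seeds × 20 participants for AEP monotonicity; 20 study seeds for the
interbrain recovery; 700 vertices; 1000 null simulations; the full 35⁴
coarse-grid φ enumeration). These sizes were chosen as the smallest at
which the checked properties are stable across seeds; all stage
parameters (windows, bands, factors, permutation counts) remain at their
full-study defaults.

## Known limitations

* Sensor-level analyses use the reduced 32-sensor synthetic montage; no
  real electrode geometry, bad-channel handling, or artifact rejection.
* Source estimation is out of scope: region series are generated directly,
  and the vertex-level clustering path runs on synthetic vertex features.
* GGC uses the pairwise-conditioned spectral form, exact for bivariate
  systems and an approximation above d = 2.
* The permutation topography assumes a balanced design; unbalanced studies
  raise rather than reweight.
* φ is a two-node measure; larger sub-systems are not decomposed.
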
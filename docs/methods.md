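# Methods

## The task and its generative rules

Each of 180 trials displays one face-up card per deck (A–D), its value
drawn from the arithmetic sequence {0, 5, …, 100} (21 values). Display
constraints: deck A's value differs from deck B's and deck C's from deck
D's within a trial (those pairs share payoffs), and no deck repeats its
value on consecutive trials. Choosing a deck reveals a second card,
modelled as uniform over the 20 universe values different from the shown
one, so ties are impossible by construction; the trial is won when the
first card is strictly larger. Decks A and B pay +100/−125 points, C and D
+50/−25, making A/B the high-variance pair at every card value.

The win probability of a shown value x is therefore exact:
P(win | x) = (#values < x)/20 = (x/5)/20, from 0 at x = 0 to 1 at x = 100.

First-card values in generated sequences are uniform over the admissible
set (rejection sampling against the constraints). The original study used
one fixed pseudo-randomised sequence shared by all participants and never
published it; its empirical value distribution was evidently not uniform
(see "Known limitations"). All generators are deterministic under a seed.

## The decision model

With scaled payoffs W (win) and L (loss magnitude) and win probability p:

    r̂    = pW − (1−p)L                  reward prediction
    Risk = p(1−p)(W+L)²                 risk prediction (two-outcome variance)
    U    = r̂ + l·Risk                   mean–variance utility
    P_i  = exp(U_i) / Σ_j exp(U_j)      softmax choice rule (no temperature)
    H    = −Σ_i P_i ln P_i              choice difficulty (entropy, nats)

`l ∈ [−1, 1]` is the subject's risk preference: negative values penalise
variance (risk aversion), positive values reward it. The linear
mean–variance form is the standard formulation of the framework this model
follows; risk may optionally enter as a standard deviation
(`ModelParams(risk_as_sd=True)`), off by default. Probabilities are fully
determined by the displayed card, so nothing is learned across trials.

### Payoff scaling

Points are divided by `payoff_scale` before valuation. Because the softmax
has no temperature parameter, this scale is the only thing that sets how
deterministic choices are: raw points (scale 1) saturate the softmax, very
large scales make all four probabilities indistinguishable from ¼. The
default is 125 (the largest payoff magnitude), which puts utilities on an
O(1) scale where `l` is identifiable from 180 trials.

Sensitivity of two headline quantities to the scale (measured with this
package; 30–200 datasets per cell, 180 trials each):

| scale | random-agent fitted MLL (nats/trial) | recovery bias, worst true l |
|------:|-------------------------------------:|----------------------------:|
| 100   | 1.481 | ≤ 0.05 |
| 125   | 1.448 | ≤ 0.05 |
| 150   | 1.433 | ≤ 0.05 |
| 200   | 1.411 | 0.19 |
| 250   | 1.402 | 0.31 |
| 500   | 1.391 | 0.59 |

The published benchmark for random data is MLL ≈ 1.39 ≈ ln 4, which this
generator only reaches at scales where `l` becomes nearly unidentifiable
(sd(l̂) ≈ 0.6–0.9 at 180 trials). No single scale reproduces both the
random-data benchmark and usable parameter recovery under a uniform
stimulus sequence; the default favours recovery, and the ≈ +0.06 nats/trial
offset of the random-agent MLL is reported as-is. The most plausible
reconciliation is the original study's unpublished, non-uniform stimulus
sequence (its non-uniformity is independently visible in the reported
total scores) and/or an unstated normalisation convention.

## Maximum-likelihood estimation

The only free parameter is `l` (k = 1). The summed log-likelihood of the
observed choices is maximised over [−1, 1] by an even grid of 1000 steps
(1001 points, so l = 0 is on the grid) followed by 4 seeded golden-section
refinements drawn from the top grid neighborhoods, plus one from the best
neighborhood. Each trial's log choice probability is a log-softmax of
utilities affine in `l`, hence concave; the summed likelihood therefore has
a single maximum and the grid+refinement search is globally exact (the
acceptance suite verifies agreement with a 100,001-point dense grid to
within one grid step). Numerically equal optima tie-break toward the
smallest |l|.

Fit quality is reported at per-trial scale, with information-criterion
penalties taken at the size M of the comparison group:

    MLL  = −LL/n                       (nats/trial; uniform data give ln 4 ≈ 1.386)
    AIC  = 2k + 2·MLL
    AICc = AIC + 2k(k+1)/(M−k−1)
    BIC  = k ln M + 2·MLL

This group-size convention is unusual (conventional criteria use the
per-dataset trial count) but is the one the published benchmark numbers
follow: with M = 1000 random datasets, BIC − 2·MLL = ln 1000 ≈ 6.91 and
AICc − AIC = 4/998, both matching the printed table. M is always an
explicit argument. Argmax prediction accuracy breaks ties toward the
lowest deck index; for uniform-random choosers its expectation is exactly
25% (the choice is independent of the argmax deck).

## Synthetic cohort

Defaults emulate the study conditions: 30 subjects; NS scores integer in
[0, 34] from a latent normal with mean 14.57, SD 3.81 (rounded, clipped);
risk preference with mean −0.15, SD 0.27, clipped to [−1, 1]; latent
NS–l correlation 0.555. Each correlated quantity q is built from one
standard-normal NS factor as ρ·z_NS + √(1−ρ²)·ε; the achieved sample
correlation is reported, never forced. Behaviour comes from softmax agents
at each subject's true l.

Task BOLD: 3 runs of 7 min at TR 2 s (210 volumes each). Run layout
30 s rest + 3 × (20 trials × 5 s + 30 s rest) = 420 s; trials have no
inter-trial interval (4 s choice + 1 s outcome), with modulated impulses at
choice onset. Each ROI series is baseline 100 + β_risk·X_risk +
β_reward·X_reward + β_entropy·X_entropy + AR(1) noise (ρ = 0.3, marginal SD
1.0). β_risk is drawn per subject with mean 1.0, SD 0.5 and latent
correlation −0.51 with NS; β_reward = 0.5 and β_entropy = 0.3 are constant.
The SD 0.5 / noise 1.0 combination yields a subject-level estimation SE of
≈ 0.24 for β_risk, i.e. ≈ 0.90 attenuation of the NS–β correlation — large
enough to matter, small enough that the generating sign survives at n = 30.
Small random-walk head drift (step SD 0.01 mm) keeps the six motion
regressors non-degenerate.

Resting state: 240 volumes at TR 2 s, multivariate Gaussian with a
per-subject 4×4 target correlation (base 0.3 off-diagonal). The
r-PI–r-striatum and r-PI–l-AI couplings are NS-modulated (latent
correlation −0.511, mean 0.45, SD 0.15, clipped to [0.05, 0.85]; a PSD
guard repairs marginal matrices by eigenvalue clipping). Motion spikes
(Poisson, mean 1 per subject; 0.6–1.2 mm one-volume excursions) are
recorded in the motion table and mirrored as shared signal artifacts, so
scrubbing is actually exercised.

What the generator does **not** emulate: image space (ROIs are time series,
not voxels), physiological noise structure beyond AR(1)/band-limited
Gaussian, the TPQ item level, reaction times, and the original fixed
stimulus sequence. Passing tests therefore show that the analysis chain
recovers known ground truth under its own stated noise model — not that it
would reproduce the original human data.

## GLM

Single-gamma HRF h(t) = (t/(pq))^p e^(p−t/q), defaults p = 8.6, q = 0.547
(unit peak near 4.7 s, < 1% of peak by 15 s); parameters configurable since
only the kernel family is conventionally fixed. Parametric modulators are
the *chosen* deck's risk and reward predictions plus the trial entropy,
mean-centered within run (decoupling them from run baselines), convolved at
dt = 0.1 s and sampled on the TR grid. Orthogonalisation beyond
mean-centering is deliberately not applied. The fit is OLS with classical
standard errors; "z-transformed β" is implemented as β/SE from the
subject-level fit. Rank deficiency raises an error naming the implicated
columns. Analysis regressors are rebuilt from each subject's *fitted*
model, as in the original procedure, not from the generating parameters.

## Resting-state connectivity

Cleaning order: linear+quadratic detrend → regression of the six motion
parameters (themselves detrended) → FD scrubbing mask → linear
interpolation across masked volumes → zero-phase FIR band-pass
0.01–0.08 Hz → optional white-matter/CSF nuisance regression → masked
volumes dropped → Pearson r per ROI pair → Fisher z = atanh(r).

FD follows the backward-difference convention: Σ|Δtranslation| +
Σ|Δrotation| converted to arc length on a 50 mm sphere (the method's
standard radius; configurable). Volumes with FD > 0.5 mm are scrubbed; a
series losing more than half its volumes is rejected outright.
Interpolation-before-filtering prevents spike energy from smearing through
the filter; filtering the raw gaps instead is selectable
(`interpolate_scrubbed=False`). The band-pass is a 79-tap Hamming-window
FIR applied forward-backward (zero phase), with the kernel's DC gain forced
to exactly zero; 79 taps respects the forward-backward padding limit at 240
volumes while giving > 20 dB stop-band suppression at twice the band edges.

## Group statistics

Pearson correlations with two-tailed t-based p-values; first-order partial
correlation via the closed form r_xy·z = (r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²))
on n−3 df (verified against the residual-residual identity and an
independent implementation); Sobel mediation with path a from OLS of M on
X and path b from OLS of Y on M controlling X, z = ab/√(b²SE_a² + a²SE_b²)
— known conservative at small n, which the null-simulation test confirms.
Bonferroni families: 4 activation ROIs (α 0.0125), 4 partial correlations
(α 0.0125), 6 connectivity pairs (α 0.0083). The mediation direction
(X = activation, M = risk preference, Y = NS) is an analysis choice exposed
as arguments, not hard-coded.

## Pipeline

`run_pipeline(PipelineConfig(seed=...))` derives every stage seed from the
global seed (task sequence, cohort, random agents, search restarts), so
identical configurations give byte-identical reports. Stages: cohort →
per-subject MLE → random-agent comparison table → per-subject GLM → NS
correlations, partial correlation and Sobel mediation for the focal ROI
(r-PI) → per-subject rsFC → NS–connectivity correlations. Problem sizes
used by the default configuration and the test suite: 200 random-agent
datasets for the benchmark table (the original used 1000; the group-size
convention still uses M = 1000), 200 agents per condition for parameter
recovery, 100 seeds for the end-to-end sign-recovery check — sizes chosen
to keep the whole suite comfortably reproducible on a laptop while holding
Monte-Carlo error well below every tolerance asserted.

## Known limitations

- The original stimulus sequence is unpublished; participant-level numbers
  (total scores, 90.5% prediction accuracy, MLL 0.31) depend on it and on
  raw data that were never deposited, and are not reproduction targets.
  Note the human column (MLL 0.31, accuracy 90.5%) and the random column
  (MLL 1.39 ≈ ln 4) jointly constrain the temperature-free softmax in ways
  a uniform-sequence replica cannot satisfy at any single payoff scale:
  near-uniform fitted probabilities on random data and sharply peaked
  probabilities on human data are mutually exclusive in this family. See
  the payoff-scaling section.
- The supplementary "directed mediation analysis" of the original study is
  not publicly specified; the standard Sobel/Baron–Kenny chain stands in.
- Voxel-space preprocessing, whole-brain cluster inference, anatomical
  segmentation, and Talairach coordinates are out of scope; named ROIs are
  synthetic time-series channels.
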
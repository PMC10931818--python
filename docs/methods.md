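# Methods note

This note records the modeling choices, parameter calibrations, and numerical
conventions behind `danseq`. The package analyzes single-forelimb lever-press
sequence behavior recorded together with single-photon calcium imaging of SNc
dopaminergic neurons, and ships a synthetic-data generator whose defaults are
the study conditions the analyses were designed for.

## Task and behavioral model

Mice press a lever with one forelimb under a fast fixed-ratio schedule:
4 presses completed within 1 s earn a reward (FR4/1 s), putting the target
inter-press interval at `window / (n_required - 1) = 0.333 s`. Presses are
organized into *bouts*: maximal runs of presses made while the animal's snout
occupies a region of interest at the lever. Bout lengths are grouped as
(≤2, 3, 4, 5, 6, 7+) and mapped to ordinal ranks 1..6 for rank statistics.
Sessions alternate lever side day to day; "contra"/"ipsi" always refers to the
forelimb relative to the imaged (or lesioned) hemisphere.

Session metrics follow the usual operant summaries: presses/min, the fraction
of presses inside multi-press bouts, mean presses/sequence, and within-bout
inter-press-interval mean and Fano factor (sample variance / mean).

## Neural model

Traces are z-scored per neuron per session using the population standard
deviation (`ddof=0`; a two-sample row `[0, 2]` maps to `[-1, 1]`). Peri-event
time histograms (PETHs) span −8..+6 s around an event in 0.1-s bins (140
bins); bins −8..−3 s are the baseline. A neuron is positively modulated in a
test window when ≥2 consecutive bins of its mean PETH exceed the 99th
percentile of its own baseline bins (negative modulation symmetrically with
the 1st percentile). Classes per neuron/condition:

- **movement initiation** — modulated in (−2, 0) s before the bout's first press;
- **execution** — modulated in (0, +1) s after the first press but not before it;
- **reward** — modulated in (0, +1) s after the first rewarded lick and not
  in the 2 s before it;
- **magazine approach** — modulated in the 2 s before the rewarded lick
  (a ramp during approach to the reward magazine).

Peak activity is the maximum of a centered 3-bin moving average within a
window, with the average truncated at the window edges.

## Statistics

All hand-rolled tests use classical conventions: pooled-variance t tests;
two-sided Fisher exact tests; Spearman correlations with mid-ranks and an
exact permutation p-value for n ≤ 8; a fully within-subject 2×2
repeated-measures ANOVA computed by explicit sums-of-squares decomposition,
with each effect tested against its own subject-by-factor error term and
Šídák-adjusted paired post hocs; a post-ANOVA linear-trend contrast with
equally spaced coefficients, `F = SS_contrast / MSE` on (1, N − k) degrees of
freedom, with missing cells dropped; correlations averaged on the Fisher-Z
scale (`tanh(mean(atanh r))`, with ±1 clipped to ±(1 − 1e−6)); and a
two-sided hypergeometric test for whether the overlap of two neuron
populations departs from independent membership (summing the probabilities of
all overlaps at most as likely as the observed one).

Cross-session ROI matching is mutual-nearest-neighbor on centroids with a
5-px distance gate, resolved greedily by ascending distance so it is
one-to-one. Functional stability of a matched ROI is the maximum Spearman
correlation of its event-aligned PETHs over up to four events, Fisher-Z
averaged over session pairs, compared against a circular time-shuffle control
(random rotation of ≥10 bins) and the best-correlated non-matched ROI of the
same animal; the three groups enter a repeated-measures one-way ANOVA on
Fisher-Z values with Tukey comparisons on the within-ROI error term.

## Synthetic generator

The generator reproduces the study design end to end, so every analysis can
be exercised on data with known ground truth. Defaults are the study
conditions; they were fixed from cohort-level values and were not adjusted
afterwards.

**Behavior.** 6 imaged mice, one session per forelimb, 1800-s sessions at
3 bouts/min. Bout lengths are shifted-Poisson on 1..12 (mean 4); within-bout
IPIs are lognormal (median 0.30 s, σ = 0.30). Rewards follow the FR4/1-s rule
at the press completing the first qualifying run. The animal then travels
from the lever to the reward magazine; the first rewarded lick occurs a
lognormal latency after reward (median 2.5 s, σ = 0.6). This latency is
deliberately slow and heavy-tailed: the magazine sits away from the lever, so
press-related transients fall neither in the 2-s pre-lick classification
window nor pile up at a fixed offset inside the lick-aligned baseline window.
Bouts (or licks) whose full ±8/+6-s peri-event window would leave the session
are dropped.

**Neurons.** 101 neurons across the 6 mice. Movement-initiation membership is
an independent Bernoulli draw (p = 0.39). Reward (p = 0.37) and magazine
approach (p = 0.15) are alternative shapes of the same lick-aligned response
— a post-lick transient versus a pre-lick ramp — so they come from one
categorical draw and are mutually exclusive; movement remains independent of
both, which is the premise of the overlap-vs-chance analysis. Execution
responses are independent (p = 0.10).

Transients are GCaMP6f-like double exponentials (rise 0.08 s, decay 0.4 s) on
unit-variance Gaussian noise. Amplitudes are specified on the trial-averaged
PETH-peak scale — the scale on which peak activity is measured — and
converted to per-event kernel amplitudes by dividing by the kernel smearing
factor induced by onset jitter (0.43 for the default movement jitter of
−1.5..−0.3 s before the first press). Defaults: movement 0.646 z contra /
0.427 z ipsi with between-neuron lognormal CV 0.55; reward 1.0 z (CV 0.45);
magazine 1.49 z contra / 0.66 z ipsi (CV 0.60); per-event lognormal jitter
σ = 0.2. A 27% subset of contralateral movement neurons are *length coders*
whose amplitude gains 0.31 z per length-group rank (anchored at the 4-press
group); the gain was calibrated so the population linear-trend F on the
neuron × length-group matrix has magnitude ≈20 given the coder fraction and
unit trial noise.

**ROI geometry.** Centroids are rejection-sampled ≥10 px apart in a
200-px field of view, jittered by 1 px per session; each ROI is recovered per
session with probability 0.62, chosen so that the expected fraction of
twice-detected ROIs that are detected in all three sessions,
`q / (3 − 2q)`, matches the observed 35.1%.

**Lesion cohort.** 8 lesioned and 6 saline mice, before/after × limb cell
means (contra 4.12→2.17, ipsi 4.13→3.52 presses/sequence for the lesion
group; 3.40→2.73 and 3.06→2.46 for saline). Per-mouse dispersion is a shared
Gaussian shift (σ = 0.58, from the printed per-cell SEMs) plus an independent
per-cell departure (σ = 0.57, back-solved from the reported interaction F on
7 denominator degrees of freedom); cell means are floored at 1.05 presses.

**Fast samplers.** Power and calibration studies use direct samplers for the
quantities each test consumes (per-neuron peaks at the printed means and
SEMs, per-bout activities, per-mouse lesion cell means, centroid maps, stable
PETH tuning with session noise matched to the observed matched-pair
correlation ≈0.68, and exchangeable-null PETHs), avoiding the full trace
simulation where it adds nothing.

**Known limits.** Bout onsets sit on a jittered regular grid rather than a
self-paced point process; licking is reduced to the single first rewarded
lick; execution transients are placed uniformly within the bout rather than
press-locked; ROI shapes are not modeled (matching is centroid-only); and
photobleaching, neuropil contamination, and motion artifacts are out of
scope. One measured consequence: a movement neuron's press transient lies in
the lick-aligned baseline window, which slightly raises that neuron's
modulation threshold and gives a small classifier-induced negative dependence
between recovered movement and reward labels (recovery of a planted reward
response: 0.84 with a movement response present vs 0.93 without). The
overlap-vs-chance test still reads chance-consistent in ≈95% of default
cohorts.

## Numerical conventions

- Sample (n−1) variance everywhere except trace z-scoring (population sd).
- PETH bins are left-closed `[t0, t0 + 0.1)`; bin width must be an integer
  number of samples at the trace sampling rate.
- Exact Spearman permutation p-values compare `|rho|` with a 1e−12 tolerance;
  the hypergeometric two-sided sum uses a `1 + 1e−9` relative tolerance on
  the observed probability mass.
- Degenerate t tests (zero variance, equal means) return statistic 0 and
  p = 1 flagged `degenerate`; zero variance with unequal means raises.
- All cohort randomness flows from one integer seed through
  `numpy.random.SeedSequence` spawning; derived seeds are reduced mod 2³¹.
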
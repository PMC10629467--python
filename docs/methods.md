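# Methods

## The analysis problem

Intraoperative multichannel EEG is summarized at two complementary levels.
At the topographic level, the scalp field at any moment is treated as one
of a few quasi-stable microstate classes; the dynamics of those classes
(how long each persists, how often each appears, how strong the field is)
index the organization of large-scale cortical networks. At the global
level, the multichannel signal is a trajectory through a k-dimensional
sensor space, summarized by its total variance (sigma), its generalized
frequency (phi) and the effective number of uncorrelated generator
processes (omega). Both levels are tracked over hours of anaesthesia,
inside and outside suppression EEG (near-isoelectric periods with
peak-to-peak amplitude under 10 µV), and related to whether the patient
later develops postoperative delirium (POD).

Because intraoperative patient EEG of this kind is not publicly
deposited, the package ships a generator that emulates the *structure* of
such data with known ground truth; every downstream stage is validated by
recovery of what the generator put in.

## Synthetic cohort generator

Each epoch is a semi-Markov process over `n_classes` (default 4) class
topographies: segment lengths are gamma-distributed with configurable
shape (default 2, truncated at one sample) and mean `mean_state_duration`
(default 100 ms, the centre of the 80–120 ms range typical of the
literature). Class maps are random orthonormal vectors in the
average-reference subspace, which makes recovery well-posed and the
pairwise-correlation bound trivially satisfied. The active map is
multiplied by an amplitude-modulated 10 Hz carrier (inside the 2–20 Hz
analysis band, so filtering preserves structure); the carrier phase
re-randomizes at each segment boundary — each microstate is its own
wavelet, reflecting field reorganization at transitions, and giving short
segments their own GFP peaks. White sensor noise is added at a configured
SNR (template sd / noise sd, default 5). Suppression epochs keep their
microstate sequence and are rescaled as a whole so the maximum channel
peak-to-peak amplitude equals `suppression_amplitude` × the current gain
(base 5 µV, always below the 10 µV detection threshold); they may be
shorter than the canonical 2.5 s, as real suppression periods are.

Cohort structure: `n_patients` patients, POD assigned to exactly
`round(pod_fraction × n)` of them (default fraction 0.29, matching the
observed incidence the models are meant to face); intervals at ~30-min
spacing with up to 24 epochs each; per-patient covariates drawn from
distributions shaped like an older surgical population (age ≈ N(71, 6.5)
clipped at 60, ~40% female, ~35% TIVA, ~34% abdominal/thoracic surgery,
MMSE ≥ 24). Every patient gets at least one suppression and one
non-suppression interval when the suppression fraction allows, keeping
the factorial design identifiable.

Ground-truth group × time trends are injected on *generating* parameters,
never on computed outputs, so recovery is a genuine test:

* `duration_slope` (ms/min) on the mean segment duration;
* `log_gain_slope` (1/min) on the log amplitude gain — sigma responds
  quadratically; the suppression rescaling target inherits the gain so the
  trend survives inside suppression (a fixed target would pin sigma there);
* `log_snr_slope` (1/min) on the log SNR;
* `concentration_slope` (1/min) on the probability that the next segment
  (re-)enters a dominant class. Occupancy concentration shrinks the
  effective spatial rank and is the generating counterpart of a falling
  omega. (An SNR drift alone cannot do this: beyond SNR ≈ 5 the epoch's
  omega is dominated by the clean four-class process and saturates.)

All randomness flows through one seeded `numpy` generator; identical seeds
give byte-identical cohorts.

## Preprocessing

4th-order Butterworth band-pass 2–20 Hz applied forward–backward
(zero-phase, `sosfiltfilt`), then average reference; the two operations
commute to numerical tolerance, which is tested. Suppression is judged on
the filtered signal (deterministic) as max-over-channels peak-to-peak
< 10 µV; the criterion is scale-monotone by construction. Epochs are
grouped greedily in time order into intervals of ≤ 24 epochs of
homogeneous suppression status; a set closes when full or when the next
epoch of that status starts more than 15 min (half the nominal 30-min
sampling grid) after the set's first epoch. Sets with fewer than 2 epochs
are dropped — single-epoch statistics are degenerate. An interval's
anaesthesia duration is the arithmetic mean of its member epochs' onsets.
For EDF input acquired at high rates, a polyphase resampler to 250 Hz
(≈ 4 ms microstate resolution, standard in this literature) is provided.

## Microstate stage

Maps at strict local maxima of the GFP time series are GFP-normalized
(so high-amplitude epochs do not dominate) and clustered by the classic
polarity-blind modified k-means: assignment maximizes squared spatial
correlation; the class update is the first principal eigenvector of the
assigned maps' outer-product sum; convergence at assignment stability or
explained-variance gain < 1e-6; 20 seeded restarts by default, best
explained variance wins; empty classes are re-seeded and flagged
degenerate if they persist. Group mean maps (per POD group × 30-min time
bin, bins with < 2 datasets excluded) and the grand mean are built by the
same polarity/permutation alignment: per solution, the class permutation
and per-class sign maximizing shared variance against the running mean
(exhaustive over the 24 permutations of four classes — exact and cheap),
with the mean recomputed as a per-class principal eigenvector and the
alignment iterated to stability. Labels A–D come from exhaustive
one-to-one matching against packaged template maps; ties break to
lexicographic label order.

The packaged templates are *synthetic* 19-channel approximations built
from the canonical classes' published geometry (two mirrored diagonal
gradients, an anterior–posterior gradient, a fronto-central peak) on a
schematic 10/20 layout; published normative maps are not redistributed.
They are adequate for deterministic labelling and for tests; users with
access to normative maps can pass their own.

## Quantifier stage

Grand-mean maps are back-fitted: GFP-peak samples take the class with the
highest absolute spatial correlation (ties to the lower class index), all
other samples inherit the label of the temporally nearest peak (ties to
the earlier peak). Same-class runs form segments; runs touching either
epoch edge are potentially truncated and are excluded from statistics.
Per interval and class: duration = mean retained-segment length;
occurrence = retained-segment count / full analysed time (the denominator
deliberately includes discarded samples, keeping it identical across
classes; configurable); GFP = mean over segments of the segment's mean
GFP. A class with no retained segment yields missing duration/GFP — an
unobserved duration is undefined, not zero — and occurrence 0. No label
smoothing is applied before segmentation.

Note a structural property of peak-based back-fitting: segments shorter
than the inter-peak spacing can be missed, so recovered mean duration sits
slightly above the generating mean (~112 ms for a 100 ms truth at a 10 Hz
carrier). The acceptance suite bounds this bias at 15%.

## State space stage

Spatial PCA is the eigendecomposition of the channel covariance over the
epoch (time-demeaned per channel); exactly k eigenpairs are returned, and
average-referenced data always carry one ≈ 0 eigenvalue (the reference
constraint). Sigma is the eigenvalue sum (= covariance trace). Phi uses
the generalized-frequency form √(derivative power / signal power)/2π with
a forward first difference × sampling rate and no smoothing — the form
with frequency units; for a multichannel sinusoid at f Hz it returns f
within discretization error (< 0.1% at 10 Hz / 250 Hz). Omega is the
antilog of the Shannon entropy (natural log) of the normalized spectrum —
the antilog is what yields the stated 1…k range, and makes the log base
immaterial; eigenvalues below 1e-12 × λmax are clamped to zero first.
Per-interval records are arithmetic means over the epochs of the set.

## Statistical stage

Mixed models are fitted by REML with a random intercept per patient
(random slopes are a config option, off by default; the original software
choice is not restated anywhere, so the simplest identifiable structure is
the default). Treatment coding with reference levels: no POD, no
suppression, duration 0, microstate class A. Quantifier models stack the
four classes in long format and carry the 4-way duration × suppression ×
POD × class interaction; descriptor models carry the 3-way interaction.
Missing quantifier cells are dropped listwise, never imputed. Designs with
a single patient per POD group or an empty POD × suppression cell are
refused as unidentifiable. Coefficient inference is large-sample Wald
(z intervals; term tests as Wald chi-square): Satterthwaite-type
denominator degrees of freedom are not available in the Python
mixed-model stack, and with the interval counts this pipeline targets the
difference is small; the convention is stated in the output rather than
silently approximated. Per-cell duration slopes are linear combinations
of coefficients (the reference cell's slope is exactly the bare duration
coefficient), with variance from the matching covariance combination.
Predicted trajectories put categorical covariates at reference and
continuous ones at their mean; bands are 95% fixed-effects confidence
intervals, and grid points beyond the observed duration range are flagged
rather than refused. No multiple-testing adjustment is applied; all
p-values are reported raw.

TANOVA operates on each patient's first interval per suppression status,
GFP-normalized: the effect statistic is the GFP of the difference of
cell-mean topographies, generalized to multi-level effects as the
root-mean GFP of the factorially centred effect maps. The null shuffles
within-subject condition cells for within effects and POD labels across
subjects for between effects; p = (count ≥ observed + 1)/(n + 1), so the
resolution is 1/(permutations + 1). Calibration was verified empirically
(rejection ≈ 5% at α = 0.05 under the null, including the three-way
effect with unbalanced groups). Channel-wise t-maps are paired (or
unpaired) per-electrode t statistics.

## Problem sizes in the test suite

Tests run the full chain at reduced scale — typically 8–12 patients,
4–6 intervals of 6–8 epochs — which a single CPU core handles in a few
seconds per cohort; statistical calibration uses 200–300 replicates of
directly simulated record tables (the quantity under test is the stats
layer, and the generator path is exercised separately by the
sign-recovery test over 10 seeded cohorts). Injected effect magnitudes in
those tests (log-gain 0.004/min, concentration 0.005/min in the
suppression-with-POD cell) are chosen to represent a pronounced,
clinically evident drift over a few hours while keeping suppression
amplitudes under the 10 µV threshold throughout.

## Known limitations

* The generator emulates microstate-structured, suppression-marked EEG; it
  does not model anaesthetic pharmacology, artefacts (electrocautery,
  movement), burst fragments of burst suppression, or channel-specific
  noise. Passing tests demonstrate correctness of the analysis chain on
  data with this structure, not clinical validity on operating-room EEG.
* Suppression detection is a fixed amplitude rule on filtered data; no
  adaptive or hysteresis-based detector is provided.
* Four classes and a 19-channel montage are the designed-for case; the
  code is generic in k and class count, but templates ship only for the
  10/20 montage.
* Wald inference is anti-conservative for very small cohorts (a handful of
  patients); the design checks refuse the worst cases but cannot make
  small-sample inference exact.
* TANOVA's within-subject permutation shuffles the full class ×
  suppression cell structure per subject (an omnibus scheme); effect-
  specific restricted permutation schemes are not implemented.
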
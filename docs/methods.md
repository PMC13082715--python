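# Methods

This note documents the models, test procedures and numerical choices
implemented in `gainmod`, and what the synthetic validation studies do and
do not establish.

## Scientific setting

Neurons in mouse visual cortex are tuned to the direction of visual motion,
and locomotion modulates the gain of their responses. The analyses here
characterize that interaction at the level of *functional subunits*: a
subunit is one direction-specific fragment of a neuron's tuning — one row of
its direction x running-speed tuning matrix — with its own speed-dependent
gain profile (its *modulator*). One dominant subunit corresponds to
direction selectivity; two subunits 180 degrees apart instantiate
orientation selectivity whose two lobes can be modulated independently by
behavior.

## Tuning-curve estimation

Trial-level responses (dF/F-like samples with a stimulus direction in
{0, 45, ..., 315} degrees, a grating temporal frequency in {1, 2, 4, 8, 15}
Hz and a running speed) are thresholded at zero and divided by the standard
deviation of the thresholded trace (population convention, denominator n).
Samples are binned by direction (8), temporal frequency (5) and running
speed — 8 linear bins on [0, 20] cm/s, half-open with the last bin closed;
speeds above 20 cm/s are excluded rather than clipped. Averaging the
resulting 8 x 5 x 8 tensor over the frequency axis (unweighted mean of the
non-empty per-frequency bin means) yields the 8 x 8 direction-speed curve R.

Quality control rejects a neuron if any of the 64 direction-speed bins is
empty, holds less than 1 second of data, or if more than 16 of the 64 bins
were averaged over fewer than 3 distinct temporal frequencies. Direction
selectivity is summarized by the specificity S = 1 − H of the speed-averaged
tuning, where H is its Shannon entropy in bits divided by 3 (log2 of the 8
bins): S = 0 for uniform tuning, S = 1 when one direction carries the whole
response. The specificity gate admits neurons whose S exceeds the 95th
percentile of S over bin-permuted curves resampled from the cohort.

## Bootstrap test of speed modulation

The statistic d_mod sums, over the 8 speed bins, the Euclidean distance
between the bin's 8-point direction tuning and the speed-averaged tuning.
The null resamples each (direction, frequency, speed) bin's responses, with
replacement, from the pooled (direction, frequency) stratum: sensory tuning
and per-bin sample counts are preserved exactly while speed structure is
destroyed. A neuron is speed-modulated when its observed d_mod exceeds the
95th percentile of the bootstrap null (1000 replicates at full scale; the
validation studies use 200, which resolves the 95th percentile to within
the quoted +/- 3% calibration band).

## Sparse subunit decomposition

The decomposition models R as a sum of direction-row basis matrices, each
row carrying an effective gain g[i, l] = m[i, l]^2 s[i]^2 (parameters are
squared so the reconstruction is non-negative). The cost is the mean squared
reconstruction error plus lambda times the mean of s^2 and lambda times the
mean of m^2. With 72 free parameters for 64 cells the model is saturated;
the sparsity penalty together with the fitting protocol — 300 first-order
gradient steps (Adam-style adaptive steps on the analytic gradient, learning
rate 0.05, best iterate kept) from 5 random initializations |N(0, 0.1)|,
keeping the fit with the highest SNR — is what makes the decomposition
informative. Structured curves pull the optimizer into sparse minima; on
synthetic two-subunit cohorts the selected fits land near 8-12 dB SNR,
the range reported for cortical data with this model class.

Reconstruction quality is SNR = 10 log10(Var(R) / MSE) over the 64 cells.
Model selection fits a 10-point lambda grid on [0.01, 0.1] and compares each
lambda's SNR with a permutation null: curves drawn from the cohort with
replacement, their 64 bins globally permuted, fitted identically. A neuron
is retained at the smallest lambda whose SNR exceeds the null's 95th
percentile. Subunits whose mean scaled modulator reaches 5% of the
strongest subunit's are *significant*. With kappa = 4 von-Mises tuning the
45-degree neighbours of a preferred direction sit at 31% of peak, so
realistic fits often carry 3-4 significant rows; analyses of "two-subunit"
neurons therefore operate on the two strongest significant subunits.

Design choices made here (the optimizer, its step size, the initialization
scale, the best-iterate rule, and the SNR definition) were fixed before the
validation runs; the contract the tests enforce is agreement of the best-of-5
fit with a 50-initialization reference, parameter recovery on model-generated
curves, and monotonicity of the penalty at the optimum — not a specific
optimizer trajectory.

## Differential modulation of two-subunit neurons

The statistic rho-bar is the largest achievable average Pearson correlation
between one non-negative curve and both of a neuron's scaled modulators
(the correlation-maximizing fit). Because correlation is shift-invariant,
the non-negativity constraint never binds and the optimum equals
sqrt((1 + rho12) / 2), where rho12 is the correlation between the two
modulators; the implementation optimizes the squared-parameterized curve
with BFGS on the analytic gradient from an analytic warm start (the shifted
sum of the standardized modulators) plus random restarts, and the unit
tests verify agreement with both a brute-force grid search and the closed
form. Low rho-bar means no single gain profile can track both modulators —
the signature of differential modulation.

The null hypothesis is *shared* modulation: speed-shuffled bootstrap trials
whose samples in the two strongest subunits' direction rows are multiplied
by the average of the two fitted modulators, rebuilt into curves, refitted
at the neuron's selected lambda (a fresh lambda path per replicate would add
an order of magnitude of compute without changing the statistic's scale),
and scored by the rho-bar of the refit's two strongest subunits. The test
is lower-tailed at alpha = 0.01. Bootstrap refits use 3 initializations and
the rho-bar optimizer 3 starts; both choices were checked against the
5-init / 10-start settings on fixtures before being fixed.

Supporting descriptive analyses: the log2 strength ratio of the stronger to
the weaker modulator; Pearson correlations of each modulator with the
speed-bin centers (1.25, 3.75, ..., 18.75 cm/s); a permutation band (5th to
95th percentile of speed correlations of speed-permuted modulators)
delimiting chance correlation; and a four-region classification of the
(weaker, stronger) correlation plane — both above the band, both below,
both inside (neutral), anything else asymmetric, including opposite-side
extremes, a corner the region definitions leave open. The noisy
shared-modulator control replaces both modulators by their norm-preserving
average plus Gaussian noise (sd 0.01 by default, grid up to 0.2): on
synthetic cohorts the jointly-extreme fractions of the plane decay
monotonically with that noise while the neutral fraction stays roughly
flat, because random RBF modulators — unlike strongly speed-correlated
cortical ones — often average to a speed-neutral profile in the first
place.

## Clustering

Modulator shapes are clustered with standard k-means (k-means++ seeding, 50
restarts, tolerance 1e-6, fixed seed) on L2-normalized features: the
stronger-first concatenation of the two scaled modulators (16-vector) for
two-subunit neurons, the single scaled modulator (8-vector) otherwise,
normalized uniformly. Default k = 12 (two-subunit) and 9 (one-subunit).
The clusters are descriptive summaries of a continuum, not discrete types;
no cluster-number selection criterion is applied, and exact memberships are
not a validated surface. Members are summarized by modulator centers of
mass (gain-weighted mean speed over bin centers) and per-group membership
proportion tables.

## Population decoding

The generative neuron for the decoding studies has 1 or 2 von-Mises
subunits r(phi) = exp(kappa (cos(phi − phi_i) − 1)) with kappa = 4
(max-normalized), each gain-modulated as r(phi) exp(m(s)) with m(s) a
linear combination of 8 Gaussian radial basis functions (peaks linearly
spaced on [0, 20] cm/s, squared width 10; weights N(0, 0.5)), plus Gaussian
response noise (sd 0.2). Note the Gaussian basis requires the negative
exponent −(s − s_i)^2 / sigma^2; the basis diverges otherwise. Two-subunit
neurons are antipodal by default and come in shared and independent
modulation flavours; in the independent flavour the weaker subunit's
weights are reduced by one common Uniform[0, 0.2] draw.

MAP decoding evaluates the Gaussian likelihood of a population response on
a 120 x 81 (direction x speed) grid, marginalizes the joint posterior and
takes each marginal's argmax (ties at the lowest grid index; priors are
uniform so this equals maximum likelihood; the decoder knows the generative
noise sd). Errors are the circular angular distance (radians) and the
squared speed error ((cm/s)^2), averaged over trials within a population
and then summarized as mean and sd over random populations. The validation
studies use 100 populations x 200 trials per size over the doubling grid
2-128 (the reference design is 500 x 500, reachable through the same
parameters); at this scale the shared-modulation plateau at pi/2 and the
roughly factor-two DS-to-OS matched-size ratio for speed decoding are
stable to well within the asserted tolerances. The data-matched variant
decodes from empirical (fitted) 8 x 8 curves normalized to maximum 1, with
stimuli restricted to the 8 directions and 8 speed-bin centers, and a
shared-modulation control that rebuilds each curve with both subunit
modulators replaced by their average.

## Synthetic cohorts: what they do and do not show

The trial generator emulates the protocol structure of two-photon
recordings during drifting-grating stimulation: long-format samples, one
imaging frame (1/30 s) per row, discrete stimulus sets, and a configurable
running-speed distribution — uniform for calibration studies (matching the
simulation design above), or a rest-plus-lognormal mixture (40% rest) that
produces the unbalanced bin occupancy the QC filters exist for. An optional
per-frequency gain vector exercises the frequency-coverage filter. The
generator does not simulate calcium indicator dynamics, eye position,
sessions/animals, or temporally correlated noise; calibration results
(e.g. the 5% and 1% type-I rates) therefore validate the test logic under
exchangeable noise, not robustness to autocorrelated dF/F traces.

Parameter-recovery studies use two constructions. Single-subunit recovery
runs the full pipeline on von-Mises neurons (4800 trials each, about 75
samples or 2.5 s per direction-speed bin) and asks whether the dominant
fitted subunit sits on the preferred-direction row. Two-subunit recovery
generates curves from the decomposition's own row model (antipodal rows
carrying exp(m(s)) gains, cells averaged over 75 noisy thresholded samples)
so that ground-truth scaled modulators are defined exactly; it scores the
median fitted-vs-true modulator correlation and the fraction of fits whose
two strongest subunits are 180 degrees apart. Von-Mises neurons spread
tuning into flanking rows, so row-level identity of the *second* subunit is
only meaningful under the row model, while dominant-row and modulator-shape
recovery hold under both.

## Degenerate inputs and edge conventions

All-negative traces and zero-variance thresholded traces are rejected as
degenerate; all-zero curves cannot be fitted; constant vectors make Pearson
correlations undefined and are propagated as NaN markers, never coerced to
zero. The 5% subunit rule retains ties at exactly 5%. Quantiles use numpy's
default linear interpolation. Significance comparisons are strict
inequalities against the respective quantile. All stochastic stages take
explicit `numpy.random.Generator` objects; pipeline stages derive theirs
from one top-level seed via `SeedSequence.spawn`, making every artifact
reproducible bit for bit.

## Known limitations

- The saturated decomposition relies on the fitting protocol for implicit
  regularization; radically different optimizers would need recalibration
  of the lambda grid.
- The differential test's null reimposes shared gain only on the two
  strongest subunit rows; residual speed structure in flanking rows of
  broadly tuned neurons slightly widens the null, making the test mildly
  conservative (observed type-I below nominal).
- Decoding assumes the response-noise sd is known to the decoder; noise
  mismatch is out of scope.
- Cluster counts follow the descriptive choices (9/12) rather than a
  selection criterion, by design.
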
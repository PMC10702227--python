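# Methods

`somnoephys` implements an end-to-end analysis chain for long-duration
multichannel intracortical recordings — unsupervised behavioral-state
staging plus state-resolved spectral, cross-frequency, spike, and
spike-field statistics — together with a synthetic-session generator that
plants every quantity the estimators are supposed to recover.  This note
records the models, the parameter choices that matter, and the places
where the design was genuinely open.

## State classification

Each 8-s bin of the (1 kHz, anti-aliased) LFP is summarized by its Welch
power spectral density between 0 and 50 Hz (2-s Hann segments, 50%
overlap; 0.5 Hz grid, 101 points), averaged across channels and
normalized per bin by subtracting the minimum and dividing by the
trapezoidal integral.  Relative spectral shape therefore drives the
classifier; absolute gain cancels exactly (a pipeline invariant that is
tested).

The normalized spectra train a stacked sparse autoencoder: encoder layers
of 256/128/64 units (linear map, batch normalization, ReLU) into a 32-unit
bottleneck with the same batch-norm + ReLU treatment, mirrored decoder,
linear output.  The loss is mean squared reconstruction error plus an L1
penalty (weight 1e-5) on the encoder activations; optimization is Adam
(learning rate 1e-3, beta1 0.9, beta2 0.999, eps 1e-8) on shuffled
minibatches of 64 for 300 epochs.  Two details are deliberate:

- The L1 term is an activation-sparsity penalty (the network is a
  *sparse* autoencoder), not weight decay; its subgradient at zero is
  taken as zero.
- ``AutoencoderConfig.bottleneck`` switches the 32-unit layer between the
  default batch-norm + ReLU treatment and a plain linear map; both were
  evaluated and behave equivalently on synthetic sessions of one hour or
  more.

The implementation is plain numpy (BLAS matmuls; the batch-norm
forward/backward and Adam update are fused numba kernels for speed) and is
deterministic given the config seed and a fixed BLAS thread count.

Head movement enters as one extra dimension: the root-sum-of-squares
across the three accelerometer axes, its variance within each 8-s bin,
log10-compressed, then centered and rescaled so the column's standard
deviation equals the largest latent-column standard deviation.  The
centering step (beyond the stated std normalization) makes the mixed
feature space location-comparable for k-means.

Bins are clustered with k-means, k=4.  Centroids are estimated using only
points whose mean pairwise Euclidean distance to all points lies within
the 90th percentile (outlier exclusion; "within the 90th percentile of
pairwise distance" is read as a per-point mean-distance criterion, which
yields a well-defined subset).  Seeding is k-means++ with 10 restarts,
best inertia kept; every bin is then assigned to its nearest centroid.
Clusters become states by sequential argmax with removal: highest mean
acceleration -> Move, then highest mean delta power (0.5-4 Hz) -> NREM,
then highest mean beta power (15-30 Hz) -> Rest, remainder -> REM.  The
rule never abstains; states occupying <2% of bins are flagged rather than
suppressed.  Finally a +/-2-bin sliding majority filter smooths the
sequence; ties keep the original label when it is part of the tie and are
otherwise resolved by a seeded random choice.

### Self-validation

k-fold validation (k=20) splits bins into 20 random groups, retrains the
full pipeline (autoencoder, latent table statistics, k-means, labeling) on
19 of them, classifies held-out bins by nearest centroid, re-applies the
majority filter on the complete timeline, and scores the percent
disagreement with the all-data classification separately on training and
held-out bins.  One held-out group is evaluated per bootstrap repetition;
repetitions re-draw the split.  Errors are reported in percent and in
total minutes.

## Spectral statistics

Magnitude-squared coherence and the weighted phase lag index are estimated
from 10-s Hann segments with 50% overlap (0.1 Hz grid) drawn only from
contiguous same-state stretches, so bin-boundary discontinuities never
enter a segment.  Coherence uses the Welch-averaged cross- and
auto-spectra, `|Pxy|^2/(Pxx Pyy)`; wPLI is `|mean Im Sxy| / mean |Im Sxy|`
over segments (the plain estimator; the debiased squared variant is out of
scope).  Both are clipped to [0, 1]; wPLI of an identically-real
cross-spectrum is defined as 0.

## Cross-frequency phase-amplitude coupling

Six canonical bands are used throughout: delta 0.5-4, theta 4-8, alpha
8-12, beta 15-30, low gamma 30-70, high gamma 70-120 Hz.  Band filtering
is a second-order Butterworth applied forward-backward (zero phase,
fourth-order magnitude).  The analytic signal gives instantaneous phase
(convention: 0 at the oscillation peak, pi at the trough, wrapped to
[0, 2pi)) and amplitude; the first and last second after filtering are
excluded from statistics to suppress filter transients.

For a (low band, high band, state) triple, the mean vector length is
`MVL = |mean(r exp(i phi))|` over in-state samples, with `r` the high-band
amplitude and `phi` the low-band phase; the mean-vector angle is the
preferred phase.  Because MVL scales with amplitude, it is normalized by
the maximum MVL attainable for the same marginals: phases are histogrammed
into 64 equal bins, samples are reordered so phases from denser bins come
first (order within a bin arbitrary), amplitudes are sorted descending and
re-paired, and the mean vector recomputed.  nMVL = MVL/maxMVL is
gain-invariant and clipped to [0, 1] (the heuristic pairing can in
principle be undercut by ties; violations are logged, none are expected in
practice).  All 15 ordered band pairs are computed per channel; channel
aggregation is left to reporting.

## Spike analyses

Spike detection is two-window discrimination: the wideband trace is
band-pass filtered 1000-2000 Hz with a first-order Butterworth (applied
zero-phase so detected times align with planted templates), and a spike is
accepted at each negative threshold crossing whose trace passes through
two delayed amplitude windows, with a 1 ms lockout.  Snippets span 1 ms
before to 2 ms after the crossing.

Overnight stability compares pairwise waveform CoD distributions
(`CoD = 1 - sum((a-b)^2)/sum((a-mean a)^2)`, first waveforms as reference)
between the first and last 1000 spikes of a unit versus the first 1000 of
the unit against the last 1000 of a different unit (10^4 subsampled pairs
each); the unit is stable iff the same-unit distribution is higher by a
one-sided Wilcoxon rank-sum at p < 0.05 with a higher median.

ISI histograms use 1-ms bins over 0-500 ms smoothed with a 3-bin moving
average; the peak location classifies units (fast-spiking iff strictly
below 10 ms).  The binning/smoothing choice keeps the mode estimate stable
near the boundary.  Rate series convolve the 1 kHz spike delta train with
a unit-area Gaussian, sigma 4 ms (FWHM ~9.4 ms, i.e. "~10 ms" width);
reflecting boundaries keep the integral exactly equal to the spike count.
Cross-correlograms are Pearson correlations of mean-subtracted rates at
lags up to +/-100 ms restricted to in-state samples.  State rate
modulation is `100*(state rate - overall rate)/overall rate`.

## Spike-field locking

Spike phases are read from the analytic series of the unit's own channel
at the nearest LFP sample (at 1 kHz and bands up to 120 Hz the worst-case
phase error is < 0.08 rad).  `PLV = |mean exp(i phi)|`; the locked phase
is the circular mean.  PLV is positively biased at small counts
(`E[PLV] = sqrt(pi)/(2 sqrt(n))` under uniform phases, ~0.009 at n = 10^4);
estimates under 10,000 spikes carry a `low_n` flag, and a Monte-Carlo bias
curve is provided.  Spike phase-by-amplitude distributions split spikes
into amplitude deciles (deciles of the amplitude at spike times) with each
decile row normalized to sum 1.  Spikes are not blanked from the LFP
before filtering by default; an optional caveat for spike bleed-through
into gamma bands remains (detection and locking share the channel).

## Statistical comparisons

Paired per-state values (channels or units x 4 states, no missing cells)
are compared with Friedman's test; pairwise post-hoc differences use the
rank-based Tukey/Nemenyi procedure: mean within-row ranks compared via the
studentized range distribution (k groups, infinite df), significance at
p < 0.05.  This is the standard rank-based rendering of an "honest
significant difference" post hoc for a Friedman design.

## Synthetic sessions

The generator is first-class code: it emulates a ~24-h cage recording
(default: 8 channels at 1 kHz, 3-axis accelerometer at 100 Hz, 12-h
lights-off spanning hours 2-14 of the session) and writes the ground truth
it plants.

**State sequence.**  A semi-Markov chain on 8-s bins.  Lights-off
alternates NREM bouts (uniform dwell 30-120 min) and REM bouts (4-15 min),
with a brief Rest/Move awakening after a REM bout with probability 0.25
(dwell 0.5-3 min).  Lights-on alternates Move and Rest (2-15 min each)
with a REM "nap" inserted with probability 0.08 (2-10 min).

**LFP.**  Each channel is `1/f` background noise (exponent 1, unit scale)
plus one carrier per band scaled by a per-state amplitude table and
cross-faded over <= 1 s at state transitions.  The default amplitude table
plants high delta in NREM, high theta/alpha in REM, a strong beta peak in
Rest, and elevated gamma during Move (movement-related broadband
activity), with accelerometer variance largest in Move, intermediate in
REM, lowest in NREM — the state contrasts a real motor-cortex recording
shows.

Carriers for the sub-50 Hz bands (the classifier's feature range) are
sums of amplitude-stabilized oscillators pinned at evenly spaced
frequencies across the band (8 components for delta, 4 for theta, alpha
and beta): each component's instantaneous frequency is a clipped
Ornstein-Uhlenbeck process (correlation time 0.3 s) around its center,
and its amplitude a log-normal envelope (CV 0.25, correlation time 1 s).  Cortical rhythms are regular, high-amplitude oscillations
whose per-bin band power fluctuates far less than filtered Gaussian noise
would; filtered-noise carriers were tried first and produced per-bin
spectral-shape variance large enough to dominate the between-state
structure, which no estimator of this pipeline could plausibly be expected
to undo.  The gamma carriers, which only enter the coupling analyses,
remain frequency-shaped Gaussian noise (second-order Butterworth magnitude
response applied in the frequency domain, negative frequencies zeroed so
the analytic phase is available by construction).  Welch spectra of both
carrier types show smooth band-shaped humps.

Cross-channel coherence is controlled by mixing a shared structured
component into every channel, `sqrt(1-f)*private + sqrt(f)*shared` with
`f = 0.5` by default; `f = 1` forces coherence 1.

**Coupling.**  For each (state, low, high, depth, phase) entry the high
band's carrier is multiplied by `1 + depth*cos(phi_low - phi0)` (clipped
at zero), using the low carrier's exact phase; the coupling coefficient is
cross-faded at state boundaries like the amplitude envelopes.  Depth maps
monotonically — but not in closed form — onto measured MVL, so recovery is
asserted as ordering, not absolute values.  Defaults plant delta->high
gamma coupling at depth 0.8 (phase pi) in NREM and 0.5 (phase pi/2) in
Move, and theta->beta at 0.6 (phase 0) in REM.

**Accelerometer.**  White noise with per-state standard deviation (Move
1.0, REM 0.2, Rest 0.1, NREM 0.05 in g-like units) plus Hann-windowed
1-s movement bursts at per-state Poisson rates (12/min in Move, 1.5/min in
REM, rare elsewhere).

**Spikes.**  An inhomogeneous renewal process thinned on a 1 ms grid.
The hazard is `A(state) * g(dt since last spike) * exp(kappa cos(phi - mu))
/ I0(kappa)`: `g` is zero inside the absolute refractory period and has a
Gaussian bump at the target ISI mode (so the ISI histogram peaks near the
configured value); `A` is calibrated per state by solving the renewal
mean-ISI integral so the mean rate matches the configured rate; the von
Mises factor has unit mean over uniform phase, implements exact von Mises
conditional phase locking, and reads the band phase from the unit's own
(mixed) LFP channel.  A separate renderer produces a 20 kHz-like wideband
trace (scaled LFP + white noise + a biphasic template at spike times) for
discriminator tests.

Every generator is deterministic given the session seed (sub-seeds are
spawned per stream), and `iter_lfp_channels` exposes channel-by-channel
streaming so a 24-h session can be analyzed without holding the full LFP
matrix in memory.

### What the generator does not emulate

Discrete NREM events (spindles, k-complexes) beyond generic band power;
electrode drift and unit waveform instability; EMG/movement artifacts with
broadband spectral shape (movement is represented by elevated gamma band
power and accelerometer variance); inter-animal differences such as
per-animal beta peak frequency (the beta carrier location is configurable
rather than fixed); continuous sleep-depth gradations — states switch
discretely with 1-s cross-fades.  Passing tests therefore demonstrate that
the estimators recover planted structure under realistic noise, not that
the classifier would reach the same accuracy on real recordings.

## Problem sizes

The default test suite runs sessions of 1-6 h with 1-4 channels and
proportionally shortened dwell times; classification-recovery checks use
6-h four-channel sessions, and the k-fold self-consistency check runs on
a 12-h eight-channel session (5,400 bins) — the smallest scale at which
autoencoder retrains were measured to be uniformly stable (0 failures in
36 retrains at 12-24 h with 8 channels, versus ~10-30% unstable retrains
at 2,700 bins with 4 channels, which is below the regime the method
operates in).  The reproduction script runs a full-length 20-h,
8-channel session (9,000 bins; recordings in this setting span 19-24 h)
with k=20 and 10 bootstrap repetitions.

## Known limitations

- The max-MVL pairing is a deterministic heuristic, near-maximal by the
  rearrangement inequality on binned phases; it is not proven maximal for
  every tie structure (nMVL is clipped and violations logged).
- Autoencoder latent geometry is only implicitly controlled; on very short
  sessions (< ~2 h, i.e. < ~1,000 bins) or when within-state spectral
  variance approaches between-state contrasts, the encoder can distort
  between-state distances enough to perturb k-means.  The default
  generator's carrier stability keeps sessions of >= 6 h well clear of
  this regime.
- The spike-train hazard shapes the ISI mode approximately; the realized
  histogram mode can sit within ~1 ms of the configured value.
- Friedman post-hoc uses the Nemenyi studentized-range approximation,
  which is conservative for small row counts.
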
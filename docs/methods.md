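# Methods

`meaburst` analyses spontaneous extracellular activity of dissociated
cortical cultures grown on 60-electrode arrays, either as a single uniform
network (1N) or as four sub-populations at the corners of the active area
(4N).  This note records the models, parameter choices and numerical
decisions behind each stage, and what the synthetic generator does and does
not emulate.

## Layout model

The 4N active area holds four 13-electrode clusters at the corners of a
1.8 mm × 1.4 mm rectangle plus 7 interstitial electrodes between them
(59 signal electrodes; the 60th contact is the reference).  Clusters are
labelled on a 2×2 grid as A=(0,0), B=(0,1), C=(1,1), D=(1,0), so the cyclic
order A→B→C→D walks the square's edges; two clusters are *adjacent* when
their grid positions differ in one coordinate, and the pairs A–C and B–D
are diagonal.  Electrode coordinates in `build_4q_layout` are schematic —
they preserve the counts, the quadrant structure and the cluster footprint,
not the vendor's exact site map, which no analysis here depends on.

1N controls are analysed with the same topology by carving **virtual
clusters**: electrodes are split into quadrants around the layout centroid
and, per quadrant, the 13 electrodes nearest the quadrant's outer corner
form the virtual cluster (ties broken by electrode id, so the carving is
deterministic).  Leftover electrodes stay unassigned, mirroring the
interstitial electrodes of 4N.  The exact spatial rule for this grouping is
a design choice; any deterministic rule that yields four 13-electrode
quadrant groups would serve.

Interstitial electrodes are **excluded** from cluster firing-rate and
activation-sequence analyses (those characterise the 13-electrode
sub-populations) but **included** in whole-network quantities such as the
mean firing rate table and the network-burst participation denominator.

## Detection chain

**Noise estimate.** The per-electrode noise SD is the robust MAD estimate
`median(|x|)/0.6745`, which is insensitive to the sparse large excursions
spikes produce; a plain SD would be inflated by exactly the events we are
trying to detect.  A constant trace yields 0 with a warning.

**Spike detection** uses a differential (peak-to-peak) threshold with
precise timing: consecutive opposite local extrema closer than one spike
*lifetime* (2 ms) whose excursion reaches 8× the noise SD mark a spike,
timed at the absolutely larger extremum; detections within the *refractory
period* (1 ms) are merged, keeping the first.  These three parameters are
the conventional settings for unsorted MEA recordings.  On noiseless
synthetic traces the detector recovers every ground-truth event within
±0.5 ms with no false positives (verified in the suite).

**Burst detection** is the string method: maximal runs of ≥5 spikes with
every inter-spike interval ≤100 ms; burst start/end are the first/last
spike of the run.  The implementation is checked against a brute-force run
scan on random small trains.

**Network bursts (NBs).** Per-electrode burst events are pooled and chained
while the gap from an event's onset to the running chain end stays below a
self-adaptive threshold; chains spanning ≥20% of the recording electrodes
become NBs (start/end = min/max over member bursts).  The threshold is
found on the log₁₀ histogram of inter-burst-event intervals: within-NB gaps
(tens of ms) and between-NB gaps (seconds) form two modes, and the
threshold is the density valley between the two largest modes, capped at
1 s.  The histogram is smoothed (σ = 1 bin) and zero-padded so boundary
modes count; if no second mode exists, or the valley does not dip below
half the smaller mode, the histogram is treated as unimodal and a 100 ms
fallback is used (flagged in the return value).  The "recording electrodes"
denominator of the 20% rule is the set of **active** electrodes, i.e. those
with MFR ≥ 0.1 spikes/s — quieter channels are discarded from all analyses.

## Firing statistics and activation sequences

Per electrode: MFR (spikes/s), MBR (bursts/min), mean burst duration (ms),
and the inter-burst-interval (IBI) family.  IBI is measured burst start to
next burst start on the same electrode — the conventional definition, and
consistent with IBI ≫ burst duration in these cultures; SD_IBI uses the
sample SD and CV_IBI = SD_IBI/mean(IBI).  Per recording: NB rate, NB
duration, inter-NB intervals and the active-electrode count.

The **instantaneous firing rate** (IFR) is the spike count in a sliding
Δt = 100 ms window realised as a Gaussian kernel: spikes are binned on a
10 ms grid and smoothed with σ = Δt/2 (so ±σ spans the window), scaled to
spikes/s.  Reflected boundary handling makes the smoothing mass-conserving,
so ∫IFR dt equals the spike count (within 1% on the discrete grid; property
tested).  "Width equal Δt" admits several kernel parameterisations;
σ = Δt/2 is the choice here, and the grid step (10 ms) is small enough that
activation-time ordering at ≥20 ms lags is unaffected.

A cluster's IFR is the average over its active member electrodes.  Within
an NB k, cluster i activates at

    t_start(i,k) = argmax of IFR_i(t) over t in [t_start(k), t_end(k)],

with ties broken to the earliest grid time and flagged.  A cluster counts
as **recruited** in an NB iff at least one of its active electrodes has a
burst overlapping the NB window — recruitment tied to detected bursting
rather than an arbitrary IFR floor, since an IFR threshold would need its
own calibration while burst overlap is already thresholded by the string
method.  The recruited clusters ordered by t_start(i,k) form the NB's
**activation sequence** (length 1–4).

## Sequence statistics

From a fixed initiator a full-length sequence can follow 3! = 6 orderings;
exactly 2 avoid both diagonals (the clockwise and counterclockwise walks),
so random propagation gives a circular path (CP) with probability 1/3.
Sequences with <3 clusters are classified SHORT and excluded from path
statistics.  Observed CP counts are compared per experiment with the
expectation S/3 (S = number of length-≥3 sequences) via the Wilcoxon
signed-rank test.

**Initiator hierarchy.** Per experiment, clusters are ranked by how often
they initiate sequences; rank r's relative frequency is "frequency class
r", and class medians are pooled across experiments.  Ties are ranked by
fixed label order and flagged (how ties should be ranked is under-determined;
any fixed order preserves the class frequencies).

**Diversity.** Sequence types are full orderings (same clusters, same
order, same length).  Shannon diversity H = −Σ pᵢ ln pᵢ (0·ln 0 = 0) and
equitability E = H/ln N, with E ≔ 0 when only one type exists (the N = 1
case is otherwise undefined; 0 matches the "no diversity" limit).

**Monte Carlo null.** A null sample matches the observed sample size *and*
the observed length multiset: for each observed sequence of length k, one
random ordered selection of k distinct clusters is drawn uniformly.
Matching the lengths is the conservative choice — it isolates type
diversity from the length distribution, which the path and recruitment
analyses already describe.  All Monte Carlo draws take an explicit seed.

**Repeated series.** Maximal runs of ≥2 identical consecutive sequences are
tabulated by run length L: occurrences O_L, weighted absolute frequency
W = L·O_L, and the relative/cumulative distributions derived from W.  Runs
of length 1 are not series.  The scan is oracle-checked against brute
force.

**Test battery.** Mann–Whitney U (pairwise), Kruskal–Wallis (multi-group,
with Bonferroni-corrected Mann–Whitney post-hocs), chi-squared (frequency
classes), Kolmogorov–Smirnov (cumulative distributions), Wilcoxon
signed-rank (paired), all two-sided at α = 0.05, all via `scipy.stats`.

## Dose–response

Phases of a drug-delivery protocol are analysed on 8-min windows after
discarding the first 2 min (mechanical/diffusion transients).  MFR is
averaged over the electrodes active during the basal recording and
normalised to the basal value; the points (concentration, normalised MFR)
are fitted with the four-parameter Hill curve in log₁₀-concentration space
by unweighted least squares (`scipy.optimize.curve_fit`).  IC50 is
parameterised as log₁₀(IC50), which keeps it positive; initial guesses are
max/min of the data, HC = 1, and the log-midpoint of the concentration
range.  Basal (concentration 0) is excluded from the fit.  Degenerate
inputs (fewer than 4 positive-concentration points, or a flat response)
raise instead of returning a meaningless fit.  Parameter recovery is exact
to 3 significant figures on noiseless self-generated grids over
HC ∈ {0.5, 1, 2} × IC50 ∈ {1, 15, 100} µM.

## Synthetic generator

`simulate_recording` emulates the statistical structure the analysis
assumes, not the biophysics.  Defaults describe a 20-min recording of an
active culture: 10 kHz metadata, 0.5 spikes/s Poisson background per
electrode, 30 NBs/min, initiator probabilities (0.45, 0.30, 0.15, 0.10)
(a two-dominant-cluster hierarchy), 100 ms inter-cluster activation lag,
300 ms of within-burst firing at 60 spikes/s per electrode, recruitment
probability 0.85 per non-initiator cluster, circular bias 0.75 and a 0.15
probability of repeating the previous sequence verbatim.

Numerical choices worth recording:

* **NB placement** is a renewal process: interval = event span + 0.2 s +
  Exponential(mean 60/nb_rate − max span − 0.2 s).  The dead time forbids
  overlapping NBs; sizing the exponential against the dead time keeps the
  realized rate at `nb_rate`, whereas thinning a Poisson stream would
  deflate it by ≈(1 + rate·gap)⁻¹ and break the Poisson-scale count checks.
* **Propagation**: the initiator is drawn from `initiator_probs`; each next
  cluster is, with probability `circular_bias`, a uniform draw among
  unvisited grid-adjacent clusters, otherwise uniform among all unvisited.
  Bias 0 makes all 6 orders equiprobable (CP fraction 1/3); bias 1 forces a
  circular walk.  Non-initiator clusters then join independently with
  probability `recruit_probs`.
* **Within-burst firing** is an inhomogeneous Poisson process with a
  raised-cosine (Hann) rate profile over `burst_len`, mean rate
  `within_burst_rate`, peaking at lag + burst_len/2.  A flat profile would
  leave the within-NB IFR argmax roughly uniform over the burst plateau and
  make activation *times* — and hence sequence order at moderate lags —
  unrecoverable in principle; the peaked profile gives every cluster a
  well-defined expected IFR maximum, which is what the ground-truth log
  records.
* **Minimum ISI** (2 ms default): per electrode, events closer than this
  are merged, because an unsorted extracellular electrode cannot resolve
  them and the spike detector's refractory period would otherwise make
  "100% recall" ill-posed against the raw event stream.

The generator does **not** emulate: electrode-to-electrode amplitude and
rate heterogeneity beyond Poisson variation, bursts that are not part of
NBs, slow nonstationarity (development, adaptation), waveform diversity, or
any biophysical (conductance-based) mechanism.  Passing recovery tests
therefore show that the chain detects and orders the *kind* of structure
modular cultures exhibit, at realistic rates and lags — not that it is
robust to every failure mode of real recordings.

`simulate_raw_traces` inserts a stereotyped biphasic template (dominant
trough aligned to the spike sample, smaller leading lobe, ~1.2 ms) into
Gaussian noise; overlapping templates sum.  `simulate_dose_response` draws
normalised-MFR points from the Hill curve plus Gaussian noise.

## Problem sizes in the test suite

Synthetic-recording tests run on 60–120 s recordings at the default rates
(~75 NBs per 2-min recording), which gives every recovery statistic dozens
to hundreds of events while keeping the full suite fast; Monte Carlo checks
use n = 10,000 draws; power checks use 12–16 simulated experiments, the
scale of a typical culture batch.

## Known limitations

* The spike detector's extrema-pair scan is a faithful realisation of the
  differential-threshold idea but not a line-by-line port of any particular
  published implementation; the same holds for the valley-seeking NB
  threshold.  Both are parameterised so users can substitute their own
  thresholds.
* The IBeI valley is found on a histogram; with very few bursts (<~20
  events) it falls back to 100 ms rather than attempting density
  estimation on too little data.
* Activation times are grid-quantised (10 ms); lags below the grid step
  are not resolvable, and the suite only claims order recovery for lags of
  at least twice the step.
* The Hill fit is unweighted; replicate-level weighting would need
  per-concentration variance estimates the 8-min protocol does not provide.
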
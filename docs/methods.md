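# Methods

`cinpop` analyses the population activity of striatal cholinergic
interneurons (CINs) from two recording modalities — somatic calcium imaging
of dozens of cells at 6–10 frames/s, and whole-cell current clamp of single
cells — and ships a synthetic-data generator that emulates both modalities
with known ground truth, in a "control" and a "dopamine-depleted"
(hyperactive, burst-and-pause) regime.  This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic tests
do and do not establish about real data.

## Event inference from fluorescence

Calcium transients are expressed as ΔF/F0 = (F − F0)/F0, with F0 either the
annulus background trace around each ROI, a rolling 20th percentile of F
(window 30 s), or the trace mean — the first two readings exist because
"background around the ROI" conflates background subtraction with baseline
normalisation, and both are useful.  The activity indicator is the positive
part of the forward-difference time derivative d(ΔF/F0)/dt; a frame is
active when that derivative exceeds `k_sd` (default 2.5) standard deviations
of the *baseline* derivative.

**Baseline SD estimator.** The SD must describe the event-free baseline.  A
plain SD — and, at CIN-like event densities, even a robust MAD — of the full
derivative trace is inflated by the transients themselves: at 3 Hz events
and 10 fps roughly a third of frames carry rises and most of the rest carry
decays, and the MAD lands ~2× above the noise floor, halving recall.  The
default estimator is therefore a two-pass masked MAD: threshold with a
provisional MAD, mask suprathreshold frames together with ±2 neighbours
(shrinking the dilation if too little baseline would remain), and
re-estimate by MAD on the unmasked frames, iterated twice.  On pure noise
this reproduces the nominal 2.5 SD tail (false-event rate ≈ Φ(−2.5) ≈ 0.62%
of frames); at high event density it stays calibrated to the noise floor.
`mad` and `sd` remain available as options.

**Event collapse.** By default, runs of consecutive suprathreshold frames
are collapsed to transient onsets: the first frame of the run, plus any
in-run frame where the derivative rises again by more than one baseline SD
(two transients landing two frames apart produce one contiguous
suprathreshold run; the re-onset rule separates them).  With collapse off,
every suprathreshold frame is marked, reproducing per-frame rasters.

**Derivative detrending (optional, off by default).** In dense tonic
regimes the slow decay of stacked transients adds a locally smooth negative
trend to the derivative that is the same order as the noise threshold.
`detrend_window=5` subtracts a centred running median (and then requires the
raw derivative to be positive, so detrending residuals on decaying flanks
cannot fire).  The centred median slightly distorts the pure-noise tail, so
it stays off by default and off in sparse recordings.

**What exactness means here.** A spike that lands a fraction of a frame
before the frame boundary contributes almost nothing to the fluorescence
sampled within its own frame; its rise registers one frame late.  Exact
raster recovery (Jaccard 1 on noiseless data) therefore holds for
frame-resolved events — ISIs of at least 2 frames and spikes away from the
boundary, which the generator provides via `snap_to_frame_centers` — and
event-recovery under noise is scored with a ±1-frame matching tolerance.
Recovery is characterised at 3 Hz, 10 fps, transient amplitude 0.2 ΔF/F0
and noise SD up to 0.02: recall and precision both ≥ 0.95.  Real recordings
add motion, neuropil contamination and indicator nonlinearity that the
generator deliberately omits, so these numbers are an upper bound on real
performance, not a claim about any rig.

## Ensemble statistics

*Coactivity* is the per-frame count of active cells.  Its significance
threshold comes from Monte-Carlo surrogates that independently circularly
shift each cell's event row (preserving per-cell event counts and
within-cell interval structure; a count-preserving permutation shuffle is
the alternative).  The pooled per-frame coactivity distribution over
`n_surrogates` (default 1000) surrogates defines the null; the threshold is
the smallest integer count whose null tail probability is below `alpha`
(default 0.05) — a single dashed-line level, not a per-frame-maximum
familywise criterion.  On a 2-cell × 4-frame raster the surrogate null
reproduces the exhaustive enumeration of all 16 shift pairs.  Surrogates
are computed on sparse event indices with `bincount`, identical in law to
rolling the rows and fast enough for 10-minute, 20-cell rasters.

*Rate of activity accumulation* is the slope of an ordinary least-squares
line through the running sum of coactivity over frames (reported per frame
and per second).  For constant counts the slope equals the count exactly.

*Population CDFs* use per-neuron percent-active frames pooled across
recordings per condition, compared with the two-sample Kolmogorov–Smirnov
test under a Bonferroni-adjusted alpha (alpha divided by the number of
planned comparisons).  *Inter-event intervals* (IISIs) are per-cell
successive event-time differences; their skewed distribution is histogrammed
at three scales (< 1 s, 1–60 s, 60–120 s) and pooled into a CDF.

*Group comparisons* dispatch by design: Wilcoxon signed-rank (paired),
Mann–Whitney U (unpaired), Kruskal–Wallis or Friedman for several samples,
each k-group test followed by Dunn's post hoc with midrank tie correction
and Bonferroni adjustment (implemented here; no installed package provides
it).  All-zero paired differences are reported as p = 1.  Proportions use
the 2×2 chi-square with df = 1 and no continuity correction.

## Synthetic generator

**Spike trains** are gamma-renewal processes; the ISI coefficient of
variation is set through the gamma shape (CV = 1/√shape; CV 0 degenerates
to a periodic train).  `burst_pause` alternates exponential-length burst
states (gamma firing at `burst_rate`) with exponential-length pauses;
`burst_rate` defaults to the value that makes the long-run mean equal the
requested rate.  These are the simplest generative laws consistent with
tonic, irregular, and burst-with-pause firing.

**Fluorescence** is a spike-triggered difference-of-exponentials kernel
(defaults: rise 0.05 s, decay 0.5 s, peak amplitude 0.2 ΔF/F0 — representative
fast-indicator values, configurable) summed on a per-cell baseline, with
optional linear drift and additive white Gaussian noise; frames are sampled
at t = j/fps.  Coactive ensembles are imposed by forcing a spike in each
member cell at the event time (optional per-member frame jitter).  Movies
draw each soma as a uniform disk in a 16-bit field; the mean disk intensity
reproduces the cell's trace up to quantisation, which closes the
ROI-extraction round trip.  Indicator saturation, bleaching and motion are
out of scope.

**Membranes** are leaky integrators (R_m in MΩ, τ_m in ms, rest E_L).
Subthreshold step responses follow the closed form
V(t) = E_L + (R_m·I/1000)(1 − e^(−t/τ)) ; for hyperpolarising steps a
relaxing bi-exponential sag component is added whose gain is solved by root
finding so that the peak/steady deflection ratio equals exactly
1/(1 − `sag_fraction`) — so a scenario can be tuned to any target sag ratio
(e.g. 1.019 or 1.053) to better than 0.001.  Suprathreshold steps are
integrated with the exact exponential update; at each crossing of `V_th` a
stereotyped AP waveform is spliced in (waveform splicing, not conductance
modelling — the analyses need waveform shape, not biophysics).  Because the
spliced waveform includes the full mAHP lobe, the mAHP duration
rate-limits repetitive firing, which is also how the control-vs-depleted
difference in firing at a 1 s, 40 pA step is emulated.

**AP waveforms** are synthesised from the target feature set itself:
a half-sine dV/dt profile peaking at the requested maximal depolarisation
rate (midpoint-integrated and rescaled so the amplitude from threshold is
exact), a flat plateau at the peak sized so the duration at half-amplitude
is exact, a half-sine repolarisation peaking at the maximal repolarisation
rate, and a raised-cosine mAHP lobe with exact amplitude and half-width,
recovering to threshold − 0.25·mAHP.  An indented spike carves a
raised-cosine notch of depth `notch_depth`·max rate into the velocity peak,
where the profile is flat, so the phase-plot trough prominence tracks the
requested depth.  The feasible half-width floor given amplitude and rates
is exposed as `min_half_width`; narrower requests are rejected.

## Electrophysiology feature battery

Spikes are detected at an upward 10 mV/ms crossing of dV/dt computed on a
0.3 ms boxcar-smoothed copy of the trace (sample-level recording noise at
20–50 kHz otherwise crosses any practical threshold); all feature
measurements use the raw trace.  Input resistance is the derivative of a
third-order polynomial fitted to steady-state I–V points (last 100 ms of
each subthreshold 1 s step), evaluated at the current where the fit crosses
−60 mV.  Rheobase is the smallest step (ascending search, 5 pA grid by
default) evoking at least one AP within 1 s.  The sag ratio divides the
peak deflection in the first 200 ms of a −100 pA step by the mean deflection
over its last 100 ms.  AP threshold is the rising-limb point where dV/dt
first reaches 4% of that spike's maximal rate (fixed-crossing optional);
amplitude is threshold-to-peak, half-width at half that amplitude, and the
mAHP is measured from threshold to the post-spike minimum within 500 ms or
until the next spike.  Indentation requires a rising-limb dV/dt local
maximum followed by a local minimum with prominence ≥ 10% of the maximal
depolarisation rate.  dV/dt is reported in mV/ms throughout.  Firing
statistics (mean rate, ISI CV) average 2-minute windows and require at
least 3 spikes for a CV.

## The packaged demo study

`workbench.demo_config()` defines three conditions of 20 cells × 10 min at
10 fps, analysed end-to-end (generation → ΔF/F0 → raster → coactivity /
slope / CDF / IISI → comparisons).  Rates are calcium-*event* rates chosen
in the regime the imaging pipeline resolves faithfully and matching the
sparse percent-active scale of population imaging (a few percent of
frames): control is tonic at 0.5 Hz; the DA-depleted regime is burst-pause
at 1.4 Hz (within-burst 3.5 Hz, mean burst 1.2 s, mean pause 1.8 s) with 30
embedded 12-of-20-cell ensemble events; the glutamatergic-blockade regime
returns to tonic 0.6 Hz.  Spike-level rates of 2–4 Hz were evaluated and
rejected for the *full-pipeline* demo: with a 0.5 s-decay indicator at
10 fps they saturate frames and invert the inferred-raster ordering; the
raster-level statistics are instead validated at 2 vs 4 Hz directly on
ground-truth rasters.

The hyperactivity signature checked across seeds: higher accumulation
slope; right-shifted percent-active CDF (KS p < 0.01); more frames above
the conditions' *common* (stricter) coactivity threshold — comparing each
raster at its own integer threshold is dominated by threshold discreteness,
which can flip the sign regardless of ensembles; more sub-second intervals
and more ≥ 5 s pause intervals per cell-minute; and a blockade slope closer
to control than half the depleted–control span.  The packaged study meets
all of these in ≥ 9/10 seeds.

## Determinism and problem sizes

Every stochastic operation takes an explicit seed; scenario generators use
one `numpy` Generator each, study runs derive per-condition seeds from a
`SeedSequence`, and identical config + seed yields byte-identical reports.
Default analysis sizes — 10-minute, 20-cell rasters, 1000 surrogates, 50-AP
parameter sweeps, 5×5 membrane grids — run in seconds on one CPU and were
chosen as the package's standard demonstration scale.

## Known limitations

Inference is thresholding, not deconvolution: it reports event onsets, not
spike counts, and within-burst spikes at or above the frame rate merge into
single events (the demo regimes acknowledge this; see above).  The membrane
model is a single-compartment integrator with spliced APs — adequate for
feature-extraction validation, not for conductance-level questions.  The
surrogate null assumes cell-wise independence under circular shift; slow
common drift in real recordings would require a different null.  Group
comparisons use asymptotic rank tests with midranks for moderate n; exact
small-sample Wilcoxon/Mann-Whitney distributions are used where scipy
provides them.
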
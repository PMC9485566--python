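# cinpop

Population calcium-imaging and current-clamp analysis of striatal
cholinergic interneurons (CINs), with a ground-truth synthetic generator
for control and dopamine-depleted firing regimes.

CINs are the tonically active cholinergic interneurons of the striatum
(1–2% of its neurons, firing autonomously at 2–10 Hz, tonically or in
bursts interspersed with pauses).  In parkinsonian, dopamine-depleted
striatum the CIN population becomes hyperactive.  `cinpop` implements the
analysis chain used to quantify that phenomenon from multi-neuron calcium
imaging and single-cell patch clamp, for researchers who record either
modality — or who want a fully synthetic, seeded test bed for the
statistics.

## What it computes

**Imaging → rasters** (`cinpop.imaging_events`): ΔF/F0 = (F − F0)/F0 per
ROI; activity inferred wherever the positive time derivative d(ΔF/F0)/dt
exceeds 2.5 SD of the baseline derivative; binary R × C rasters (R cells,
C frames); percent-active frames; a KCl-challenge slice-viability filter
(> 85% responsive cells).  ROI traces can come from trace CSVs or from a
TIFF-style movie plus a circular-ROI table with annulus background.

**Population statistics** (`cinpop.ensemble_stats`): per-frame coactivity
counts c(t) = Σᵢ A[i, t] with a Monte-Carlo significance threshold from
per-cell circular-shift surrogates (the dashed line under the raster); the
rate of activity accumulation — the OLS slope of the running sum of
coactivity; Kolmogorov–Smirnov comparisons of per-neuron percent-active
CDFs with Bonferroni correction; inter-event-interval (IISI) histograms at
three scales and pooled CDFs; Wilcoxon / Mann–Whitney / Friedman /
Kruskal–Wallis (+ Dunn's post hoc) group comparisons and 2×2 chi-square
proportion tests.

**Electrophysiology** (`cinpop.ephys_features`): input resistance as the
derivative of a cubic I–V fit at −60 mV; rheobase (minimum 1 s current step
evoking an AP); sag ratio of the −100 pA step (peak/steady deflection);
phase plots (dV/dt vs V) with per-spike features — threshold at 4% of max
dV/dt, amplitude from threshold, half-width, max depolarisation and
repolarisation rates, mAHP amplitude and half-width, rising-limb
indentation; spontaneous rate and ISI CV over 2-minute windows; I–F curves.

**Synthetic ground truth** (`cinpop.synthgen`): gamma-renewal and
burst/pause spike trains with controllable rate and ISI CV; GCaMP6f-like
fluorescence (difference-of-exponentials kernel, noise, drift, embedded
coactive ensembles) with the matching ground-truth raster; 16-bit movies
with disk somata; leaky-integrator membranes with tunable sag and
stereotyped, feature-exact AP waveforms.

**Study runner** (`cinpop.workbench` and the `cinpop` CLI): a seeded
end-to-end synthetic study (control vs DA-depleted vs antagonist-blockade
regimes), before/after-drug segment comparisons, JSON reports with config
hashes, and raster/CDF figures.

## Worked example

Run the packaged demo study (20 cells × 10 min per condition, full
pipeline, one explicit seed):

```python
from cinpop import workbench as wb

cfg = wb.demo_config()
report = wb.run_study(cfg, seed=1)
for name, cond in report["conditions"].items():
    print(f"{name:18s} slope {cond['slope_events_per_s']:6.2f} ev/s   "
          f"coactivity threshold {cond['coactivity_threshold']}   "
          f"events {cond['n_events']}")
comp = report["comparisons"]["control_vs_depleted"]
print(f"control vs depleted: KS D = {comp['ks_D']:.3f}, "
      f"p = {comp['p_value']:.3g}")
```

prints

```
control            slope  10.63 ev/s   coactivity threshold 4   events 6374
depleted           slope  17.26 ev/s   coactivity threshold 5   events 10375
depleted_blockade  slope  12.64 ev/s   coactivity threshold 4   events 7575
control vs depleted: KS D = 1.000, p = 0
```

The DA-depleted regime accumulates activity ~60% faster than control, its
per-neuron percent-active CDF is shifted entirely to the right (KS D = 1
with 20 neurons per group), and the glutamatergic-blockade regime falls
back toward control — the population signature of CIN hyperactivity and
its synaptic dependence.

The same pipeline from the shell, stage by stage:

```bash
cinpop simulate --cells 10 --duration 120 --rate 0.5 --pattern irregular \
                --seed 7 --out demo
# wrote demo_traces.csv (10 cells x 1200 frames) and demo_truth.csv
cinpop infer --traces demo_traces.csv --out demo_raster.csv
# wrote demo_raster.csv (546 events)
cinpop ensembles --raster demo_raster.csv --surrogates 1000 --seed 8 \
                 --out demo_stats.json
# demo_stats.json: coactivity_threshold 3, n_significant_peaks 10,
#                  slope_events_per_s 4.51
```

`cinpop run-study --seed 1 --out studydir` writes the full report bundle
(`report.json`, per-condition trace and raster CSVs, `summary.md`;
`--figures` adds raster + coactivity and CDF plots).  External recordings
enter at any stage through the same CSV formats (traces: cells × frames
with a frame-time header; sweeps: `time_s, voltage_mV, current_pA` with a
protocol JSON sidecar).

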
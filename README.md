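# hrvgate

Quality-gated nocturnal heart rate (HR) and heart-rate-variability (HRV)
metrics from wearable interbeat intervals, with agreement analysis
against a reference normal-to-normal (NN) interval series.

## The problem

PPG-based wearables (rings, watches) report interbeat intervals (IBIs)
with a per-interval validity rating, but transient artefacts — poor skin
contact, motion, missed or spurious pulses — leave gaps that bias HRV
estimates far more than they bias mean HR: rMSSD depends on successive
differences and spectral indices on the continuity of the series. This
package implements the validation pipeline used to answer *how strictly
should per-segment data quality be gated before wearable HRV can be
trusted*:

1. **Quality cascade** for device IBIs: keep only rating-1 intervals,
   require the two immediately preceding and succeeding ratings to also
   be 1, and drop physiologically implausible intervals during sleep
   (outside 375–2000 ms, i.e. HR outside 30–160 bpm). Reference NN
   intervals are screened by the same plausibility band plus a 30 %
   maximum consecutive change.
2. **Segmentation**: time-in-bed is divided into 5-min windows; each
   window's *duration-based validity proportion* is the fraction of the
   window covered by valid IBIs (so 240 s of valid IBIs passes the 80 %
   threshold exactly). Device segments are accepted at a configurable
   threshold sweep (30/50/80/95 %), reference segments need ≥150 valid
   NN intervals, and nights need ≥20 accepted device epochs and ≥50 %
   accepted reference segments.
3. **Metrics** per accepted segment: mean HR = 60000 / mean(IBI); rMSSD
   over successive pairs that are adjacent in the original recording
   with both members valid; Lomb–Scargle band powers of the
   mean-centred, unevenly sampled interval series, with
   HFnu = HF / (HF + LF) for HF = 0.15–0.40 Hz and LF = 0.04–0.15 Hz.
   Accepted 5-min values are averaged into 30-min (≥3 segments) and
   night-level (≥20 segments) windows.
4. **Agreement** between device and reference on segments passing both
   chains: Pearson r, Lin's concordance correlation coefficient
   CCC = 2·cov(x,y) / (σ²ₓ + σ²ᵧ + (μₓ − μᵧ)²), Bland–Altman bias and
   95 % limits of agreement on d = device − reference
   (bias ± 1.96·SD(d)), and per-participant MAE / MAPE / MdAPE with the
   conventional <10 % acceptability bound.

Because paired device/reference recordings of this kind are rarely
shared, the package ships a synthetic cohort generator
(`hrvgate.simulate`) producing paired nights with known ground truth:
reference beats from an integral-pulse-frequency-modulation scheme with
controlled LF/HF spectral content, and device series derived by timing
jitter plus clustered artefact episodes with invalid ratings and
corrupted durations (merged/split beats). Younger and older group
presets emulate lower HR/rMSSD ranges and noisier device timing in the
older group.

## Worked example

```python
import hrvgate as hg

result = hg.run(hg.RunConfig(sim=hg.SimConfig(seed=1), seed=1))
s = result.summary
for metric in ("hr", "rmssd", "hf_nu"):
    c = s[(s.group == "all") & (s.level == "5min")
          & (s.metric == metric) & (s.threshold == 0.8)].iloc[0]
    print(f"{metric:6s} 5-min @80%:  r={c.r:.3f}  ccc={c.ccc:.3f}  "
          f"bias={c.bias:+.3f}  LoA=[{c.loa_low:+.3f}, {c.loa_high:+.3f}]  "
          f"MdAPE={c.mdape:.2f}%")
print(result.retention[result.retention.group == "all"].round(1)
      .to_string(index=False))
```

prints

```
hr     5-min @80%:  r=1.000  ccc=1.000  bias=+0.000  LoA=[-0.018, +0.018]  MdAPE=0.00%
rmssd  5-min @80%:  r=0.984  ccc=0.870  bias=+4.508  LoA=[-2.175, +11.191]  MdAPE=6.71%
hf_nu  5-min @80%:  r=0.934  ccc=0.888  bias=+0.041  LoA=[-0.050, +0.132]  MdAPE=4.08%

group  initial_segments  retention_pct_30  retention_pct_50  retention_pct_80  retention_pct_95
  all              1800              97.8              95.6              85.6              75.6
```

Reading the numbers: mean HR is essentially immune to device noise
(r ≈ 1, zero bias). rMSSD is highly correlated but systematically
inflated by device timing jitter (+4.5 ms here — i.i.d. timing noise of
SD σ adds 6σ² to the mean squared successive difference), which is what
CCC penalizes relative to r. HFnu is slightly overestimated because
jitter adds white power across both bands. The retention sweep shows the
cost of stricter gating: raising the validity threshold from 30 % to
95 % discards progressively more 5-min segments.

The same pipeline is available from the shell:

```
hrvgate simulate --seed 1 --out cohort/       # paired per-night CSVs + manifest
hrvgate analyze --input cohort/ --thresholds 0.3,0.5,0.8,0.95 --out results/
hrvgate analyze --seed 1 --out results/       # or generate-and-analyze in one go
```

Outputs are plain CSV tables (`segments.csv`, `metrics_5min.csv`,
`paired.csv`, `summary.csv`, `participant_errors.csv`,
`mdape_heatmap.csv`, `retention.csv`) plus a `run_log.json` with
per-stage record counts.

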
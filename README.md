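# mermap

Microelectrode-recording (MER) analysis for intraoperative subthalamic-nucleus
mapping: artifact removal, spike sorting, background reconstruction, per-site
parameter extraction, and maximum-parameter target depth/location prediction
with accuracy and ROC evaluation — exercised end-to-end on a synthetic
Ben's-Gun session generator with full ground truth.

## Pipeline

1. **Artifact removal** (`mermap.artifacts`) — trim to 30 s, segment into
   non-overlapping 0.5 s epochs, score each boundary with the variance
   coefficient `vc[k] = var(s[k]) / var(s[k-1])`, discard epochs with
   `vc > 1.8`, and re-join survivors with short monotone pchip bridges.
2. **Spike sorting** (`mermap.sorting`) — zero-phase 4th-order Butterworth
   band-pass (500–5000 Hz); robust-sigma amplitude threshold
   (`4 · median(|x|)/0.6745`, both polarities, 1.5 ms lockout); 64-sample
   waveforms → 64 coefficients of a 4-level Haar decomposition; the most
   non-normal coefficients (Lilliefors statistic) feed superparamagnetic
   clustering (KNN Potts model, Swendsen–Wang sweeps across a temperature
   grid, co-membership correlation > 0.5).
3. **Background reconstruction** (`mermap.background`) — each spike window
   (0.5 ms before to 2.5 ms after) replaced with 3 ms of spike-free signal
   from a random location in the same trace, cross-faded, then low-passed at
   500 Hz.
4. **Feature extraction** (`mermap.features`) — the 19-parameter battery:
   epoch firing rates (Mean_SR/Max_SR), modal ISI, burst index, LvR, and
   Welch-spectrum mean amplitude / max peak / RMS over the canonical bands
   (low 2–7, alpha 8–12, low beta 13–20, high beta 21–30, beta 13–30,
   gamma 31–49 Hz).
5. **Localization & evaluation** (`mermap.localization`) — argmax-parameter
   depth prediction per trajectory and location prediction across the five
   Ben's-Gun trajectories, exact-match accuracy against ground truth,
   trapezoidal ROC/AUC with Hanley–McNeil standard errors, and Pearson
   correlations with Bonferroni correction.
6. **Synthetic sessions** (`mermap.synthetic`) — 5 trajectories × 15 depths
   (−10 … +4 mm), region-dependent profiles (thalamus-ZI / white matter /
   STN / SNr) with gamma-renewal spike trains, 70–150 µV biphasic templates
   on 2–6 µV background, band-limited oscillations (low-beta peak in STN,
   gamma in SNr), optional exogenous artifacts, and a complete ground-truth
   sidecar.

## CLI

```bash
mermap simulate --seed 1 --out session.h5        # + session.ground_truth.json
mermap clean session.h5 --out clean.h5 --report rejections.csv
mermap sort clean.h5 --out spikes.csv --no-cluster
mermap background clean.h5 spikes.csv --out background.h5
mermap features session.h5 --out features.csv
mermap localize features.csv --truth session.ground_truth.json \
    --out report.csv --roc-out roc.csv
mermap run --config run.cfg                      # full reproducible run
```

`run.cfg` is a flat `key = value` file covering every tunable
(`mermap.config.RunConfig` lists the keys and defaults); the master seed
derives all stage seeds deterministically.

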
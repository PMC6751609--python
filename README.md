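# myonet

Lower-limb **muscle networks** and **signal synergies** from multichannel
surface EMG recorded during gait, with a fully specified synthetic generator
standing in for patient recordings.

The package targets the analysis style used to compare gait coordination
between patients with myotonic dystrophy type 1 (DM1) and healthy controls:
rather than looking only at activation amplitudes, it treats the eight
recorded muscles (rectus femoris RF, biceps femoris BF, tibialis anterior TA,
gastrocnemius medialis G, both sides) as nodes of a frequency-resolved
network whose edges express shared neural drive.

## What it computes

From 8-channel EMG at 1 kHz with heel-strike/toe-off annotations:

1. **Envelopes** — zero-phase 0.5–70 Hz band-pass, down-sampling to 200 Hz,
   Hilbert-magnitude rectification; gait-cycle epoching (right heel strike to
   right heel strike) with phase normalization.
2. **Spectra** — per-muscle normalized power spectral density on a 2 Hz grid
   (35 bins covering 0–70 Hz).
3. **Undirected networks** — intermuscular coherence (IMCoh): Welch
   magnitude-squared coherence of envelope pairs (1 s Hanning windows, 75 %
   overlap, cross-spectra pooled over windows and trials).
4. **Directed networks** — a multivariate autoregressive (MVAR) model of the
   envelopes, order selected by AIC and validated against the nonparametric
   coherence, from which partial directed coherence (PDC, column-normalized)
   gives the direction of information flow between muscles.
5. **Frequency components** — non-negative matrix factorization (alternating
   least squares) of the pair-by-frequency connectivity matrix into spectral
   signatures and per-component edge weights.
6. **Graph metrics** — weighted clustering coefficient, global efficiency and
   betweenness centrality of each component's muscle graph.
7. **Muscle synergies** — Lee–Seung multiplicative-update NMF of the
   muscle-by-time envelope matrix, `M = W C + E`, with the number of
   synergies chosen as the smallest `k` whose variability accounted for
   (VAF) exceeds 90 %; cycle-to-cycle synergy variability.
8. **Gait & posture** — gait-cycle duration, step cadence, stance:swing
   ratio; centre-of-pressure path length, 90 % sway-ellipse area, Romberg
   quotient.
9. **Group statistics** — KS normality screen, factorial ANOVA with partial
   η², Bonferroni post-hocs, Spearman correlation, and the regression of
   synergy variance on connectivity summaries.

Because no public recordings exist for this population, the
`myonet.synthetic` module generates gait EMG from a *planted* generative
model (synergy matrices, band-limited common drives, lagged directed
couplings, amplitude-modulated broadband carrier) with `HC` and `DM1`
presets, so every estimator can be validated by parameter recovery.

## Worked example

```python
import dataclasses
import myonet as mn

cfg = dataclasses.replace(mn.preset("HC"), seed=1)
rec = mn.generate_emg(cfg)                       # 63 s of 8-channel EMG
env = mn.make_envelopes(rec)                     # 0.5-70 Hz, 200 Hz, Hilbert

spec = mn.normalized_psd(env)
peak = spec.bin_centers_hz[spec.psd.mean(axis=0).argmax()]
print(f"envelope PSD peak bin: {peak:.0f} Hz")

smooth = mn.preprocess.smooth_envelopes(env)     # synergy input
epochs = mn.epoch_by_cycles(smooth, rec)
model = mn.select_n_synergies(epochs.concatenated(), k_max=8, seed=1,
                              n_restarts=5)
print(f"synergies: k={model.k}, VAF={model.vaf_pct:.1f}%")

conn = mn.imcoh([env])
fc = mn.decompose_spectra(conn, K=4, n_restarts=4, seed=1)

gait = mn.gait_parameters(rec.heel_strikes, rec.toe_offs)
print(f"gait: GCD={gait.gcd_s:.2f} s  cadence={gait.cadence_hz:.2f} steps/s  "
      f"SSR={gait.ssr:.2f}")
```

prints

```
envelope PSD peak bin: 11 Hz
synergies: k=2, VAF=92.8%
gait: GCD=1.05 s  cadence=1.90 steps/s  SSR=1.50
```

The 11 Hz bin is the 2 Hz analysis band [10, 12) containing the planted
10 Hz common drive of the healthy-control preset; `k=2` recovers the two
planted synergies (the VAF curve is 88.8 % at k=1, 92.8 % at k=2, so 2 is
the smallest count above the 90 % threshold); the gait numbers are the
normative cadence (~1.9 steps/s) and the 60:40 stance:swing split (ratio
1.5) built into the event stream.  Decomposing the coherence spectra at
K=4 isolates a component whose signature peaks in the 10 Hz bin; on its
muscle graph the distal muscles carry the hub role (mean betweenness 5.75
for TA/G vs 1.25 for RF/BF with this seed), the planted ankle-strategy
coupling.

A command-line interface mirrors the pipeline:

```bash
myonet simulate --preset DM1 --seed 4 --out work/dm1_04
myonet connectivity work/dm1_04 --estimator imcoh --out work/conn.tsv
myonet decompose work/conn.tsv --out work/components.json
myonet graph-metrics work/components.json --out work/metrics.tsv
myonet run-all --out work/full --n-hc 10 --n-dm1 7 --seed 0
```

## Layout

```
src/myonet/
  synthetic.py     generator (presets, EMG, COP, connectivity ensembles), I/O
  preprocess.py    filtering, decimation, Hilbert envelopes, epoching
  connectivity.py  normalized PSD, IMCoh, MVAR + AIC, PDC, model validation
  components.py    ALS NMF of connectivity spectra, VAF-based K selection
  network.py       weighted CC / GE / BC on muscle graphs
  synergy.py       Lee-Seung NMF synergies, VAF rank rule, cycle variability
  gait_posture.py  GCD / cadence / SSR, COP path, sway ellipse, Romberg
  stats.py         ANOVA + partial eta^2, Bonferroni, Spearman, regression
  pipeline.py      end-to-end driver with manifest
  cli.py           command-line interface
```

See `docs/methods.md` for the generative model, estimator conventions and
their limitations.
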
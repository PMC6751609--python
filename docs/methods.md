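# Methods

This note documents the models, estimator conventions and design choices of
`myonet`, and what the synthetic presets do and do not emulate.

## Synthetic gait EMG: the generative model

One subject's recording is built in four layers.

**Synergy layer.** Noise-free envelopes are the non-negative product
`W_true @ C(t)` of a planted synergy matrix (8 muscles x k_true) and
periodic recruitment curves over the gait phase. Recruitment curves are sums
of circular Gaussian bumps; per cycle, each synergy's amplitude is jittered
multiplicatively (log-normal with log-SD `recruitment_jitter`) and its phase
shifted (SD `0.05 * recruitment_jitter` cycles), emulating cycle-to-cycle
variation of muscle activation without new free-form mechanisms. A tonic
baseline (15 % of each muscle's peak) keeps the envelope positive.

**Common-drive layer.** Each drive band adds band-limited unit-SD Gaussian
noise, scaled by the gain times the muscle's envelope SD, to every muscle of
its subset. A shared drive creates intermuscular coherence confined to the
band; a single-muscle "drive" shapes the PSD without creating coherence.
Band noise is realized by filtering white noise to the 2 Hz *analysis* bin
containing the nominal center (e.g. 10 Hz -> [10, 12) Hz). Aligning planted
bands with the analysis grid makes planted-band recovery well-posed: a band
symmetric about a bin edge would split its power between two bins and the
maximal bin would be a coin flip.

**Directed-coupling layer.** Each coupling adds a lagged, gain-scaled copy
of the source muscle's (mean-removed) envelope to the target, creating the
asymmetry that partial directed coherence measures.

**Carrier layer.** The raw signal is the envelope multiplying zero-mean
white Gaussian noise (a surrogate for interference EMG), plus additive
sensor noise. This makes the pipeline's rectification step meaningful: the
Hilbert envelope of the filtered signal recovers the planted envelope up to
multiplicative demodulation noise, as with real EMG.

Gait events are deterministic: right heel strikes every `cycle_duration_s`,
left events offset by half a cycle, toe-offs at 60 % of the cycle (the
normative stance:swing split).

### Presets

| | HC | DM1 |
|---|---|---|
| planted synergies k_true | 2 (plantarflexor / dorsiflexor, concentrated on G and TA — the ankle strategy) | 5 (spread over proximal and distal muscles, one mixed crossed pattern) |
| cycle duration | 1.05 s (cadence 1.90 steps/s) | 1.4 s |
| recruitment jitter | 0.05 | 0.30 |
| common drives | 10 Hz over distal pairs (TA–TA, G–G across limbs; TA–G within limb), incoherent 10 Hz on proximal muscles | dominant incoherent ~6 Hz on every muscle; coherent 5/8/18/35 Hz drives over proximal–distal and crossed pairs |
| directed couplings | distal, unidirectional (TA->G within limb, G_l->G_r) | bidirectional proximal-distal and crossed |

Drive gains and bump widths were fixed once so that the planted spectral
peak dominates the gait-cycle harmonics of the envelope and the VAF-90 rank
rule recovers the planted synergy counts; they are the conditions the
presets exist to emulate (group PSD peaks near 10 Hz and 6 Hz, two
control-like vs five patient-like synergies), not free parameters of the
analysis.

**What the generator does not emulate:** motoneuron-pool physiology,
biomechanics (no force or kinematic consistency), non-stationary fatigue or
myotonic after-discharges, electrode artifacts, cross-talk. Passing the
planted-recovery tests therefore shows that the estimators are correct and
calibrated, not that the pipeline is robust to every artifact of real
recordings.

**COP traces** are stationary AR(1) processes per axis (correlation time
1 s, stationary SDs in mm); any bounded stationary process suffices to test
the posture metrics, which are purely geometric.

## Preprocessing

4th-order Butterworth band-pass 0.5–70 Hz applied forward–backward
(zero-phase) at the native rate; polyphase FIR resampling to 200 Hz; the
envelope is the magnitude of the analytic (Hilbert) signal. Filtering
precedes decimation, and the analytic signal is taken at 200 Hz. Trailing
partial gait cycles are dropped, never padded; phase normalization uses 200
points per cycle by default (configurable).

For **synergy extraction only**, envelopes are first low-pass smoothed
(zero-phase Butterworth, 8 Hz default): the Hilbert magnitude of a broadband
carrier carries Rayleigh-distributed demodulation noise (CV ≈ 0.52) that
bounds the attainable VAF of any low-rank model near 77 %, far below the
90 % rank threshold, whereas synergy recruitment lives below a few Hz.
Low-pass smoothing of envelopes before NMF is the standard convention in the
synergy literature. The spectral/connectivity chain always uses unsmoothed
envelopes (the drives of interest reach 35 Hz).

## Spectra and connectivity

* Analysis grid: 35 contiguous [2k, 2k+2) Hz bands covering 0–70 Hz, labeled
  by their centers (1, 3, …, 69 Hz). Native Welch lines at 0 Hz are excluded
  from band averages because segment detrending removes DC.
* PSD: Welch, 1 s Hann windows, 75 % overlap, per-channel normalization to
  unit total power.
* IMCoh: magnitude-squared coherence `|S_xy|^2 / (S_xx S_yy)` with cross-
  and auto-spectra averaged over all windows of all trials before the ratio
  (pooled mode; a per-trial mode that averages coherency magnitudes across
  trials and then squares is available). The nominal window overlap is 750 ms
  (75 % of the 1 s window). For independent signals the estimator's bias is
  `1/L_eff`, with `L_eff` the overlap-corrected effective window count; the
  calibration test checks this identity within 20 %.
* MVAR: least-squares VAR on demeaned envelopes; candidate orders 1..20
  (default) compared by AIC on a common effective sample; stability checked
  via the companion matrix. Model validation compares the model-implied
  coherence (from `S(f) = H Σ H*`, `H = A(f)^{-1}`) with the Welch coherence
  per pair; a pair is flagged when the spectral correlation is below 0.7
  *and* the mean absolute difference exceeds 0.05 — near-flat spectra of
  uncoupled channels have no shape to correlate and must not be flagged.
* PDC: column-normalized convention,
  `PDC(j->i, f) = |A(f)_ij| / sqrt(sum_k |A(f)_kj|^2)`, evaluated at the bin
  centers; the squared values over all targets (diagonal included) sum to
  one per source and frequency.

On envelope data the AIC-selected order typically saturates at the allowed
maximum — envelopes have rich autocorrelation — which is why the order cap
is exposed and recorded.

## Frequency components and graph metrics

The pair-by-frequency connectivity matrix is factorized by alternating
non-negative least squares (each sub-problem solved exactly, so the
Frobenius error is non-increasing per iteration), best of several restarts,
convergence at relative error change < 1e-6 or 500 iterations. Components
are reported with unit-maximum signatures (scale absorbed into edge
weights), sorted by ascending spectral centroid. The number of components is
the smallest K with VAF ≥ 90 % (mirroring the synergy rule; the threshold is
configurable). Each candidate K warm-starts from the previous solution, so
the VAF curve is non-decreasing by construction. Note that on healthy-like
data the group coherence matrix is close to rank one (the locomotor band
dominates), so the VAF rule may select K=1; fixed-K decomposition is
available for component-resolved comparisons.

Graph metrics are computed on the full weighted graphs (thresholding is for
display only): weighted clustering coefficient in the geometric-mean
triangle form with max-rescaled weights (Onnela; Fagiolo for directed
graphs), global efficiency as the mean inverse shortest-path length on
reciprocal-weight distances (zero weight = no edge; disconnected pairs
contribute zero), and betweenness centrality on the same distances, raw or
normalized by the number of source–target pairs. The test suite checks all
three against exhaustive triangle/path enumeration on random 8-node graphs.

## Synergies

Lee–Seung multiplicative updates for the Frobenius objective, 20 restarts
(uniform random initialization scaled by the data norm), convergence at
relative error change < 1e-6 or 1000 iterations; W columns unit-normalized
with the scale absorbed into C. Rank selection: smallest k with
`VAF = 100 (1 − ||E||_F^2 / ||M||_F^2) ≥ 90 %`; per-muscle VAF is reported
as a diagnostic. Envelope rows are scaled to unit variance before NMF by
default (configurable) so weak muscles still influence the rank choice.
Synergies are matched across gait cycles by Hungarian assignment on
W-column cosine similarity; cycle variability reports the mean matched
similarity, the coefficient of variation of recruitment curves (over cycles
sharing the modal k) and the per-cycle selected-k distribution.

## Gait and posture metrics

Gait-cycle duration is the mean right-heel-strike interval, cadence is
2/GCD (two steps per cycle), and the stance:swing ratio averages both sides'
mean-stance over mean-swing. The sway ellipse is the chi-square prediction
ellipse of the mean-removed COP covariance: area
`pi * chi2_2(0.90) * sigma1 * sigma2` with the principal-axis SDs
(chi-square quantile 4.6052 at 90 % coverage) — the standard posturography
construction. Only the mean is removed before the ellipse fit (configurable
detrending was considered and rejected as an extra degree of freedom). The
Romberg quotient is the eyes-closed over eyes-open area ratio. Device-
proprietary scores (gait quality index, stabilometric and static indices)
are out of scope; only their constituent quantities are computed.

## Statistics

The factorial ANOVA is a fixed-effects general linear model on cell values
(type-II sums of squares), with partial
`eta^2 = SS_effect / (SS_effect + SS_error)` and Bonferroni-corrected
pairwise t-tests. Caveat, stated deliberately: applying a fixed-effects
model to within-subject muscle-pair x frequency-bin cells ignores
subject-level correlation; the package reproduces this analysis shape
rather than substituting a mixed model. The KS normality check estimates
the reference mean/SD from the sample (no Lilliefors correction), making it
conservative — it is a screening device. The synergy-on-connectivity
regression reduces the 56 x 35 PDC values to per-component means (bins where
the component signature exceeds half its maximum, averaged over pairs)
because a full-dimension design cannot be estimated from small cohorts; a
rank-deficient or underdetermined design raises an error instead of being
silently regularized.

## Numerical conventions and degenerate inputs

* Multiplicative NMF updates guard denominators with 1e-12; exact-rank
  problems converge to VAF 100 % within 1e-6 given tight tolerances.
* All-zero frequency components yield zero metrics with a degeneracy flag;
  all-zero synergy cycles raise an error.
* Coherence values are clipped to [0, 1] against floating-point overshoot.
* Unstable MVAR models are rejected for PDC rather than silently used.
* Problem sizes in tests and the acceptance script (subject counts of 10,
  preset-length records of 45–63 s, 10-seed batches) are the package's
  defaults for desk-scale validation of the synthetic conditions.

## Known limitations

* NMF factors are identifiable only up to permutation/scale and only for
  (approximately) separable data; recovery tests plant separable factors.
* The 2 Hz grid quantizes spectral peaks to bin centers (odd frequencies);
  a planted 10 Hz drive is reported as its containing bin [10, 12).
* PDC magnitudes depend on the innovation covariance only through the
  coefficient estimates (the column-normalized convention is not scale-
  invariant across channels with very different noise floors).
* The Welch bias check, not confidence intervals, is the only inferential
  statement about coherence; no cluster or network-based statistics are
  implemented.
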
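# Methods

`lmotools` evaluates luminopsins (LMOs) — luciferase–opsin fusion proteins
that can be driven either by a physical light source (optogenetically) or by
a luciferin substrate oxidized by the tethered luciferase (chemogenetically).
The package implements the two analysis workflows of an LMO characterization
study, plus a synthetic generator that reproduces the statistical structure
of the raw recordings so every stage is testable end to end.

## Coupling efficiency from voltage-clamp sweeps

The headline statistic is the coupling efficiency

    CE = |I_luciferin| / |I_photo|

measured per cell under voltage clamp at −60 mV, 10 kHz sampling. Because
both currents flow through the same opsin population in the same cell, the
ratio is invariant to expression level; this is the property that makes CE
comparable across constructs.

**Photocurrent.** The lamp-evoked current is averaged over the last 100 ms
of the 1 s illumination epoch. The terminal window deliberately avoids the
transient peak: opsins desensitize over the first few hundred ms, and the
pre-adaptation peak is much less reproducible than the steady state.

**Luciferin-induced current.** The chemogenetic current follows luciferin
wash-in over tens of seconds, so there is no fixed measurement epoch.
"Where the amplitude plateaus" is operationalized as a sliding-window
search: a 1 s window moves over the post-onset region; a window qualifies
as a plateau when its fitted |slope| is below 5 % of its baseline-subtracted
mean per second, and among qualifying windows the deepest one wins (earliest
on ties). If nothing qualifies — a flat-zero response, or a sweep truncated
mid-rise — the deepest window overall is used and the measurement is flagged
(`plateau_fallback`), so a zero-coupling construct still yields a (noise-
level) amplitude rather than an error.

**Baseline.** Both amplitudes are baseline-subtracted using the mean over a
500 ms window ending 10 ms before the respective epoch; each sweep uses its
own pre-epoch baseline. The baseline length/gap are package choices — any
window comfortably longer than the noise correlation time behaves
identically.

**Nonfunctional calls.** Cells whose |photocurrent| falls below 5× the
baseline noise SD (robust MAD estimate from the baseline window) are flagged
"n.f." rather than contributing a noise-over-noise ratio; a cohort with no
functional cell is flagged as a nonfunctional construct. The 5 SD floor is a
package choice for an inherently qualitative call; it cleanly separates the
~−4 pA residual currents of the trafficking-impaired double-emitter preset
from every functional preset at default noise (5 pA SD).

**Display filter.** A zero-phase Gaussian low-pass with its half-power
(−3 dB) point at 250 Hz is provided for figures. The Gaussian magnitude
response is exp(−f²/2σ_f²); σ_f = f_c/√(ln 2) puts the response at 1/√2 at
f_c. Amplitude measurements always use the raw trace; the filter's DC gain
is exactly 1, so it would not bias the window means anyway (tested to
<0.1 %).

## Synthetic patch-clamp generator

The generator's defaults are the study conditions: 10 kHz sampling, 1 s
illumination, n = 5 cells per cohort, additive white Gaussian noise at
5 pA SD, lognormal cell-to-cell expression scaling with σ = 0.3.

**Photocurrent kinetics.** During light,

    I(t) = A · (1 − e^(−t/τ_rise)) · (r + (1 − r)·e^(−t/τ_desens)),

with exponential shut-off (τ_off) afterwards. Defaults τ_rise = 3 ms,
τ_desens = 150 ms, τ_off = 20 ms, r (plateau/peak) = 0.8 reproduce the
qualitative shape of excitatory channelrhodopsin photocurrents: peak within
a few ms, sustained plateau for the remainder of the pulse. Only the ratio
of the two currents is constrained by the study; absolute amplitudes A
(−450 to −900 pA per construct) are free parameters set at values typical of
well-expressing HEK293 cells.

**Luciferin wash-in.** Chamber concentration follows single-compartment
exchange, C(t) = C_final(1 − e^(−t/τ_wash)) with τ_wash = volume/flow
(1 mL / 1.5 mL·min⁻¹ ⇒ 40 s) and C_final = 100 µM. Receptor drive is
Langmuir occupancy with K_half = 20 µM, *normalized to its value at
C_final*:

    I_luc(t) = CE_true · A·r · f(C(t))/f(C_final).

The normalization makes the fully washed-in current exactly CE_true times
the photocurrent plateau — the generator's ground truth is defined at the
achieved chamber concentration, not at hypothetical substrate saturation.
Without it every recovered CE would be scaled by f(C_final) ≈ 0.83 and the
generator's labels would not mean what the analysis estimates.

**Stepped activation.** Bright-emitter constructs show discrete jumps in the
luciferin-induced current, interpreted as percentage-wise recruitment of the
expressed LMO population as luciferin spreads. With `step_count = K` the
normalized drive is quantized to the nearest multiple of 1/K, producing
K + 1 discrete levels (0 … 1). Nearest-level rounding (rather than
floor-and-hold) is used so that the final level is full activation once
wash-in passes 1 − 1/(2K); step heights and dwell times are not quantified
anywhere, so equal increments are one admissible phenomenology. Default
sweep length (165 s past onset) leaves the top level held for >2 minutes,
far longer than the 1 s plateau window.

## MEA analysis

**Noise and threshold.** Per-channel baseline noise SD is estimated as
1.4826 × MAD over a quiet window; MAD tolerates the spikes themselves where
a plain SD is inflated >20 % at ~1 % spike-sample occupancy. Spikes are
counted where the signal crosses −9 SD (negative polarity, the usual
extracellular trough); each maximal sub-threshold excursion contributes one
spike at its trough, crossings within 1 ms merge, and 1 s after each
treatment event is blanked to cover the time-locked application artifact.

**Rates and responders.** Firing rates are counts over half-open windows,
60 s before the event and 60 s starting after the blank. Responder
filtering (for luciferin treatments) keeps channels whose rate under a
blue-LED probe is ≥1.2× baseline — silent channels are kept iff they fire
under the LED. The 60 s window and 1.2 ratio are package defaults for
criteria the study states only qualitatively.

**Synthetic MEA recordings.** Channels fire as independent renewal
processes: ISIs are a 2 ms refractory period plus an exponential whose rate
is adjusted so the realized mean rate equals the nominal preset rate (a
thinned Poisson would undershoot by ~7 % at the highest preset rate,
34.75 Hz). Rates switch from `pre_rate` to `post_rate` at the event. Spikes
are biphasic 1 ms templates with a 12× noise-SD trough; at 9 SD threshold
against 12 SD spikes the detector's expected recall is >0.99 and the
Gaussian false-positive rate at 9 SD is negligible (per-sample tail
~10⁻¹⁹). The six shipped rate presets are the study's pooled per-electrode
means for two constructs × {LED, vehicle, CTZ}. What this generator does
*not* emulate: bursting, inter-channel correlation, electrode-to-electrode
rate heterogeneity beyond Poisson variability, waveform diversity, and
non-stationary drift — so passing recovery tests demonstrates correctness
of the measurement chain, not robustness to every property of real
cultures.

## Permutation test

Pre/post rate samples (possibly unequal sizes — different electrode sets
may enter the two conditions) are compared by the difference of means. The
null is built by pooling, shuffling, and re-splitting at the original group
sizes, 30,000 times; the two-sided p uses the add-one estimator
p = (k + 1)/(N + 1) with k the count of permuted |diff| ≥ |observed|, which is
a valid p-value (never 0) and reproduces the printed corrected floor
6/30001 → 0.0002 at m = 6 Bonferroni comparisons (3 treatments × 2
construct groups). A corrected value displayed as "0.0000" elsewhere is
treated as display rounding of the same floor. Implementation detail: the
pool is sorted before shuffling and split at the smaller group size —
distribution-identical to splitting at the original sizes, and it makes the
two-sided p exactly invariant under swapping the pre/post labels at a fixed
seed. Group means are reported with Student-t 95 % CIs.

## Radiance vs coupling

Plate-reader luminescence is normalized per well to reporter fluorescence
(mean of well ratios per construct, n = 8 wells). The generator couples
emission to CE through a donor-quenching factor 1 − q·CE (q = 0.7): if
luciferase-to-opsin FRET is efficient, donor photons are lost to energy
transfer, so radiance and CE vary inversely. The summary statistic is the
Spearman rank correlation between CE (nonfunctional constructs ranked at
CE 0) and mean normalized radiance; only ordinal radiance claims are
testable, so preset radiance values encode the reported ranking (the
double-emitter nonfunctional construct brightest) rather than absolute
photon counts. With all-tied radiance the correlation is reported as NaN.

## Numerical choices and problem sizes

- Sliding-window statistics use O(n) cumulative sums; window means and OLS
  slopes are exact (no FFT approximation).
- Epoch times convert to samples by rounding; intervals are half-open
  everywhere, so a spike exactly at a window end is excluded.
- Permutation ties count as exceedances, with an ulp-scale tolerance
  (10⁻¹² relative) so reorderings of identical values compare equal.
- Seeds: every stochastic entry point takes an integer seed or a
  `numpy.random.Generator`; batch runs derive independent per-task streams
  from a `SeedSequence`, all below 2³¹.
- Test/acceptance problem sizes: 5-cell cohorts with 170 s luciferin
  sweeps; 30-channel, 135 s MEA recordings for rate recovery; 8 channels for
  detector calibration; 1000 replicates × 999 permutations for type-I
  calibration. These sizes put Monte-Carlo error comfortably inside each
  check's tolerance.

## Known limitations

- The plateau search maximizes |mean − baseline| over many overlapping
  windows, so in pure noise it returns a small positive-biased magnitude
  (extreme-value effect, ≲0.3 pA at default noise) — negligible against
  functional currents but the reason zero-coupling constructs report CE
  ~10⁻³ rather than exactly 0.
- CE recovery carries a ≈0.3 % downward bias from finite wash-in (occupancy
  reaches 99.7 % of its final value by the end of the default sweep).
- The permutation test treats pooled electrodes as exchangeable independent
  samples; hierarchical structure (culture, DIV) is deliberately not
  modelled.
- No vendor binary formats; the CSV + JSON sidecar dialect is the only
  on-disk representation.
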
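# lmotools

Analysis toolkit for **luminopsins** (LMOs) — luciferase–opsin fusion
proteins that make a neuron's opsin addressable both optogenetically (LED or
arc lamp) and chemogenetically (a luciferin such as coelenterazine, oxidized
by the tethered luciferase into bioluminescence that gates the opsin).

It is written for electrophysiologists screening LMO constructs, and covers
the three measurement chains such a screen needs:

1. **Patch clamp → coupling efficiency.** From whole-cell voltage-clamp
   sweeps (10 kHz, −60 mV), measure the lamp-evoked photocurrent at steady
   state (last 100 ms of a 1 s illumination) and the luciferin-induced
   current at its wash-in plateau, and form the construct's coupling
   efficiency

   CE = |I_luciferin| / |I_photo|,

   an expression-independent measure of how well the luciferase drives its
   own opsin. Cells without a usable photocurrent are called "n.f."
   (nonfunctional) instead of reporting a noise ratio.

2. **MEA → firing-rate statistics.** On multielectrode-array recordings of
   spontaneously active cortical cultures, detect spikes where the signal
   exceeds 9 standard deviations of the baseline noise (robust MAD
   estimate), restrict to responder electrodes (firing increases under a
   blue-LED probe), count spikes in 60 s windows before and after a
   treatment (LED / vehicle / luciferin), and test pre-vs-post mean rate
   differences with a 30,000-iteration permutation test under Bonferroni
   correction. p-values use the add-one estimator (k+1)/(N+1).

3. **Plate reader → radiance.** Normalize bioluminescence to fluorescent-
   reporter expression per well and rank constructs; efficiently coupled
   constructs emit *less* light (FRET donor quenching), so CE and radiance
   correlate negatively (Spearman).

Because raw recordings from such a study are not bundled here, a
first-class synthetic generator (`lmotools.synth`) produces patch sweeps,
MEA recordings (with ground-truth spike times) and plate tables with the
statistical structure the analyses assume, parameterized per construct by a
shipped preset registry (`lmotools.PRESETS`, `lmotools.MEA_RATE_PRESETS`).
See `docs/methods.md` for the models and their assumptions.

## Worked example

Simulate a 5-cell cohort of the GeNL_SS–ChRmine construct (preset
`lmo11`, true CE 0.65) and analyze it:

```python
import lmotools as lt

pairs = lt.make_patch_cohort(lt.get_preset("lmo11"), n_cells=5, seed=1)
results, summary = lt.analyze_cohort(pairs)
for i, r in enumerate(results, 1):
    print(f"cell {i}: photo {r.photocurrent.amplitude_pA:8.1f} pA  "
          f"luciferin {r.luciferin_current.amplitude_pA:8.1f} pA  CE {r.display_ce}")
print(f"cohort mean CE = {summary.mean_ce:.3f} (n = {summary.n_functional})")
```

```
cell 1: photo   -621.5 pA  luciferin   -403.9 pA  CE 0.65
cell 2: photo   -716.9 pA  luciferin   -465.9 pA  CE 0.65
cell 3: photo   -618.6 pA  luciferin   -402.0 pA  CE 0.65
cell 4: photo   -379.0 pA  luciferin   -246.4 pA  CE 0.65
cell 5: photo   -735.3 pA  luciferin   -477.8 pA  CE 0.65
cohort mean CE = 0.650 (n = 5)
```

Photocurrents vary more than two-fold with the cells' expression levels,
but the per-cell ratio — and hence the cohort mean — recovers the
construct's coupling efficiency.

The same workflows are available from the shell:

```bash
lmotools simulate-patch --preset lmo11 --n-cells 5 --seed 1 --out runs/lmo11
lmotools analyze-patch  --in runs/lmo11 --out runs/lmo11_results
lmotools simulate-mea   --preset lmo7 --treatment ctz --channels 30 --seed 1 --out runs/mea
lmotools analyze-mea    --in runs/mea --window 60 --threshold-sd 9 --out runs/mea_results
lmotools permtest       --in rates.csv --n-perm 30000 --m 6 --seed 1 --out perm.csv
```

Traces are exchanged as UTF-8 CSV (time in seconds; currents pA; voltages
µV) with a JSON sidecar carrying sampling rate, epoch/event annotations and
— for simulated MEA data — ground-truth spike times. Every run echoes its
resolved configuration and seed into the output directory.

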
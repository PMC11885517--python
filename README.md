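# cploc — Bayesian inference in change-point sound localization

`cploc` is a simulation and analysis pipeline for a dynamic auditory
localization task: a listener hears a sequence of sounds whose azimuth
locations scatter (SD 10°, "experimental noise") around a hidden generative
mean; with hazard H = 1/6 each sound is a change-point at which the mean is
resampled uniformly in ±60°; each sound is, with probability 1/12, the final
*probe* whose location must be reported together with an 80% uncertainty
interval. Every sequence is presented twice — audio-only (A) and
audio-visual (AV, sensory noise fixed at 1°) — never in adjacent slots.

The package provides:

* **a generative task simulator** (`cploc.task`) reproducing exactly this
  design, including paired A/AV sessions;
* **a near-optimal Bayesian observer** (`cploc.observer`) that tracks a
  gridded posterior over the generative mean μ. Before sound *t* the belief
  is mixed with the reset distribution, `prior_t = (1−H)·post_{t−1} + H·U(±60°)`,
  and updated with a Gaussian likelihood of SD √(σ_exp² + σ_s²). Two
  per-sound latent variables are extracted: **prior uncertainty**
  PU_t = SD(post_{t−1}) and **surprisal** SU_t = −ln p_prior(x̃_t), the
  negative log density of the full prior at the noisy observation. At the
  probe the observer reports the mean and central 80% credible interval of
  its posterior over the probe's *location*;
* **maximum-likelihood fitting** (`cploc.fitting`) of sensory noise σ_s and
  response noise σ_m to localization responses, marginalizing sensory noise
  by common-random-number Monte Carlo;
* **behavioral metrics** (`cploc.behavior`): estimation error
  |x_resp − x_t|, response uncertainty, and prior bias
  (x_resp − x_t)/(x_{t−1} − x_t), summarized by condition × SAC
  (sounds-after-change-point) level;
* **a synthetic-EEG generator** (`cploc.synth_eeg`) with implanted
  PU/SU-driven ERP and oscillatory components on a 1/f background, with
  ground-truth masks;
* **spectral decomposition** (`cploc.spectral`): induced power (evoked
  response subtracted), 4–30 Hz Hanning STFT (300 ms windows, 16 ms steps)
  and 40–100 Hz multitaper (windows 250→100 ms), with relative-change
  baselining against 0–500 ms;
* **mass-univariate regression + cluster permutation**
  (`cploc.regression`): per-subject OLS of z-scored EEG on z-scored PU and
  SU, group sign-flip permutation tests with max-cluster-mass correction
  (cluster-forming α = 0.001, 1000 permutations, clusters > 5 ms; PU window
  −250..100 ms, SU window 0..500 ms; AV−A paired contrasts);
* **brain–behavior linking** (`cploc.brain_behavior`): cluster-averaged
  probe-epoch activity regressed on trial-level behavior, group one-sample
  t-test at α = 0.05.

## Worked example

```python
import numpy as np
from cploc import task, observer

rng = np.random.default_rng(3)
session = task.generate_session(task.TaskConfig(), 300, rng)
a = observer.ObserverParams(sensory_noise_sd=10.0)
av = observer.av_params(a, 1.0)
latents, trials = observer.run_session(session, {"A": a, "AV": av}, rng=rng)

inc = latents[~latents.is_first]
print(inc[inc.sac <= 6].groupby("sac")[["pu", "su"]].median().round(2))
covered = ((trials.probe_location >= trials.ci_low)
           & (trials.probe_location <= trials.ci_high)).mean()
print(f"coverage: {covered:.1%}")
```

prints (seed 3):

```
        pu    su
sac
1     7.65  6.43
2    10.05  4.14
3     8.10  3.94
4     7.42  3.92
5     6.71  3.84
6     6.33  3.85
coverage: 81.8%
```

Surprisal is maximal at SAC 1 (the change-point sound itself, where the old
prior misfits the new location) and prior uncertainty at SAC 2 (the belief
carried *into* the second sound reflects the reset triggered by the first).
Median PU is higher in A than AV (8.92 vs 6.39: noisier input, broader
belief) while mean SU is higher in AV than A (6.18 vs 4.54: a tighter prior
is more surprised by change-points), and the 80% credible interval covers
the true probe location on ~80% of trials — the observer is calibrated.

## Analysis scripts

The `analysis/` drivers run the full study on simulated data and write
tables under `results/`:

| script | what it does |
|---|---|
| `01_simulate_task.py` | session + generative statistics check |
| `02_run_observer.py` | latents, SAC medians, interval calibration |
| `03_fit_observer.py` | σ_s / σ_m parameter recovery |
| `04_behavior.py` | behavioral metrics, SAC summaries, error–uncertainty correlation |
| `05_simulate_eeg.py` | synthetic epochs with ground truth |
| `06_regression_clusters.py` | time-domain PU/SU clusters, AV−A contrast |
| `07_tfr_clusters.py` | low-band induced-power regression clusters |
| `08_brain_behavior.py` | probe-epoch cluster scores vs behavior |

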
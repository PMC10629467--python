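# somnostate

Whole-brain EEG analysis during general anaesthesia: microstate
segmentation and quantifiers, Wackermann state space descriptors, and
mixed-effects trend models over anaesthesia duration — with a synthetic
cohort generator carrying known ground truth, so the entire chain is
testable without patient data.

## Who this is for

Clinical neurophysiologists and methods researchers who work with
intraoperative multichannel EEG (19-channel International 10/20 montages)
and want a reproducible, scriptable pipeline for:

* **EEG microstates** — sub-second periods of quasi-stable scalp topography,
  conventionally grouped into four classes A–D. Maps at peaks of the global
  field power (GFP, the spatial standard deviation of the average-referenced
  map) are clustered by a polarity-blind modified k-means; grand-mean class
  maps are built hierarchically with permutation/polarity alignment and
  labelled against canonical templates. Back-fitting yields per-interval
  **duration** (ms), **frequency of occurrence** (1/s) and **GFP** (µV) per
  class, with truncated edge segments discarded.
* **State space descriptors** — for each 2.5-s epoch, a spatial PCA of the
  channel covariance gives eigenvalues λ₁…λ_k, from which
  **σ = Σλᵢ** (total field variance, µV²),
  **φ = (1/2π)·√(Σ‖u̇(t)‖² / Σ‖u(t)‖²)** (generalized frequency, Hz), and
  **Ω = exp(−Σ λ'ᵢ ln λ'ᵢ)** with λ'ᵢ = λᵢ/Σλ (spatial complexity, a
  lower-bound estimate of the number of uncorrelated generator processes,
  ranging from 1 to k).
* **Suppression EEG** — intraoperative periods with all-channel
  peak-to-peak amplitude below 10 µV, a marker of excessively deep
  anaesthesia, handled as a first-class factor throughout.
* **Trend models** — linear mixed-effects models (random intercept per
  patient) of each quantifier/descriptor against anaesthesia duration ×
  suppression × subsequent postoperative delirium (POD), expanded with
  microstate class for the quantifiers, adjusted for age, sex, MMSE band,
  ASA physical status, surgical site, anaesthetic type and randomization
  arm. Per-cell duration slopes (e.g. Supp⁺|POD⁺) come out as coefficient
  contrasts with 95% CIs; topographic differences are tested with a
  randomization test (TANOVA) plus channel-wise t-maps.

## Worked example

```python
import numpy as np
from somnostate.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    seed=7,
    simulation={"epochs_per_set": 8},
    cohort={"n_patients": 10, "intervals_per_patient": 4, "suppression_fraction": 0.4,
            "group_effects": {"log_gain_slope": {(True, True): 0.004},
                              "concentration_slope": {(True, True): 0.005}}},
    clustering_restarts=8,
    n_permutations=199,
)
results = run_pipeline(cfg, "out/demo")
print(results["descriptors"].head(4).round(2).to_string(index=False))
print(results["contrasts"]["omega"].round(4).to_string(index=False))
```

```
patient_id  mean_time  suppression   sigma   phi  omega
      P000      16.17        False 1213.79 10.29   3.91
      P000      46.15         True    8.41  9.97   3.27
      P000      72.56        False 1230.40 10.23   3.82
      P000     106.13        False 1260.91 10.15   3.83
  pod  suppression  estimate     se  ci_low  ci_high      p
False        False    0.0003 0.0008 -0.0013   0.0019 0.7053
False         True    0.0019 0.0010 -0.0002   0.0039 0.0715
 True        False   -0.0008 0.0013 -0.0033   0.0017 0.5383
 True         True   -0.0104 0.0041 -0.0185  -0.0024 0.0113
```

The descriptor table shows what the generator built: ~30-min interval
spacing, suppression intervals with σ pinned two orders of magnitude below
non-suppression intervals, φ near the 10 Hz carrier, Ω near the effective
rank of a four-class topographic process. The ω contrast table recovers the
injected ground truth: the occupancy-concentration drift placed only in the
suppression-with-subsequent-POD cell appears as a negative ω slope exactly
there (−0.010 per minute, CI excluding zero) and nowhere else.

The same pipeline is scriptable from the shell:

```bash
somnostate simulate --config cfg.json --out sim/      # EDF + ground truth
somnostate preprocess --edf sim/P000.edf --out prep/  # filter, reference, epochs
somnostate microstates --epochs prep/P000_epochs.h5 --out ms/
somnostate quantify --epochs prep/P000_epochs.h5 --maps ms/P000_class_maps.csv --out q/
somnostate statespace --epochs prep/P000_epochs.h5 --out d/
somnostate stats --quantifiers q.csv --descriptors d.csv --meta m.csv --out st/
somnostate run --config cfg.json --out full/          # everything, one command
```

## Layout

| module | role |
| --- | --- |
| `somnostate.synth` | synthetic cohorts with ground truth (maps, sequences, trends) |
| `somnostate.preprocess` | 2–20 Hz zero-phase band-pass, average reference, suppression flagging, interval assembly |
| `somnostate.microstates` | GFP, peak picking, polarity-blind modified k-means, aligned averaging, template labelling |
| `somnostate.quantifiers` | back-fitting, truncation-aware segmentation, duration/occurrence/GFP |
| `somnostate.statespace` | spatial PCA, sigma, phi, omega |
| `somnostate.stats` | mixed models, cell contrasts, predicted trajectories, TANOVA, t-maps |
| `somnostate.pipeline` / `somnostate.cli` | configuration, orchestration, report bundle, CLI |

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
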
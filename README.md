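# gainmod

Subunit-resolved analysis of how locomotion modulates sensory tuning in
visual cortex.

Neurons in mouse visual cortex are tuned to the direction of visual motion,
and running changes the gain of their responses. `gainmod` asks a sharper
question: does running speed modulate a neuron's tuning *as a whole*, or
does it adjust the gain of individual **functional subunits** — the
direction-specific fragments of the tuning curve — differently? The package
provides the full analysis chain for trial-level recordings (and a
synthetic generator that emulates them):

- estimation of direction x running-speed tuning curves from trial tables
  (8 directions x 5 temporal frequencies x 8 speed bins on 0-20 cm/s),
  with the quality-control filter cascade;
- a bootstrap test of speed modulation (statistic
  `d_mod(R) = sum_l || R[:, l] − R̄ ||`, the summed distance of each speed
  slice from the speed-averaged tuning, against speed-shuffled surrogates);
- the core model, a **sparse subunit decomposition**

      R̂[k, l] = Σ_i φ_i[k, l] · m[i, l]² · s[i]²,

  fitted by penalized least squares
  (`MSE + λ·mean(s²) + λ·mean(m²)`) over a λ grid with permutation-null
  model selection, exposed statsmodels-style as
  `SubunitDecomposition(curve).fit(...) → SubunitDecompositionResults`
  (scaled modulators `g[i, l] = m²s²`, significant subunits, SNR,
  `summary()`);
- a bootstrap test of **differential modulation** of the two strongest
  subunits (statistic ρ̄, the best average correlation of one non-negative
  curve with both modulators, against shared-modulation surrogates);
- k-means clustering of modulator shapes, correlation-plane
  classification, strength ratios;
- **MAP population decoding** of stimulus direction and running speed from
  simulated populations of direction-selective and orientation-selective
  neurons (shared vs independent subunit modulation), plus a data-matched
  variant driven by fitted curves.

## Worked example

```python
import numpy as np
from gainmod import (
    SubunitDecomposition, generate_trials, sample_neuron,
    build_tensor, average_frequency, qc_filters, test_modulation,
    threshold_normalize, null_snr_distribution, select_fit,
)
from gainmod.simulate import uniform_speed_sampler

rng = np.random.default_rng(7)
# an orientation-selective neuron whose two subunits are modulated
# independently by running speed
neuron = sample_neuron("independent", n_subunits=2, rng=rng)
trials = generate_trials([neuron], 4800, rng,
                         speed_sampler=uniform_speed_sampler())
trials["response"] = threshold_normalize(trials["response"].to_numpy())

tensor = build_tensor(trials)
print(qc_filters(tensor))
curve = average_frequency(tensor)

mod = test_modulation(trials, n_boot=200, rng=rng)
print(f"d_mod = {mod.d_mod_data:.2f}, 95% null threshold = {mod.threshold:.2f}, "
      f"significant = {mod.significant}")

model = SubunitDecomposition(curve)
fits = model.fit_path(rng=rng)                      # 10 sparsity values
lams, null = null_snr_distribution([curve], n_null=200, rng=rng)
best = select_fit(fits, lams, null)
print(best.summary())
```

Output (abridged):

```
QCReport(passed=True, reasons=[])
d_mod = 9.12, 95% null threshold = 1.94, significant = True
Sparse subunit decomposition
==============================================
lambda:          0.0200
SNR:             8.55 dB
MSE:             0.10662
significant:     [1, 2, 4, 5, 6]
----------------------------------------------
 dir (deg)    mean gain  significant
         0       0.0000
        45       2.4346          yes
        90       0.7897          yes
       135       0.0000
       180       0.6398          yes
       225       1.9621          yes
       270       0.6258          yes
       315       0.0000
```

The neuron passes QC, and its tuning is strongly speed-modulated: the
observed d_mod is almost five times the 95th percentile of the
speed-shuffle null. The decomposition selected at λ = 0.02 reconstructs
the curve at 8.6 dB SNR; its two strongest subunits sit on antipodal rows
(45° and 225°, mean gains 2.43 and 1.96) — the orientation-selective,
differentially modulated architecture the analysis is designed to detect —
while the weaker flanking rows reflect the width of von-Mises tuning on a
45° grid.

A full pipeline run (simulate → QC → specificity gate → modulation test →
decomposition → differential test → clustering) with survivor counts at
every filter stage:

```bash
gainmod run --seed 1 --out runs/demo        # or: gainmod.pipeline.run_pipeline
```

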
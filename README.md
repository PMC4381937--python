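# methylib

Sequence determinants of DNA methylation states: what keeps CpG islands
unmethylated, and how much of it is CG density versus transcription-factor
binding?

`methylib` is a Python package for analysing insertion libraries of DNA
fragments whose methylation is read out by bisulfite sequencing. It
implements the full computational chain of such a study — in-silico
digestion of a genome with methylation-sensitive restriction enzymes,
size selection and reference-set construction, bisulfite read assignment
and filtered methylation calling, the CG-density model and its
combination with DNase hypersensitivity, sequence-design utilities for
synthetic constructs, and condition-pair methylation-dynamics profiling —
together with a synthetic-data generator so that every stage runs and is
tested without any external download.

## The model

The methylation a fragment acquires is a sigmoidal function of its CG
density x (CG starts per 100 bp):

    y(x) = 100 / (1 + exp(-b (x - c)))        b < 0

with the asymptotes fixed at 100% and 0% before fitting (the known
saturation states of methylation data), leaving slope `b` and inflection
`c` as the only free parameters. The reference coefficients are
`b = -0.337`, `c = 6.917`: methylation crosses 50% at ~6.9 CGs/100 bp
and falls below 20% beyond ~11 CGs/100 bp — the density regime that
protects a sequence by itself. TF binding adds a second, spatially
confined protection: the combined model regresses methylation on the
sigmoid prediction plus categorised DNase cut counts collected in a
300 bp window around each CG, trained on two contigs and evaluated on
the held-out rest of the genome.

## Worked example

```python
import numpy as np
from methylib import SigmoidModel, fit_sigmoid, DEFAULT_B, DEFAULT_C

model = SigmoidModel(DEFAULT_B, DEFAULT_C)
print(round(model.predict(6.917), 1), round(model.predict(12.0), 2))

rng = np.random.default_rng(0)
density = rng.uniform(2, 20, 183)
meth = np.clip(model.predict(density) + rng.normal(0, 10, 183), 0, 100)
fit = fit_sigmoid(density, meth)
print(round(fit.b, 3), round(fit.c, 3), round(fit.r_squared, 3))
```

prints

```
50.0 15.28
-0.31 6.753 0.881
```

— at the inflection density the model predicts 50% methylation, at 12
CGs/100 bp it predicts 15.28%, and refitting 183 noisy synthetic
fragments recovers the generating coefficients.

The numbered scripts under `analysis/` run the full study on synthetic
data and write their tables to `results/`:

```
01_simulate_data.py     # genomes, ground-truth methylomes, DNase tracks
02_design_library.py    # enzyme screen, digestion, reference fragment set
03_call_methylation.py  # 50x bisulfite reads -> filtered per-CG calls
04_fit_cg_model.py      # sigmoid fit + dinucleotide regression screen
05_combined_model.py    # CG / DHS / CG+DHS comparison, window scan
06_design_sequences.py  # CG-preserving mutants, REST motif pair
07_dynamics.py          # differentiation vs cancer change profiles
```

A complete run takes a few minutes. Headlines from the bundled
conditions: the end-to-end pipeline (digest → sequence → call → fit)
returns `b = -0.306, c = 6.329, R² = 0.957` against generating values
(-0.337, 6.917); the held-out R² ordering is CG+DHS (0.67) > CG (0.38) >
DHS (0.01); the DNase collection-window scan peaks at 300 bp, the
generating footprint; differentiation-like methylation gains track the
CG-density prediction within 7 points per bin while cancer-like gains
are flat 30-point shifts even where the model predicts <20%.

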
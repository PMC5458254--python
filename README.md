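# oemri — oxygen-enhanced MRI hypoxia mapping

Tumor hypoxia drives treatment resistance in gliomas, but the reference
measurements — fiber-optic pO2 probes, immunohistochemistry for markers
such as GLUT-1 — are invasive or post-mortem.  Oxygen-enhanced MRI
(OE-MRI) offers a noninvasive alternative: during a breathing-gas
switch from room air to 100% oxygen, dissolved paramagnetic O2 raises
T1-weighted signal wherever tissue is well oxygenated, so voxels that
fail to enhance flag hypoxia.

This package implements the full analysis chain for three-stage
(pre-oxygen / oxygen / post-oxygen) gas-challenge dynamic series, for
imaging scientists working with such data or validating methods against
synthetic ground truth:

- **PSIC mapping** (`oemri.psic`): per-voxel percentage of
  signal-intensity change,
  `PSIC = 100·(SI_max − SI_pre)/SI_pre`, with `SI_pre` the pre-oxygen
  stage mean and `SI_max` the oxygen-stage peak of the (optionally
  smoothed) voxel time course; high/low classification at a threshold
  (default 10%) and the **low-PSIC area fraction** of a tumor mask.
- **pO2 trace analysis** (`oemri.po2`): stage-wise summaries of probe
  traces, `ΔpO2 = pO2_max − pO2_pre` (both stage means), and pairing of
  ROI PSIC values with ΔpO2.
- **Statistics** (`oemri.stats`): Spearman rank correlation (with exact
  permutation p for small n), paired t-tests, low-PSIC-fraction
  grouping at 20%/30% cuts, Kaplan–Meier curves and the k-group
  log-rank test.
- **Synthetic phantoms** (`oemri.phantom`): a seeded concentric tumor
  simulator (necrotic core / hypoxic penumbra / active rim / normal
  tissue) with mono-exponential wash-in/wash-out kinetics and exact
  closed-form ground truth, plus matched pO2 traces, histology
  surrogates and survival cohorts.
- **I/O, config and CLI** (`oemri.io`, `oemri.pipeline`, `oemri.cli`):
  NIfTI series/maps/masks (PNG masks accepted), CSV tables, YAML run
  configs, and an `oemri` command with `simulate`, `map`, `classify`,
  `curve`, `po2`, `correlate`, `survival` and `run-all` subcommands.

See `docs/methods.md` for the model, parameter defaults and numerical
choices.

## Worked example

Run the whole synthetic-cohort study — 9 phantom subjects mapped at
SNR 20, 5 subjects with matched pO2 traces, histology surrogates, and a
90-animal survival cohort grouped on low-PSIC area fraction:

```sh
$ oemri run-all --seed 1 --out results/demo
INFO oemri: imaging cohort: 9 subjects mapped in 0.7 s
INFO oemri: pO2 analysis: 10 paired rows in 0.0 s
INFO oemri: histology surrogates in 0.0 s
INFO oemri: survival cohort: 90 rats, log-rank p=1.18e-12 in 0.1 s
INFO oemri: pipeline complete in 0.8 s
{
  "logrank_p": 1.1803874144067825e-12,
  "median_survival_days": {
    "high": 9.76488372713776,
    "low": 39.3198307736792,
    "medium": 23.92635600666941
  },
  "spearman_psic_delta_po2": 0.8303030303030302
}
```

Reading the numbers: animals whose tumors have a *low* fraction of
poorly-enhancing (hypoxic) area survive longest (median ≈39 days),
the medium group ≈24 days, the high group ≈10 days, and the log-rank
test rejects equality of the three survival curves decisively.  ROI
PSIC values correlate strongly (Spearman ρ ≈ 0.83, n = 10) with the
probe-measured ΔpO2 — enhancement tracks actual tissue oxygenation.
The output directory holds per-subject PSIC maps (NIfTI), the
per-subject summary `subjects.csv`, ROI and pO2 tables, KM curves,
`tests.json` with every statistic, and a `manifest.json` recording the
seed and all parameters; rerunning with the same seed reproduces every
CSV/JSON byte for byte.

The same pieces are available as a library:

```python
from oemri import (StageTiming, default_phantom_spec, generate_phantom,
                   compute_psic_map, low_psic_fraction)

spec = default_phantom_spec(seed=7, noise_sigma=50.0)   # SNR 20
series, truth = generate_phantom(spec)
timing = StageTiming.from_durations((300.0, 300.0, 300.0))
pmap = compute_psic_map(series, timing)
print(low_psic_fraction(pmap, truth.tumor_mask), truth.true_low_fraction)
```

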
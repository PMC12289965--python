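# sdmscope

Desk-scale self-driving microscopy for studying protein-aggregation onset,
fully simulated: a generative virtual microscope, trainable onset/aggregate
classifiers, an event-triggered two-mode acquisition engine, and a Brillouin
shift/linewidth quantification pipeline. Everything runs end-to-end on one
CPU with no external data.

## What is in the box

| Module | Role |
| --- | --- |
| `sdmscope.synthetic_scope` | Virtual sample + renderers: multi-plane fluorescence time-lapse, brightfield, per-pixel Brillouin spectra, labeled onset/brightfield datasets, ground-truth maps |
| `sdmscope.classifiers` | Numpy neural networks (conv / recurrent / patch-attention variants), protocol training (Adam @ 1e-5, BCE, early stopping, best-val checkpoint), metrics |
| `sdmscope.sdm_engine` | The self-driving loop: grid planning, BATCH / IMMEDIATE trigger modes, virtual clock, session logs, capture scoring |
| `sdmscope.brillouin_analysis` | Lorentzian doublet fitting, instrumental-linewidth deconvolution (0.270 GHz), Otsu segmentation, aggregate-vs-periphery region statistics |
| `sdmscope.stackio` / `sdmscope.config` / `sdmscope.cli` | OME-TIFF + HDF5 + CSV formats, strict YAML/JSON configs with canonical hashes, the `sdmscope` command |
| `sdmscope.benchmarks` | One-call reference benchmarks (dataset → train → evaluate, Brillouin recovery chain) |

## CLI quick tour

```bash
# generate the default labeled onset dataset (71 events / 68 non-events)
sdmscope simulate onset-dataset --n-events 71 --n-nonevents 68 -T 1 -Z 8 --seed 0 --out data/onset

# train / evaluate the single-frame conv classifier
sdmscope train --dataset data/onset --arch single_frame_conv --seed 0 --out models/onset
sdmscope evaluate --model models/onset --dataset data/onset

# self-driving session on a virtual sample (oracle or trained model)
sdmscope simulate sample --grid 3x3 --event-fraction 0.5 --out sample.json
sdmscope sdm-run --sample sample.json --oracle --mode immediate --out session.jsonl
sdmscope sdm-score --log session.jsonl --sample sample.json

# Brillouin: point-scan, fit maps, region report
sdmscope simulate brillouin-map --fov-um 35 --step-um 1.0 --out spectra.h5
sdmscope brillouin-map --spectra spectra.h5 --fsr 15.0 --out maps/t0000
sdmscope brillouin-report --maps maps --fluor fluor_dir --out region_stats.csv
```

## Notes

- All randomness derives from one seed through named substreams
  (`sdmscope._rng.substream`); identical inputs give bit-identical outputs.
- The benchmark preset (`benchmark_config()`) renders 128 px images over the
  same ~39 µm field of view so training stays within minutes on one CPU; the
  default `SimConfig` keeps the full-scale 352 px / 111 nm geometry.
- The dataset composition follows the 71 events / 68 non-events convention;
  an alternative count of 69 non-events appears in one part of the source
  description and can be requested explicitly via `--n-nonevents 69`.
- Classifier networks are intentionally small, framework-free numpy models;
  gradients are verified against numerical differentiation in the test
  suite.
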
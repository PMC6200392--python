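# kymoslide

Simulation and quantification of relative sliding and stalling of
antiparallel microtubule pairs driven by a crosslinker-motor system
(PRC1-Kif4A-like), from two-channel TIRF kymographs.

In this assay a surface-immobilized microtubule is crosslinked to a second,
"moving" microtubule. Motor-crosslinker complexes in the overlap slide the
moving filament toward the immobilized plus-end while dense protein caps
("end-tags") build at both plus-ends. Sliding shows three phases - constant
velocity, slowdown, stall - and the stall happens when the two end-tags
collide, so the final overlap length equals the sum of the end-tag lengths
(the *molecular roadblock* mechanism). The package provides:

- **kymosynth** - a mechanistic simulator of sliding trajectories and a
  TIRF-image renderer (Gaussian PSF, Poisson noise) so every analysis stage
  can be validated against known ground truth;
- **kymoquant** - sub-pixel kymograph quantification: filament extents and
  overlap bounds from the microtubule channel, end-tag segmentation and
  intensity bookkeeping from the GFP channel, and event tracking (initial
  overlap `L0`, final overlap `L_FO`, microtubule lengths `ML1/ML2`,
  end-tag lengths `LET1/LET2`);
- **phase_kinetics** - instantaneous sliding velocity and least-squares
  three-phase changepoint segmentation;
- **overlap_model** - the quantitative model: the saturating
  velocity-overlap relation `v = v0 L / (L + K_L)`, the motor-ensemble law
  `v = v0 (1 - (1 - S)^N)` with `N = a L / delta` (`delta` = 8 nm binding
  site), and the closed-form sliding efficiency
  `S = 1 - 0.5^(1/N(K_L))`;
- **ensemble_stats** - event exclusion rules, Gaussian histogram fits,
  Pearson correlations, binned plots, linear regressions and the
  molecules-per-micron calibration;
- **cli_io** - TIFF/CSV/JSON formats, a strict YAML configuration schema and
  the end-to-end pipeline.

## Worked example

Run the full pipeline on 60 simulated fast-condition events plus 40
slow-condition events:

```sh
python analysis/02_condition_statistics.py --seed 1
```

prints

```
== low_crosslinker (n = 60) ==
phase-1 velocity: 46.9 +/- 7.9 nm/s (N=60)
untagged density (Gaussian fit): 3.58 +/- 1.78 A.U./nm
Pearson r (v vs initial overlap): 0.93
velocity-overlap fit: v0 = 77.7 nm/s, K_L = 1824 nm

== high_crosslinker (n = 40) ==
phase-1 velocity: 11.5 +/- 3.4 nm/s (N=40)
untagged density (Gaussian fit): 6.52 +/- 2.24 A.U./nm
```

i.e. the low-crosslinker condition slides ~4x faster despite recruiting
~2x less motor per unit overlap length, and the sliding velocity grows with
the initial overlap length. Feeding the fitted half-max overlap
`K_L = 1824 nm` into the efficiency calculation,

```sh
python analysis/04_sliding_efficiency.py
```

```
v0 = 77.7 nm/s, K_L = 1824 nm (n = 60 events)
  a      N      S
  0.01    2.3  0.262
  ...
  0.10   22.8  0.030
```

the per-complex sliding efficiency spans ~0.26 down to ~0.03 for
sliding-competent occupancies between 1% and 10% - the complex behaves like a
very low duty-ratio motor, which is exactly why the ensemble velocity scales
with overlap length. The roadblock test,

```sh
python analysis/03_roadblock_scaling.py --seed 1
```

```
L_FO / (LET1+LET2): 1.021 +/- 0.013 (N=50)
L_FO vs ML1+ML2: slope = 0.400 (end-tag fraction 0.4), r = 1.00
```

confirms that the measured stalled overlap equals the summed end-tag lengths
and scales linearly with total filament length.

The other drivers: `analysis/01_simulate_example.py` writes one example
kymograph + figure, `analysis/05_recovery_benchmark.py` tabulates
measurement errors against ground truth at per-pixel SNR 5.

## Command-line interface

```sh
kymoslide simulate --config configs/demo.yaml --n 10 --seed 1 --out scratch/sim
kymoslide analyze  --in scratch/sim --out scratch/quant
kymoslide fit-model --events scratch/quant/events.csv --out scratch/model.json
kymoslide stats    --events scratch/quant/events.csv --analysis velocity_vs_overlap --out scratch/stats
kymoslide run-all  --config configs/demo.yaml --out scratch/all
```

Kymographs are 2-channel TIFF stacks (channel 0 = microtubule, channel 1 =
GFP, one row per frame) with pixel size and frame interval in a JSON sidecar
and in the embedded description. Externally produced event tables
(e.g. published source-data spreadsheets) can be read through
`ensemble_stats.load_event_table` with a column-mapping dictionary.

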
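# radioplan

Radiotherapy plan evaluation on 3D dose grids and dose-volume histograms
(DVHs): plan-quality metrics, radiobiological outcome models (EUD, TCP,
NTCP), a seeded synthetic cohort generator, and paired-condition statistics
(Friedman omnibus plus Dunnett-style post hoc with the star convention).

## What it does

- **`radioplan.grids` / `radioplan.dvh`** — dose grids, structure masks,
  differential/cumulative DVHs, and the usual plan metrics: min/max/mean/
  median/mode/STD, Dx% and Vx by linear interpolation, conformity index
  (RTOG single-ratio default, Paddick variant), gradient measure
  (equivalent-sphere radius difference of the 50% and 100% isodose
  volumes), and an ICRU62-style homogeneity gate (D98%/D2% within
  −5 %/+7 % of prescription).
- **`radioplan.radiobiology`** — mechanistic Poisson TCP
  (`exp(−N·e^(−αD))`), phenomenological Poisson TCP
  (`(1/2)^exp[2γ50(1−D/D50)/ln2]`, with the volume-weighted product form
  for heterogeneous DVHs), generalised power-mean EUD, LKB probit NTCP
  (`Φ((EUD−TD50)/(m·TD50))`, EUD exponent `a = 1/n`), Poisson-LQ NTCP, and
  an optional per-bin EQD2 correction. A built-in YAML registry supplies
  the default model parameters; user configs merge by structure+endpoint.
- **`radioplan.cohort`** — synthetic phantoms (body, target, lungs, heart,
  esophagus, cord), plan-like dose grids that satisfy the coverage
  (V95 % ≥ 95 %) and homogeneity gates by construction, and six paired
  calculation conditions (AAA, AAA_C, AXB_Dm, AXB_Dw, AXB_C_Dm, AXB_C_Dw)
  derived from each base plan by parametric perturbations. Fully
  deterministic under a master seed.
- **`radioplan.stats`** — tie-corrected Friedman rank-sum test,
  paired-comparison Dunnett-style family-wise adjustment (equicorrelated
  multivariate-t reference by seeded Monte Carlo; Bonferroni fallback), and
  `star_label` (`*` p<0.05 … `****` p<0.0001, `ns` otherwise).
- **`radioplan.io` / `radioplan.pipeline` / `radioplan.cli`** — volumetric
  containers (dose + masks + spacing in one file), DVH tables (CSV dialect
  and an Eclipse-style exported text dialect with %-axis conversion),
  validated YAML run configs, and a resumable four-stage pipeline with a
  provenance manifest.

## CLI

```bash
# generate a synthetic cohort (volumes + manifest)
radioplan simulate --patients 20 --seed 1 --out runs/demo

# DVH metrics and TCP/NTCP outcomes
radioplan evaluate --out runs/demo

# Friedman omnibus + Dunnett-style post hoc per metric
radioplan compare --control AAA --seed 1 --out runs/demo

# text summary + per-metric box plots
radioplan report --out runs/demo

# or everything at once (stages are resumable; --force recomputes)
radioplan run --seed 1 --out runs/demo
```

Options can also come from a YAML config (`--config`); unknown keys are
rejected. See `radioplan <verb> --help`.

## Notes on conventions

- Doses are cGy everywhere internally; α/β values are accepted in Gy and
  converted at registry load.
- D_min/D_max come from raw masked voxels; the homogeneity gate uses
  D98 %/D2 % as near-min/near-max; standard deviation is the population
  estimator.
- Dx%/Vx interpolate linearly between tabulated cumulative points; plateau
  ties resolve to the lowest dose attaining the volume level.
- γ50 for the Poisson-LQ models is not part of the published parameter set;
  a documented default of 1.5 is used unless configured, and outputs record
  the value used.
- Post-hoc comparisons are computed even when the omnibus test is not
  significant, flagged via `omnibus_significant`.
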
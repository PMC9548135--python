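# contambench

Benchmarking library-preparation contamination and in silico
decontamination for low-input shotgun metagenomics, on simulated
mock-community dilution series with known truth.

Samples with sub-nanogram microbial DNA (skin swabs, CSF, placenta,
ancient or environmental samples) are dominated by two artifacts: reagent
contamination introduced during library preparation, and kit-dependent
distortion of the measured community. `contambench` emulates the standard
way these artifacts are quantified in the lab — a synthetic spike-in
community (83 components on a twofold molar ladder across 8 concentration
tiers) serially diluted from 5000 pg down to 0.5 pg plus negative
controls, prepared with five kit profiles (`Son_N`, `Son_Q`, `End_N`,
`End_Q`, `Tn5_V`) — and evaluates decontamination strategies against the
simulation's truth labels, read by read.

The package is aimed at microbiome researchers and method developers who
need a controlled testbed for decontamination algorithms or for power
analyses of dilution-series designs.

## What it computes

* **Simulator** (`mock_community`): truth-labelled genus/component count
  tables per (kit, input, replicate) library, with kit-specific
  contaminant pools (load medians {Son_Q 15.59, Son_N 2.32, End_N 0.05,
  End_Q 0.04, Tn5_V 0.01} pg), input-proportional endogenous contaminants,
  GC/length amplification bias, and finite-molecule duplication.
* **Metrics** (`profile_metrics`): total sum scaling; Jensen-Shannon
  distance `JSD(p, q) = sqrt(JS divergence, log base 2)` in [0, 1];
  fidelity and reproducibility (`1 − JSD`); proportion of designated
  reads; conversion rate
  `Q_lib · R_designated / (Q_input · 2^N_PCR)`; duplication rate;
  abundance-bias ratios and their length regression; rarefaction.
* **Contaminant quantification** (`contaminant_quant`): absolute
  contaminant mass via the spike-in ratio
  `m = input · contaminant reads / designated reads`; the endogenous
  screen (per-kit regression on log10 input, BH-corrected, flagged at
  p.adj < 0.05 and R² > 0.55 in ≥ 4 kits); core (>0.1%) and dominant
  (>1%) contaminant catalogs; remaining-contaminant curves.
* **Decontamination** (`decontam_methods`): 5x/10x fold-over-NC
  classification, and frequency / prevalence / either scoring with
  thresholding.
* **Evaluation** (`evaluation`): read-weighted confusion counts,
  precision/recall, the 40-point threshold sweep on [0.1, 0.5] maximizing
  recall at 100% precision, decontaminated-profile JSD, and a one-factor
  PERMANOVA (pseudo-F, R², permutation p) for variance attribution.

See `docs/methods.md` for the model, its assumptions and its limits.

## Worked example

```python
import contambench as cb

config = cb.RunConfig(seed=7)          # full 5-kit dilution series
report = cb.run_pipeline(config)

meds = report["quantification"]["per_kit_median_pg"]
print({k: round(v, 3) for k, v in meds.items()})

lib = next(r for r in report["libraries"]
           if r["library_id"] == "Son_Q_0.5pg_rep1")
print(lib["proportion_designated"], lib["fidelity_sequins"])

row = next(r for r in report["decontamination"]["Son_Q"]["methods"]["either"]
           if r["library_id"] == "Son_Q_0.5pg_rep1")
print(row["tp"] / (row["tp"] + row["fn"]), row["jsd_before"], row["jsd_after"])
```

prints (seed 7):

```
{'End_N': 0.118, 'End_Q': 0.115, 'Son_N': 4.543, 'Son_Q': 18.164, 'Tn5_V': 0.088}
0.1159 0.9345...
0.9148... 0.8551... 0.4811...
```

Reading it: the spike-in estimator recovers each kit's planted
contaminant load (sonication-like kits carry picograms of reagent DNA,
enzymatic and tagmentation kits hundredths of a picogram). A Son_Q-like
library at 0.5 pg input is ~88% contaminating reads; either-mode
decontamination at the optimized thresholds removes ~91% of them, yet the
decontaminated profile still sits at JSD ≈ 0.48 from the true signal —
heavy, highly variable contamination cannot be fully reverted in silico,
whereas the same method takes lightly contaminated Tn5/End-like libraries
below JSD 0.05.

The same stages are scriptable from the shell:

```sh
contambench simulate --seed 7 --out runs/demo
contambench decontam --profiles runs/demo/profiles.tsv --mode either --out runs/demo
contambench evaluate --profiles runs/demo/profiles.tsv --out runs/demo
contambench report   --seed 7 --out runs/demo
```

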
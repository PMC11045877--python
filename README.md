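# biadquant

Quantification of **dual-color BiAD (bimolecular anchor detector)** fluorescence
microscopy — a sensor class that reads out chromatin modifications (5mC,
H3K9me2/3, H3K27me3, H3K36me2/3) at endogenous repeat loci in single cells.

A dCas9/sgRNA anchor marks the target locus with a full-length fluorophore
(YPet, the *marker* channel) and simultaneously presents one half of a split
fluorophore (IFP2.0); a chromatin reader domain carries the other half.  Where
the modification is present, the reader binds and the split fluorophore
reconstitutes (BiFC) — the *BiAD* channel lights up at the marked locus.
Binding-deficient reader mutants (e.g. MBD1 R44Q, HP1β W42A) are the negative
control.

This package implements the downstream image analysis as a tested, scriptable
pipeline:

- **imaging I/O** — TIFF/OME-TIFF z-stacks, maximum-intensity projection,
  explicit channel-role binding, CSV tables;
- **segmentation** — the two-threshold ROI scheme: a low marker threshold for
  the nucleus, a high threshold for the ≤ 6 brightest marker spots, mean ROI
  intensities in all channels (manual per-cell thresholds or automatic
  Otsu/quantile defaults);
- **quantification** — per spot *s*:

  `relative_biad(s) = (BiAD(s) − BiAD(nucleus)) / (marker(s) − marker(nucleus))`

  averaged over spots per cell; allelic Xi/Xa classification by overlap with
  an immunostain territory and per-cell normalisation to the mean Xa signal;
  per-arm normalisation to a control detector;
- **statistics** — two-tailed unpaired t tests (Welch or Student), one-way
  ANOVA with Tukey's posttest, Tukey-whisker boxplot summaries with
  replicate-colored points;
- **synthetic data** — a simulator rendering nuclei, copy-number-scaled spots,
  Xi territories, transfection dropout and Poisson + Gaussian camera noise,
  with exact ground truth for every stage.

See `docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

Simulate a wild-type vs. binding-deficient-mutant experiment (30 cells each,
true per-spot ratio 0.5 for WT, 0 for the mutant), quantify and compare:

```sh
biadquant demo --outdir demo --seed 1 --n-cells 30
```

prints

```json
{
  "n_analyzed": 60,
  "n_excluded": 0,
  "group_means": {
    "WT": 0.5022162760281947,
    "mutant": 0.00176892783429579
  },
  "t_statistic": 252.25163778081912,
  "p_value": 1.1202775980225488e-84
}
```

All 60 cells passed QC; the recovered mean relative BiAD signal of the WT
group (0.502) matches the configured truth of 0.5, the mutant null sits at
zero, and the two-tailed unpaired Welch t test separates the groups decisively.
`demo/` also contains the per-cell and per-spot CSV tables, the QC report and
a replicate-colored boxplot (`boxplot.png`).

The same steps are available separately (`biadquant simulate`, `biadquant
quantify`, `biadquant compare`) for on-disk OME-TIFFs plus a sample sheet, or
programmatically:

```python
import biadquant as bq

cfg = bq.SimulationConfig(biad_gain=0.5, seed=1)
sim = bq.simulate_cell(cfg)
thr = bq.ThresholdPair(*bq.suggested_thresholds(cfg))
cell = bq.quantify_cell(sim.image, thr, condition="WT")
print(cell.mean_relative_biad)   # ~0.5
```

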
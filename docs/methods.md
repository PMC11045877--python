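# Methods

## The measurement

A dual-color BiAD (bimolecular anchor detector) sensor reports a chromatin
modification at a chosen genomic repeat locus in single cells.  A dCas9/sgRNA
anchor binds the repeat array; an MS2 scaffold on the sgRNA recruits a bright
full-length fluorophore (YPet) that marks the locus — the **marker** channel.
A SunTag array on dCas9 carries one half of a split near-infrared fluorophore
(IFP2.0); the other half is fused to a reader domain for the modification of
interest.  When the modification is present, the reader binds and the split
fluorophore reconstitutes (bimolecular fluorescence complementation) — the
**BiAD** channel.  Binding-pocket mutants of the reader are the negative
control: the locus is still marked, but no BiAD signal can form.

Quantification per cell proceeds in four steps:

1. **Projection.** Z-stacks are collapsed per channel by maximum-intensity
   projection.
2. **Two-threshold segmentation.** A low marker-channel threshold defines the
   nucleus (largest 4-connected component, holes filled); a higher threshold
   defines the brightest marker spots inside the nucleus (8-connected
   components, area ≥ `min_spot_area`, at most six per cell, ranked by mean
   marker intensity).
3. **Ratiometric spot signal.** For each spot and channel the nuclear mean is
   subtracted from the spot mean; the *relative BiAD signal* of spot *s* is

   r_s = (I_BiAD(s) − I_BiAD(nucleus)) / (I_marker(s) − I_marker(nucleus)).

4. **Per-cell aggregate.** The cell's value is the arithmetic mean of r_s over
   its valid spots; cells are the statistical unit.

Because marker amplitude scales with the local repeat copy number and BiAD
amplitude scales with copy number × modification occupancy × detector binding,
the ratio cancels copy number and is comparable across loci spanning 45 to
more than 1,000 repeats.

Two derived analyses mirror the figure-level workflows: **allelic
enrichment** — spots are labelled Xi when ≥ 50% of their pixels (inclusive)
overlap an immunostain territory (e.g. H3K27me3 marking the inactive X), and
every spot in a cell is divided by that cell's mean over Xa spots, so Xa
anchors at 1.0 — and **control normalisation** — each cell's value is divided
by the mean of the control-detector condition within its treatment arm, so
controls anchor at 1.0 per arm.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `nucleus_threshold`, `spot_threshold` | per-cell manual, or auto | manual mode reproduces the by-eye per-nucleus thresholds of the original workflow; auto mode uses Otsu (nucleus) and the 99.5th within-nucleus marker percentile (spots) for batch reproducibility |
| `max_spots` | 6 | cap on spots per cell; matches the polyploid cell line's 2–4 loci with headroom |
| `min_spot_area` | 4 px | suppresses single-pixel shot-noise components; no area filter is implied by the original workflow, so it is configurable |
| `eps` denominator guard | 1e-6 of the marker dynamic range | spots with corrected marker below this are excluded (logged), never forced to a ratio |
| `overlap_fraction_min` | 0.5 (inclusive) | Xi/Xa decision boundary against the stain territory |
| t-test `variant` | `welch` | the source convention states only "two-tailed, unpaired"; Welch is the robust default, Student's is available for fidelity |

Negative corrected BiAD values are **retained**: clamping at zero would bias
the mutant-detector null upward and invalidate the WT-vs-mutant contrast.
The nuclear mean **includes** spot pixels (the nucleus is thresholded and
measured as one ROI); an exclusion option exists and is off by default.  With
equal per-spot ratios the spot contamination of the nuclear mean cancels
exactly in the ratio, which is why noiseless top-hat simulations are recovered
to float precision; with unequal ratios (Xi enrichment) it contributes a bias
bounded by the spot-to-nucleus area fraction (< 3% at defaults).

## The simulator

`biadquant.simulate` renders cells with known ground truth: an elliptical
nucleus (semi-axes 42 × 30 px in a 128 × 128 px frame) at base intensities
(marker 100, BiAD 40 photons) over a background of 5; 2–6 top-hat or Gaussian
spots (radius 3 px) with marker amplitude = `marker_gain` × copy number and
BiAD amplitude = marker amplitude × true ratio, where true ratio =
detector efficiency × modification fraction × BiAD/marker gain ratio
(× Xi enrichment on Xi loci, × 0 on transfection-dropout cells); an optional
stain territory (a disc covering ~20% of the nucleus) containing the Xi loci;
and a camera model of Poisson shot noise, Gaussian read noise and a DC offset.
The default noisy conditions place the per-pixel spot signal-to-noise ratio at
10: amplitude 200 over base 100 with read σ 10 gives a noise sd at the spot of
√(Poisson 300 + read 100) = 20, so SNR = 200/20.
A single seed fixes everything; per-cell substreams are spawned from a master
`SeedSequence`, so experiments are reproducible regardless of generation
order.

What the simulator does *not* emulate: optical aberrations, z-dependent PSF,
photobleaching, chromatic shift, fluorophore aggregation, cell-to-cell
expression variability beyond dropout, or any nonlinearity in the copy-number
→ brightness mapping (the linear `marker_gain` model is an assumption; real
recruitment saturates).  Passing tests therefore demonstrate correctness of
the *analysis* under the stated signal model, not performance on real
micrographs — in particular, real per-cell manual thresholds and touching
nuclei are out of scope.

## Numerical and design choices

- Intensities are converted to float64 at load; bit depth is metadata only.
- Spot ranking ties break by larger area, then lower component label.
- Quantiles use linear interpolation (type 7), matching common plotting
  libraries; whiskers extend to the most extreme data within 1.5 IQR.
- Tukey HSD adjusted p-values come from the standard studentized-range
  implementation; the omnibus F is the classical between/within mean-square
  ratio.
- The permutation cross-check of the t test uses the absolute difference in
  group means over 10⁵ label permutations.  A t p-value and a permutation
  p-value are answers from *different* tests; at n = 40 per group their gap
  dominates the Monte-Carlo sd (≈ 0.0016), so the agreement tolerance is
  fixed at 0.02 absolute.
- Degenerate inputs: empty masks and empty tables raise contract errors;
  cells with no nucleus, no spots, no valid denominator, or no usable allele
  labels are excluded with machine-readable QC reasons, and the QC report
  always partitions the input (analyzed + excluded = all cells).
- Problem sizes in the test and acceptance runs (50-cell recovery runs, 100
  30-vs-30 contrast replicates, 500-cell dropout runs) were chosen as the
  smallest sizes at which the binomial/Monte-Carlo bounds being asserted are
  meaningful.

## Known limitations

- 2D analysis only (the projection), as in the source workflow; spots that
  overlap in projection are merged.
- Replicates are recorded and colored in plots but pooled in tests; no
  hierarchical (cell-within-replicate) model.
- Stain-territory segmentation uses global Otsu within the nucleus; faint or
  fragmented territories on real images may need manual thresholds.
- The linear copy-number → brightness model is uncharacterised on real data.
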
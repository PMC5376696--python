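# macrospot

Quantification and antigen hit calling for gridded protein-macroarray
membrane scans.

## The problem

In phage-display antigen identification, a candidate antibody (a single
domain antibody, dAb, and its Fc fusion, dAb-rFc) is used to probe a
high-density protein filter: a membrane spotted with thousands of bacterially
expressed cDNA clones. The clones are arranged in 3×3 blocks — eight
peripheral protein spots around a central ink guide dot — and every clone is
deposited twice within its block (duplex spotting). After probing and
scanning, the analysis must answer one question: *which clone does the
antibody actually bind?*

`macrospot` implements that analysis as a reusable pipeline:

1. **Grid registration.** The ink guide dots are detected (robust threshold,
   connected components, intensity-weighted centroids) and a 6-parameter
   affine map from the nominal block lattice to the scan is fitted with
   Tukey-reweighted least squares, tolerating translation, rotation, mild
   scale and outlier blobs.
2. **Spot quantification.** Each spot is scored as a robust z-score
   `z = (raw − background) / spread`, where `raw` is the median pixel value
   in the spot disk, `background` the median of a surrounding annulus
   (excluding pixels of neighbouring spots and guide dots) and `spread`
   1.4826 × the median absolute deviation of the same annulus.
3. **Hit calling.** Replicate z-scores are averaged per clone; a clone is a
   hit only if **both** duplicate spots reach the detection threshold
   (z ≥ z_min, default 3) — a clone detected only once in duplex is omitted
   — and only clones hit with **both** probe formats survive the final
   dual-format intersection.

Because no public scan of such a membrane is available, the package includes
a first-class synthetic generator (`macrospot.simulate`) that renders
membranes with known ground truth — spatially varying background, pixel
noise, lognormal spot-amplitude variation, failed deposits and artifact
smears — so every stage is testable end to end.

## Worked example

Generate the packaged dual-probe demo membrane (10×10 blocks, 400 clones;
clones G1–G5 bind the dAb probe, G1/G2/G3/G6/G7 bind the dAb-rFc probe, but
G2 and G3 each lost one replicate deposit in that channel) and run the full
chain:

```sh
macrospot simulate --seed 20170105 --outdir demo
macrospot run --image-a demo/scan_dAb.tif --image-b demo/scan_dAb-rFc.tif \
              --layout demo/layout.tsv --config demo/config.txt \
              --outdir demo/results
```

which prints

```
dAb: 5 hits
dAb-rFc: 3 hits
common: 1 hits (G1)
```

The dAb channel finds its five true binders; in the dAb-rFc channel G2 and
G3 are rejected by the replicate-consistency rule (each was detected at only
one of its two spots), leaving G1, G6 and G7; and the dual-format
intersection leaves the single common antigen, G1. The ranked per-channel
lists and the common list are written as TSV, e.g. `demo/results/hits_common.tsv`:

```
rank  clone_id  combined  z_rep1   z_rep2   channel
1     G1        6.0387    5.6966   6.3809   dAb+dAb-rFc
```

where `combined` is the mean of the per-channel clone scores (themselves
means of the two replicate z-scores).

The same stages are available as library functions
(`macrospot.simulate_image`, `detect_guide_dots`, `fit_grid`,
`quantify_array`, `score_clones`, `call_hits`, `intersect_channels`,
`run_pipeline`) and as individual subcommands (`register`, `quantify`,
`call`, `intersect`, `titer` — the last converts A269/A320 UV absorbance
readings of phage preparations into particles/mL).

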
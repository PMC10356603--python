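# wmfish

Quantification of whole-mount single-molecule RNA FISH (smFISH) microscopy in
plant tissue: from multichannel confocal images to per-cell transcript
counts, protein-reporter intensities, RNA/protein log-ratio maps and
spot–protein colocalization fractions.

## Who this is for

smFISH labels each mRNA molecule with tens of fluorescent oligo probes, so a
single transcript appears as one diffraction-limited spot. In intact
(whole-mount) cleared plant tissue the analysis problem is threefold:

1. **Cell segmentation** — cells are outlined by a cell-wall stain (e.g.
   SR2200/Renaissance 2200); a marker-controlled watershed on the wall
   channel produces a label map (0 = wall, 1..n = cells) that is the spatial
   frame for everything downstream.
2. **Spot detection** — mRNA foci are found with a scale-normalized
   Laplacian-of-Gaussian band-pass (which also suppresses the large, smooth
   autofluorescent structures typical of plant tissue), an automatic
   threshold at the plateau of the count-vs-threshold curve, and per-spot
   2D Gaussian fits giving sub-pixel centers and background-corrected
   amplitudes.
3. **Per-cell quantification** — each spot is assigned to the cell under its
   center, yielding counts N_c; channel intensities are measured per cell;
   the log ratio L_c = ln((I_RNA + ε)/(I_protein + ε)) drives per-cell
   heatmaps; and, with a protein-defined structure (a nucleus or nuclear
   envelope segmented from a reporter channel), the colocalized fraction
   F_c = K_c / N_c quantifies subcellular mRNA targeting.

A synthetic-microscopy module generates images with exact ground truth
(label map, spot list, per-cell counts, protein mask), so every stage is
validated by recovery tests without any external data. Group statistics
(distribution summaries with ±1.58×IQR whiskers, Pearson correlation,
Welch's t-test, one-way ANOVA with Tukey HSD) support multi-condition
comparisons with cells as the statistical unit.

## Worked example

Simulate a 50-cell tissue (512×512 px, Poisson(12) transcripts per cell,
nuclear protein blobs, Gaussian noise), then run the full pipeline on the
written TIFF:

```python
from wmfish import simulate, io

cfg = simulate.SimConfig(image_shape=(512, 512), n_cells=50,
                         count_law=("poisson", 12.0),
                         protein_pattern="nuclear_blob",
                         noise_sigma=5.0, seed=8)
simulate.generate_dataset(cfg, "demo")

rc = io.RunConfig(input_path="demo/stack.tif", out_dir="demo_out",
                  coloc={"tolerance_radius": 1.0})
result = io.run_pipeline(rc)
print(result["cells"][["area", "n_spots", "rna_mean",
                       "protein_mean", "log_ratio", "coloc_fraction"]].head())
```

```
         area  n_spots  rna_mean  protein_mean  log_ratio  coloc_fraction
cell_id
1        5726        9    11.517        10.266      0.105           0.111
2        3638        7    11.293        17.861     -0.428           0.143
3        4433        8    11.247        15.169     -0.278           0.375
4        6793        9    11.241        18.645     -0.473           0.111
5        4522       13    12.306        15.155     -0.194           0.231
```

Each row is one segmented cell: its area in px², the number of detected
mRNA foci (N_c), mean RNA- and protein-channel intensities, the RNA/protein
log ratio, and the fraction of its spots falling within the segmented
protein mask. Comparing against the simulator's ground truth (pairing
predicted and true cells with `segmentation.match_labels`):

```
matched cells: 50   recall: 1.0   mean IoU: 0.986
count recovery: r = 0.943   MAE = 0.94
```

i.e. all 50 cells are recovered one-to-one at IoU 0.986, and per-cell
detected counts track the true counts to within about one molecule.

The same workflow is available from the shell:

```sh
wmfish simulate --seed 8 --out demo
wmfish run --config run.yaml
```

with subcommands `simulate | segment | detect | quantify | coloc | report |
run` mapping 1:1 to the library stages.

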
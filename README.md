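# cardiomap

Spatial mapping and statistics of left-ventricular gene expression.

`cardiomap` is for experimenters who biopsy the whole left ventricle (LV) at
known catheter-mapped coordinates, quantify transcripts by qPCR, and want to
*see* and *test* where expression changes — the "image-omics" idea of
replacing the voltage values of an electroanatomical (NOGA/CARTO-style) map
with per-location fold changes, rendered as 2D bulls-eye polar maps and 3D
ventricular surfaces.

## What it computes

* **Geometry** — the LV as a truncated prolate hemiellipsoid; arc-length
  bulls-eye projection `(x,y,z) ↔ (ρ, θ)` with anterior at 12 o'clock; AHA
  17-segment assignment; a deterministic 52-biopsy sampling layout.
* **qPCR** — comparative-Ct quantification with geometric-mean
  normalisation over references (GAPDH, HPRT1, PPIA):
  `ΔCt = Ct_target − mean(Ct_refs)`, `ΔΔCt = ΔCt − ΔCt_cal`,
  `FC = E^(−ΔΔCt)`; dilution standard curves with `E = 10^(−1/slope)`.
* **Display** — fold changes on a 0–100 scale (min → 0, max → 100, optional
  reference anchor pinned to 20), inverse-distance-weighted interpolation
  over the disk, colour-coded bulls-eye PNG/SVG and PLY/OBJ surface meshes.
* **Zone statistics** — an ischemic polygon drawn on the 5 h map and
  transposed verbatim onto control/24 h maps; per-animal ischemic and remote
  means; one-way ANOVA with Holm–Šidák-adjusted pairwise contrasts.
* **Segment statistics** — per-segment means/SDs and the 2×SD
  biological-relevance rule (`|Δmean| > 2·SD_pooled`), displayed as a
  17-segment polar schematic with relevant segments in red.
* **Synthetic studies** — a generator with a Gaussian ischemic-core effect
  and replicate-level Ct noise, providing exact ground truth for every
  stage.

## Worked example

```python
import cardiomap as cm

study = cm.simulate_study(seed=7)                 # control 8, I/R-5h 6, I/R-24h 6
expr  = cm.delta_delta_ct(study.ct)               # fold change per sample x gene
zone  = cm.ischemic_zone_polygon(study.config)    # polygon on the 5h map
cls   = cm.transpose_zone(zone, {"control": study.locations}) \
          .drop_duplicates("location_id")
stats = cm.compare_zone_groups(
    cm.zone_summaries(expr, cls[["location_id", "inside"]]))
print(stats.loc[stats.zone == "ischemic",
      ["gene", "mean_control", "mean_ir5h", "mean_ir24h", "anova_p"]].round(4))
```

prints

```
 gene  mean_control  mean_ir5h  mean_ir24h  anova_p
CASP3        1.0049     2.6548      0.9882   0.0000
  CLU        1.0153     1.3387      1.3620   0.0000
ERCC4        1.0303     1.5434      1.4934   0.0000
GATA4        1.0290     1.5779      1.9020   0.0000
  HK2        1.0212     1.9890      0.3600   0.0000
MEF2C        1.0029     1.0186      1.0096   0.8912
HIF1A        1.0240     2.1993      1.3265   0.0000
```

i.e. the apoptosis/stress genes are strongly up in the ischemic zone at 5 h
(CASP3 2.7-fold), HK2 collapses globally by 24 h (0.36-fold), and the flat
gene MEF2C stays at baseline (ANOVA p = 0.89).  The segment rule on the same
study flags, among others, the two segments that lie fully inside the
generated ischemic core:

```python
summ  = cm.segment_summaries(expr, study.locations[["location_id", "segment"]])
flags = cm.relevance_flags(summ[summ.group == "control"], summ[summ.group == "ir5h"])
flags[(flags.gene == "CASP3") & flags.flagged].segment.tolist()
# -> [1, 7, 10, 12, 13, 14, 16, 17]   (truth core segments: 7 and 13)
cm.render_segment_polar(flags[flags.gene == "CASP3"], path="casp3_flags.png")
```

The full pipeline (maps, zone stats, segment flags, manifest) runs with

```bash
cardiomap run --seed 7 --out out/        # or: simulate / quantify / map / zones / segments
```

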
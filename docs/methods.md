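# Methods

`cardiomap` implements a spatial "image-omics" workflow for the left
ventricle (LV): per-biopsy qPCR fold changes are projected onto the
bulls-eye polar map and the 3D ventricular surface in the style of an
electroanatomical mapping console, and quantified two ways — by
ischemic/remote zone statistics and by the AHA 17-segment display with a
2×SD relevance rule.  This note records the models, the defaults and why,
and what the synthetic studies do and do not establish.

## Surface model and polar projection

The LV is modelled as a truncated prolate hemiellipsoid, apex down:
`x = a sinφ cosθ`, `y = a sinφ sinθ`, `z = −L cosφ`, with basal radius
`a = 30 mm`, apex–base length `L = 60 mm` (a pig-heart scale) and
`φ ∈ [0, trunc·π/2]`.  A parametric surface was chosen over mesh
reconstruction so that synthetic data generation, projection and 3D
rendering need no point-cloud processing; reconstructing a surface from an
arbitrary catheter point cloud is out of scope.

The bulls-eye radial coordinate `rho ∈ [0, 1]` is the *normalised meridian
arc length* from the apex, computed with the incomplete elliptic integral of
the second kind and inverted by Brent's method (round-trip error ≲ 1e-12;
the test suite asserts 1e-9).  Arc-length normalisation was an open choice —
the mapping console's projection formula is proprietary — and is preferred
to chord-based alternatives because it makes `rho` strictly monotone along
every meridian and area-faithful per ring.  `theta` increases
counter-clockwise with the anterior wall at 90° (12 o'clock on the displayed
map, septum at 9 o'clock), the conventional AHA orientation.  At the apex
`theta` is undefined and reported as 0.

Segments follow the AHA 17-segment scheme on rho rings
`[0, .25) / [.25, .5) / [.5, .75) / [.75, 1]` (apex cap 17; apical 13–16 in
90° sectors; mid 7–12 and basal 1–6 in 60° sectors).  Rings and sectors are
half-open so every point has exactly one owner; `rho = 1` belongs to the
basal ring.

The default biopsy layout is deterministic: concentric rings at rho
0.125/0.375/0.625/0.875 carrying 4/12/16/20 sites (52 total), each ring
rotated by half a spacing so no site sits on a sector boundary; every
segment contains at least one site.  A seed adds reproducible jitter but is
never the default — reproducibility without a seed was judged more useful
than realism of hand-placed biopsies.

## qPCR quantification

Classical comparative-Ct with multi-reference normalisation:
`ΔCt = Ct(target) − mean(Ct of GAPDH, HPRT1, PPIA)` (the arithmetic mean in
Ct space *is* the geometric mean in quantity space),
`ΔΔCt = ΔCt − ΔCt(calibrator)`, `FC = E^(−ΔΔCt)`.

* Calibrator: no single sample is canonical, so the default is the gene-wise
  mean ΔCt over all control-group samples; a named location (e.g. the
  basal-posterior display anchor) or a single (animal, sample) can be
  selected instead.  With a named single-sample calibrator its own fold
  change is exactly 1.
* Efficiency: `E = 2` by default.  A five-point 1:8 dilution standard curve
  (OLS of Ct on log10 quantity; `E = 10^(−1/slope)`) can be attached and its
  fitted `E` is then applied run-wide — whether the original protocol
  rescaled quantities per run or only monitored efficiency is not knowable,
  so both behaviours are exposed and run-wide correction is the default.
* Replicates are averaged; a replicate SD above 0.5 cycles (a common
  laboratory convention) raises a QC flag without excluding the sample.
* The packaged primer panel covers CASP3, CLU, ERCC4, GATA4, HK2, MEF2C and
  the three references; no primer pair is available for HIF1A, which is kept
  in the default target panel with empty primer metadata.

## Display scale, interpolation, rendering

Because a voltage map cannot show negative values, fold changes are mapped
to a 0–100 display scale per gene (pooled across groups, so maps are
comparable over time): min → 0, max → 100.  Optionally a reference location
is anchored to exactly 20 display units via two linear branches
`[min, anchor] → [0, 20]`, `[anchor, max] → [20, 100]`; plain min-max is the
default.  Constant input degenerates to 20 everywhere with a warning.
Colour stops: 0 red, 10 yellow, 20 green (baseline), 60 blue, 100 pink,
interpolated linearly in RGB; green is placed at the anchor value to
reconcile "green = baseline" captions with a red-to-pink scale.

Scattered values are interpolated by inverse-distance weighting (power 2) on
the flattened disk: exact at sample sites, bounded by the input range,
parameter-light, and deterministic — appropriate when the reference
software's interpolation is unpublished.  Interpolation acts on
display-scaled values (convert, then map); interpolating fold changes first
is available as a flag.  The 3D display colours a triangulated parametric
surface (default 48×96 + apex vertex) by the same IDW in disk coordinates
and exports PLY/OBJ meshes, watertight except for the open basal rim.

## Zone statistics

The ischemic zone is a manually supplied simple polygon drawn on the 5-h
map and transposed verbatim to the other groups (all groups share biopsy
coordinates, so membership is a set identity).  Boundary points count as
inside — some fixed rule is needed, and inclusion is stable under the
polygon being drawn through a sample marker.  The remote zone is the
complement within the disk.  A display-threshold contour helper exists for
convenience but is never the default.

Per animal × gene, fold changes (never display values) are averaged inside
and outside; groups are compared by one-way fixed-effects ANOVA with the
three pairwise pooled-variance t contrasts adjusted by Holm–Šidák.  The
unit of analysis is the animal — pooling the 52 within-heart biopsies
would pseudo-replicate — with a pooled per-sample mode available.
Degenerate data policy: all-equal values give `F = 0, p = 1`; zero
within-group variance with distinct means gives `F = ∞, p = 0`.

## Segment quantification and the 2×SD rule

Per gene × group × segment, location fold changes (pooled across the
group's animals) give a mean and SD.  A control-vs-treated segment
difference is "biologically relevant" when `|mean_a − mean_b| >
2·SD_pooled`, with `SD_pooled² = ((n_a−1)s_a² + (n_b−1)s_b²)/(n_a+n_b−2)`.
The phrase "2×SD of the mean values of both segments" is genuinely
ambiguous; two alternative readings (2 × SD of the two means — which can
never flag, since SD of two numbers is |diff|/√2 — and 2 × (s_a+s_b)) are
implemented behind a switch.  Flags are strict inequalities, symmetric in
the two groups and scale-equivariant.  Segments with fewer than two values
on either side are *undetermined* and rendered grey, never red.

## Synthetic studies

The generator emulates the study design: groups control/5 h/24 h of
8/6/6 animals, 52 locations, 7 target + 3 reference genes.  On the disk the
true effect blends a core and a remote log2 amplitude through a Gaussian
kernel centred at (rho 0.35, theta 90°) — the apical-anterior mid-LAD
territory — with width σ = 0.25; the ground-truth zone is kernel weight
≥ ½ (radius σ√(2 ln 2) ≈ 0.29).  Default per-gene amplitudes encode the
qualitative spatiotemporal patterns of the seven genes (e.g. HK2 core +2 /
remote −1 at 5 h and globally −1.5 at 24 h; MEF2C flat).  Measured Ct =
baseline − log2FC + animal effect (SD 0.15 cycles, shared across genes,
cancelling exactly in ΔCt) + N(0, 0.25) per replicate (2 replicates);
reference genes carry no group effect.  Everything is deterministic given
(config, seed).

What the synthetic studies do **not** model: spatial autocorrelation of
biological noise, fibrotic admixture in basal segments, RNA-quality
gradients, gene–gene co-regulation, or non-Gaussian effect geometry.
Passing tests therefore demonstrate the *pipeline's* correctness and
calibration under the assumed noise model, not performance on real hearts.

### Validation experiments (problem sizes)

* **Null calibration** — 1000 simulated null studies (all amplitudes 0);
  the fraction of the 14 000 gene × zone analyses with any Holm–Šidák
  adjusted p < 0.05 is ≈ 4.6 %, within the nominal 5 % familywise level.
* **Zone recovery** — with a probe gene set to a pure core effect
  (log2FC 2), polygon membership matches the generator truth set exactly
  (52/52).  The in-zone *arithmetic mean* fold change sits near 2.5, not
  2² = 4: in-zone kernel weights average ≈ 0.63, so the Gaussian-blend
  field mathematically caps the zone mean well below the peak amplitude.
  The peak is recovered exactly (fold change 4.0) at a location placed on
  the kernel centre with noise off.
* **Flag recovery** — over 200 replicate default studies, the segments
  whose sampling locations lie fully inside the truth zone (7 and 13) are
  red-flagged for the core-localised probe gene in 100 % of replicates,
  and the flat gene is never flagged (0 of 3 400 segment comparisons).

These sizes keep the whole suite and the reproduction script each under a
few minutes on one CPU.

## Known limitations

* One fixed angular convention; maps from consoles with other orientations
  must be rotated upstream.
* No mixed-effects or repeated-measures modelling and no spatial
  autocorrelation correction in the zone ANOVA.
* The 9-segment console display and proprietary map exports are not
  supported.
* IDW is exact and bounded but not smooth at sample points; it is a
  display choice, not an inference method.
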
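# micromot

Quantification of spatially constrained cell motility for micropattern and
migration assays: corner/side scoring of membrane extensions and focal
adhesions (FAs) in square-confined cells, circular-dorsal-ruffle (CDR)
counting, scrape-wound track metrics, and depth-thresholded 3D
Matrigel-invasion scoring — with a seeded synthetic-data generator that
provides ground truth for every stage.

It is written for cell biologists and image analysts studying how physical
cues (ECM geometry, a free wound edge, a 3D matrix) direct where cells form
motile processes, e.g. when comparing wild-type cells against adhesion-
scaffold mutants such as paxillin-null fibroblasts.

## The measurements

**Corner/side partition.** A cell confined to a square adhesive island of
side L is overlaid with a 4x4 grid: the four corner cells versus the eight
edge-interior cells split the island boundary into two classes of equal
perimeter (2L each). Membrane extensions — thresholded actin-rich
components emanating from the cell periphery with projected area > 1 um² —
are assigned to the class holding the majority of their boundary contact,
giving per-cell corner/side areas and the corner fraction
corner/(corner+side). CDRs are interior annular actin structures
(annularity = hole/filled area > 0.1 by default) counted and measured by
their ring-filled area. FAs are detected in the adhesion-marker channel and
assigned by centroid to interior corner/side zones of equal area and equal
edge contact; FA length is the second-moment major-axis length.

**Track metrics.** For a cell track p₀…p_n at a wound edge with into-wound
unit normal **n** and edge direction **e**:

- path length P = Σ|pᵢ₊₁ − pᵢ|, net displacement D = |p_n − p₀|
- displacement into wound = (p_n − p₀)·**n** (signed)
- speed = P / elapsed time
- angle = arccos((p_n − p₀)·**e** / D), so 90° = perpendicular to the edge
- directional persistence = D / P (1 = perfectly straight path)

**Invasion scoring.** Nuclei are 3D components of a confocal z-stack taken
at 4 um intervals; a cell is *invasive* if its nucleus lies more than 8 um
into the Matrigel and *deep* beyond 24 um, expressed as percentages of all
cells and pooled over at least five fields of view.

## Worked example

Simulate and quantify two 25-cell conditions — one with a strong corner
bias for membrane extension (0.85), one unbiased (0.5):

```python
import micromot as mm

cfg = mm.RunConfig(seed=1, out_dir="demo", n_cells=25,
                   conditions={"pax_plus": 0.85, "pax_null": 0.5},
                   cdr_rate=1.0)
results = mm.run_island_pipeline(cfg)
print(results["comparisons"][["condition_a", "condition_b", "metric", "p_value"]])
```

The run writes `summaries.csv`, `records.csv`, `comparisons.csv`,
`report.{json,md}`, QC overlays and a provenance log into `demo/`. The
report for this exact invocation reads:

| condition | n | corner area (um²) | side area (um²) | corner fraction | CDRs/cell |
|---|---|---|---|---|---|
| pax_null | 25 | 78.6 | 92.1 | 0.468 | 0.96 |
| pax_plus | 25 | 169.6 | 34.6 | 0.829 | 1.04 |

| a | b | metric | p |
|---|---|---|---|
| pax_null:corner | pax_null:side | extension_area_um2 | 0.414 |
| pax_plus:corner | pax_plus:side | extension_area_um2 | 1.85e-10 |
| pax_null | pax_plus | corner_fraction | 1.17e-07 |

Read: the corner-biased condition extends 169.6 um² of membrane from corner
regions versus 34.6 um² from sides (paired p = 1.9e-10 — a genuine corner
preference), while the unbiased condition shows no preference (p = 0.41);
the measured corner fractions (0.829, 0.468) recover the planted biases,
and the between-condition difference is significant (Welch p = 1.2e-7).

The same library surface is exposed as a CLI:

```bash
micromot simulate --seed 1 --out sim --n-cells 5
micromot quantify-islands --images-dir sim --out results
micromot tracks --seed 1 --n-cells 20 --out tracks_out
micromot invasion --seed 1 --n-fovs 5 --cells-per-fov 100 --out inv_out
```

Module map: `micromot.geometry` (island model and corner/side partition),
`micromot.protrusions` (segmentation, extensions, CDRs, time courses),
`micromot.adhesions` (FA detection/morphometry), `micromot.tracks`
(migration metrics), `micromot.invasion` (z-stack scoring),
`micromot.synth` (ground-truth generator), `micromot.pipeline` /
`micromot.cli` (orchestration, statistics, reports). The science and the
numerical conventions are documented in [docs/methods.md](docs/methods.md).

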
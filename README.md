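# vesselquant

Scriptable quantification of vascular networks in fluorescence micrographs.
`vesselquant` segments bright ("labelled") vasculature on a dark background
with a multiscale Hessian tubularity filter, thins the segmentation to a
topology-preserving skeleton, analyses the skeleton into junctions,
endpoints and branches, and reports nine morphometric and spatial
parameters per image:

| parameter | meaning |
|---|---|
| explant area | area of the convex hull containing all vessel pixels |
| vessel area | area of the segmented vessels |
| vessel density | % of the explant area occupied by vessels |
| total junctions | merged branching points of the skeleton |
| branching index | junctions per unit of explant area (default 10⁴ px²) |
| total vessel length | sum of Euclidean step distances along all branches |
| average vessel length | total length / branch count |
| total endpoints | open-ended skeleton segments |
| mean lacunarity | mean of the box-counting lacunarity curve Λ(r) |

A branch ("vessel") is a skeleton segment between two branching points, or
between a branching point and an endpoint.

## Library use

```python
import vesselquant as vq

image = vq.load_image("explant.tif")             # 8/16-bit grey or 24-bit RGB
config = vq.AnalysisConfig(sigmas=(2, 4, 6), v_min=0.1, low=0.1,
                           min_particle=50, max_hole=40)
result = vq.analyze(image, config)               # AnalysisResult
run = vq.run_pipeline(image, config)             # + mask, skeleton graph, hull
vq.write_results([result], "results.csv")
vq.render_overlay(image, run.mask, run.graph, run.hull, "overlay.png")
```

`analyze` is a pure, deterministic function of `(image, config)`. Intensity
thresholds (`low`, `high`, `v_min`) are normalized to [0, 1] regardless of
bit depth; user-facing vessel *diameters* map to Gaussian scales as
sigma = d/2.

## Command line

```sh
# analyse a directory of images (one CSV row + one overlay PNG per image)
vesselquant analyze images/ --out results.csv --diameters 4,8,12 \
    --vmin 0.1 --low 0.1 --min-particle 50 --max-hole 40

# generate synthetic tubular-network fixtures with exact ground truth
vesselquant make-fixtures --out-dir fixtures --seed 1 --count 3
```

Per-image failures are isolated: remaining images are still analysed and
written, and the exit code is non-zero. A run log (config echo, per-stage
pixel counts, timings) is written next to the result table. Results can
also be mirrored to XLSX with `--format xlsx`.

## Synthetic fixtures

`vesselquant.synthetic` generates raster images of tubes and branching
trees (Gaussian cross-section around analytic centerlines) together with
exact ground truth (centerline pixels, junction/endpoint counts, total
centerline length), plus controlled degradations (`sparsify`, `thin`,
`add_specks`, `add_noise`) emulating inhibitor phenotypes. All tests run
against these fixtures; no external data is needed.

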
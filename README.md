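# cellprox

Monte-Carlo nearest-neighbour association scoring for cell-class
co-localization in masked tissue micrographs.

## The problem

In fluorescence images of tissue sections one often asks whether one cell
class preferentially localizes near another — for example, whether CD45+
leukocytes accumulate around p16+/GFP+ senescent stromal fibroblasts in
skin. Raw distances are not interpretable on their own: the answer depends
on the geometry of the analyzable region (the interstitial stroma, after
masking out epithelium, hair follicles, muscle and background) and on how
many cells of each class the image happens to contain. `cellprox`
implements the standard conditional Monte-Carlo answer for people doing
quantitative tissue image analysis: spatial statisticians' cross-type
nearest-neighbour testing, packaged for the microscopy workflow
(detection → masking → scoring → cohort aggregation).

## The statistic

For one image with query points (e.g. immune cells) and reference points
(e.g. senescent cells) inside a valid-region mask *W*:

1. `d_obs` — the median over query cells of the Euclidean distance to the
   nearest reference cell. The median, not the mean, so isolated far-away
   cells cannot dominate.
2. Monte-Carlo null: *K* rounds (default 100,000) re-place the query cells
   uniformly at random over *W*, keeping the reference cells fixed; each
   round records its median nearest-neighbour distance, giving draws
   `d_rand_1..d_rand_K` with mean `d_rand` and standard deviation `s`.
3. The **association score**

       z = (d_rand − d_obs) / s

   Positive `z`: the query class sits closer to the reference class than
   chance (association); negative: farther (repulsion). Because the
   sampled medians are near-Gaussian for non-tiny cell counts, `z = 2`
   means the observed median lies below ≈97.5% of the null medians; the
   empirical percentile is also reported directly.

Two control modes mirror the main analysis: distance to a reference
*region* (e.g. the epithelial layer) and same-class self-association
(distance to the nearest other cell of the same class, the whole set
re-placed under the null). Per-image scores aggregate to cohort level as
mean, s.d. and a Student-t 95% CI, with an association call from the CI's
position relative to zero.

Since the null conditions on the mask and the observed reference geometry,
no analytic edge correction is needed — irregular stroma with holes is
handled exactly.

## Worked example

Everything is testable without data downloads via the synthetic module,
which generates an elliptical "tissue" mask with an epithelial band and
follicle holes, two interleaved point classes (CSR, attracted with a
parent–offspring Gaussian displacement of scale `sigma_c`, or inhibited),
and rendered two-channel spot images:

```python
import cellprox as cp

spec = cp.SyntheticSpec(pattern="attracted", sigma_c=5.0, seed=42)
sample = cp.generate_sample(spec)
model = cp.NearestNeighbourAssociation(
    sample["offspring"], target=sample["parents"], mask=sample["mask"])
res = model.fit(n_rounds=100_000, seed=cp.derive_seed(42, "readme"))
print(res.summary())
```

```
Nearest-Neighbour Association Results
=====================================================
Sample:                                        sim-42
Mode:                                  point_to_point
Source points:                                    150
Target points/pixels:                              30
Observed median NN dist (px):                 5.30164
Null mean of medians (px):                    17.8895
Null s.d. of medians (px):                    1.13576
Monte-Carlo rounds:                            100000
Association score:                            11.0832
Null medians > observed:                   100.0000%
Direction:                                association
=====================================================
```

The 150 query cells sit a median 5.3 px from their nearest reference cell
where random placement in the same mask gives 17.9 ± 1.1 px, hence a score
of 11.1 s.d. — strong association, as built into this simulation. Scoring
several images and aggregating:

```python
scores = []
for s in range(4):
    sp = cp.SyntheticSpec(pattern="attracted", sigma_c=5.0, seed=s)
    sm = cp.generate_sample(sp)
    r = cp.analyze_sample(sm["offspring"], sm["parents"], sm["mask"],
                          n_rounds=10_000, seed=cp.derive_seed(7, f"img{s}"))
    scores.append(r.score)
print(cp.summarize_group(scores, "senescent-like").summary())
```

```
Cohort Association Summary
==============================================
Group:                          senescent-like
Samples:                                     4
Mean score:                            11.0379
s.d. (error bars):                      0.7267
95% CI of the mean:             (9.881, 12.19)
Call:                              association
==============================================
```

## Command line

`cellprox` exposes the same stages as subcommands:

```sh
cellprox simulate --out sim/ --pattern attracted --seed 3
cellprox detect   --image sim/query.tif --mask sim/mask.tif --out pts.csv
cellprox score    --source pts.csv --target sim/parents.csv \
                  --mask sim/mask.tif --rounds 100000 --seed 1 --out res.json
cellprox aggregate --results results/ --manifest manifest.csv --out agg/
cellprox pipeline --config pipeline.yaml --out run/
```

Real-data workflows: manually annotated cell CSVs (`x,y[,cell_class,
sample_id]`) go straight to `score`; multi-channel TIFFs go through
`detect` with a mask supplied as a binary raster or named-polygon JSON.

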
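# destain

Analysis of FM1-43 synaptic-vesicle **unloading (destaining) kinetics** in
live-cell fluorescence time-lapse movies, plus the accompanying electron-
microscopy ultrastructure statistics. The package is aimed at groups that
image FM-dye-loaded primary neurons, depolarize them (e.g. 50 mM K⁺ for
5 min) and want to quantify how strongly individual presynaptic boutons
release dye — and whether genotypes differ in their release kinetics.

Because raw microscopy data of this kind is rarely deposited, the package
ships a first-class **simulator** that renders destaining movies with exact
ground truth (bouton positions, sizes, unloading depths, trafficking
puncta, stage drift, bleaching, shot/read noise), so every stage of the
analysis is testable end to end.

## What it computes

1. **Drift correction** — translation-only registration of every frame
   against frame 0 by upsampled cross-correlation on band-passed images.
2. **Spot detection** — scale-normalized Laplacian-of-Gaussian matched
   filtering over σ ∈ [300, 800] nm with sub-pixel localization. For a
   Gaussian punctum of amplitude *A* and width σ₀ the response at scale
   σ is 2*A*σ²σ₀²/(σ²+σ₀²)², maximal (= *A*/2) at σ = σ₀.
3. **Tracking** — greedy mutual-nearest-neighbour linking; objects moving
   < 500 nm within 3 frames are *stationary boutons*, the rest are
   *trafficking* puncta and are excluded.
4. **Unloading kinetics** — each bouton trace is normalized to its
   baseline mean (relative intensity, RI ≡ 1 over the baseline window),
   gated by three criteria (post-stimulation slope drop, baseline
   stdev/mean < 0.5, baseline slope stability), and hierarchically
   clustered (Ward) into **weak** (~18 % RI decrease) and **strong**
   (~35 %) unloading profiles.
5. **Statistics** — two-sample permutation tests on the difference of
   means (exhaustive when C(n+m, n) ≤ 200 000, else Monte-Carlo with the
   (b+1)/(B+1) correction); ANCOVA-style comparison of destaining
   regression lines `RI ~ time × group` with an interaction F test; and
   Pearson correlation of vesicle density vs active-zone length for EM
   tables.

## Worked example

```python
from destain import SimulationConfig, simulate_movie, run_unloading_pipeline

cfg = SimulationConfig(width=256, height=256, n_frames=120, stim_frame=20,
                       stim_duration_frames=100, n_boutons=24,
                       n_trafficking=3, seed=8)
movie, truth = simulate_movie(cfg)
result = run_unloading_pipeline(movie)
summary, _ = result.summary_tables()
print(summary.to_string(index=False))
```

prints

```
        label  n  mean_depth  mean_post_slope
  excluded_qc  1    0.326911        -0.003752
non_responder  1    0.312834        -0.003484
       strong 12    0.318226        -0.003664
         weak  9    0.174156        -0.002104
```

24 simulated boutons (true unloading depths 0.35 strong / 0.18 weak, equal
mix) were detected, tracked and classified: 12 strong and 9 weak boutons
recovered with class mean plateau depths 0.318 and 0.174; one trace failed
the baseline-stability QC criterion and one marginal trace fell below the
responder gate. `mean_depth` is the fractional RI loss over the final
quarter of the stimulation window, `mean_post_slope` the fitted RI/frame
destaining rate. (Under a linear full-window decay the plateau-window
estimate is ≈ 0.88 × the true depth; see `docs/methods.md`.)

The same workflow is scriptable from the shell:

```bash
destain simulate movie --seed 8 --out data/
destain detect  --movie data/movie.tif --out data/spots.csv
destain track   --spots data/spots.csv --out data/tracks.csv
destain measure --movie data/movie.tif --tracks data/tracks.csv --out data/traces.csv
destain kinetics --traces data/traces.csv --stim-frame 30 --stim-duration 300 \
                 --out data/classified.csv
destain stats em --records em.csv --out em_report.csv
```

## Layout

- `destain.simulate` — movie / trace / EM-table generators with ground truth
- `destain.io` — TIFF + CSV + config readers/writers, validation, logging
- `destain.detect` — drift estimation/correction, multi-scale spot detection
- `destain.track` — linking, motion classification, ROI photometry
- `destain.kinetics` — normalization, QC criteria, profile clustering
- `destain.stats` — permutation tests, regression comparison, correlations
- `destain.pipeline` / `destain.cli` — end-to-end orchestration and CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
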
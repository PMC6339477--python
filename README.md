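# fptrack

Foraging-behaviour analysis for central-place seabirds tracked at high GPS
frequency. `fptrack` segments trajectories into **travel** and **search**
(area-restricted search, ARS) using first-passage-time analysis, annotates
behaviour with rank-standardised daily oceanographic covariates (sea surface
temperature, turbidity as Kd(490), chlorophyll-a), and estimates habitat
preference with a binomial random-intercept mixed model. It is written for
movement ecologists who have per-minute GPS fixes of repeated foraging trips
from a colony plus daily single-band covariate rasters, and who want the full
chain — filtering, scale detection, classification, annotation, inference —
as one reproducible, testable pipeline.

## The method

1. **Preprocessing.** Tracks are thinned to 1 fix/min (greedy
   nearest-to-grid subsampling, no positional interpolation). Fixes reached
   at ground speed < 10 km/h indicate a bird sitting on the water and are
   removed from behavioural analysis.
2. **First-passage time.** For fix *i* and radius *r*, FPT(*i*, *r*) is the
   time to cross a circle of radius *r* centred on the fix, summing backward
   and forward passage. Sweeping *r* over 5–1,000 m, the radius maximising
   Var[log FPT(*r*)] across a track is that track's ARS scale; the working
   scale is the median of per-track peaks.
3. **Classification.** At the working scale, fixes with FPT above a
   threshold (default 300 s) are *search*; of the remaining low band, the
   half at or below the band median is *travel*; the intermediate rest is
   excluded from modelling.
4. **Covariates.** Daily rasters are aggregated to 0.05° by NA-ignoring
   block means, averaged with the previous day, and rank-standardised onto
   [0, 20] within the analysis window, making habitat quality comparable
   across days with very different absolute ranges.
5. **Inference.** With y = 1 for search and 0 for travel,

   logit P(y_ij = 1) = β₀ + β·x_ij + αᵢ,  αᵢ ~ N(0, σ²),

   fitted by maximum likelihood with adaptive Gauss–Hermite quadrature
   (bird identity as the random intercept). Wald tests per coefficient and
   latent-scale variance-partition R² (marginal/conditional, logit residual
   variance π²/3) summarise the fit.

A seeded generator (`fptrack.simulate`) produces the whole study — looping
two-mode correlated-random-walk trips whose mode-switch hazard responds to
the ranked covariates, plus low-persistence daily raster fields — with known
ground truth for every stage.

## Worked example

```
fptrack simulate --out fixture --seed 1
fptrack analyse --config run.yaml     # tracks_path/raster_dir pointing at fixture
```

or in Python:

```python
from fptrack import SimConfig, simulate_tracks, tracks_from_frame, analyse_tracks

out = simulate_tracks(SimConfig(seed=1))
report = analyse_tracks(tracks_from_frame(out.tracks), out.stack)
print(round(report["ars"]["global_scale_m"]), "m")
print(report["summary_table"])
```

prints

```
762 m
Parameter           Estimate       SE       Z   P-value
intercept              0.474    0.243    1.95     0.051
sst_rank               0.057    0.005   11.88    <0.001
turbidity_rank        -0.042    0.005   -8.72    <0.001
chla_rank             -0.009    0.004   -2.12     0.034
random intercept variance: 0.777
R2 cond./marg.: 0.21/0.03
```

Here 762 m is the detected ARS working scale (median of per-track
variance-of-log-FPT peaks); the coefficient signs recover the generating
habitat preference (search probability rising with the SST rank, falling
with the turbidity rank; the generating chlorophyll effect is essentially
zero), and the gap between conditional and marginal R² reflects the
individual random-intercept variance.

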
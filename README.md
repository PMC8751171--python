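# mslur — multiscale land-use regression for intraurban PM2.5

`mslur` implements a two-stage exposure-modelling pipeline for mapping
fine-particulate (PM2.5) concentration across a dense city at 10 m
resolution, of the kind used in environmental epidemiology to assign
pedestrian exposure:

1. **City scale.** Hourly PM2.5 from a sparse regulatory monitoring
   network is regressed on satellite aerosol optical depth (AOD, the
   mandatory predictor) plus buffered land-use fractions, road-network
   line densities, bus-stop counts, population density, kriged station
   meteorology, sounding indices, and building-morphology summaries, with
   **geographically and temporally weighted regression (GTWR)**:

   ```
   PM2.5_ij ~ (α0 + β_ij) + (α1 + β_ij)·AOD_ij + α2_ij·P0_ij + … + ε
   ```

   Each buffered predictor family is first reduced to the single radius
   (from the 50–2000 m series) whose values correlate most strongly with
   the response (the distance-decay curve method), then a bidirectional
   stepwise screen retains only terms with p < 0.05 and VIF < 3.
   Local coefficients are weighted least squares under a gaussian
   space–time kernel; bandwidth and the space–time scale ratio minimise
   AICc; models are validated by leave-one-out CV. Seasonal fits are
   combined into an annual map by day-count weighting.

2. **Neighborhood scale.** 1-s backpack sampling along pedestrian routes
   is corrected for hygroscopic growth (`CF = 1 + 0.25·RH²/(1−RH)`),
   adjusted against the hourly background station, and converted into the
   within-site deviation **ΔPM2.5**. That deviation is regressed on sky
   view factor, point-based frontal area index, and eight road-segment
   centrality / space-syntax metrics (straightness, betweenness,
   closeness, connectivity, control value, mean depth, global/local
   integration). The resulting Δ layer is predicted only within road
   space and within the training range of each predictor (no
   extrapolation), then added onto the city-scale map.

Because real inputs of this kind (regulatory monitors, MAIAC AOD,
planning-department land use, mobile campaigns) are not redistributable,
the package ships a first-class **synthetic city generator** that
produces a complete study area — land use, buildings + DSM, road graph,
stations, population, AOD scenes with cloud QA, pedestrian tracks — with
a known generative PM2.5 truth, so the full pipeline is testable and its
parameter recovery measurable.

## Worked example

```python
from mslur.pipeline import run_pipeline
from mslur.synthetic_city import synthetic_config

state = run_pipeline(synthetic_config(seed=1), out_dir="runs/demo")

print(state["selection"].selected)
print({s: round(f.diagnostics["cv_r2"], 3)
       for s, f in state["gtwr_fits"].items()})
print(state["delta_model"].report()["selected"])
```

prints (seed 1):

```
['AOD', 'RES_300', 'KINX']
{'spring': 0.977, 'summer': 0.983, 'fall': 0.972, 'winter': 0.975}
['FAI_POINT', 'SVF', 'CLOSE', 'LINTEG']
```

Reading this: the screening kept AOD (forced), the residential areal
fraction at its true generative buffer radius of 300 m, and one
chance-level temporal covariate; the seasonal GTWR models cross-validate
at CV R² ≈ 0.97–0.98; and the neighborhood ΔPM2.5 model retained the two
morphology indices (frontal area index positive, sky view factor
negative — more open streets run cleaner) plus two network metrics. The
run directory contains the seasonal/annual/Δ/final maps as ASCII grids,
CSV tables, JSON model reports, and a manifest with content hashes; the
same config and seed reproduce it bit-identically.

The same stages are available from a shell:

```sh
mslur run --seed 1 --out runs/demo
mslur stages
```

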
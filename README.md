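# rumiclust

Sensor collars on dairy cows log how many seconds per hour each animal spends
ruminating (RT) and eating (ET). Because rumination is heritable and each
cow's circadian RT/ET pattern is a stable individual "fingerprint", those
patterns can be used to screen herds for animals with low enteric-methane
(CH4) emitting potential — without putting every cow on a gas-measurement
system. `rumiclust` implements that screening procedure end to end, for
precision-livestock and animal-science researchers:

1. **Distance.** For every pair of cows, a dependent multivariate dynamic
   time warping (DTW) distance is computed over their paired hourly (RT, ET)
   series: one warping path shared by both dimensions, squared-Euclidean
   local cost `c(i,j) = (rt_a[i]-rt_b[j])^2 + (et_a[i]-et_b[j])^2`,
   accumulated by the classical dynamic programme
   `D[i,j] = c(i,j) + min(D[i-1,j], D[i,j-1], D[i-1,j-1])`, with the reported
   distance `sqrt(D[n,m])`. An optional Sakoe–Chiba band and per-cow
   z-normalisation are available.
2. **Clustering.** Agglomerative hierarchical clustering (agnes-style;
   average linkage by default) of the DTW distance matrix, cut at k = 2 to
   give a low-rumination (LR) and a high-rumination (HR) cluster, with the
   agglomerative coefficient as a structure statistic.
3. **Ordination and selection.** Principal coordinates analysis (classical
   MDS) of the distance matrix for visualisation, then a deterministic
   version of the study-cohort pick: the most extreme cows along axis 1 in
   each cluster, paired across clusters by parity, days in milk (DIM) and
   milk yield (MY).
4. **Phenotype statistics.** Per-cow-day CH4/CO2/H2, intake (DMI), milk
   yield, CH4 efficiency (CH4/DMI, g/kg), CH4 intensity (CH4/MY, g/kg) and
   feed efficiency (MY/DMI) are compared between clusters with linear mixed
   models (cluster fixed effect, cow random intercept, REML); circadian
   behaviour is modelled with a penalized additive model (cyclic hour smooth,
   date smooth, cow intercepts); CH4–behaviour associations are screened with
   Pearson correlations in 2-hour bins.
5. **Synthetic herds.** A generator produces herds with the full statistical
   structure the analysis assumes (circadian profiles, cow fingerprints, two
   latent groups, diurnal methane tracking feeding) and known ground truth,
   so the whole pipeline runs and is testable without proprietary herd data.

The DTW/clustering/ordination stages are sklearn-style estimators
(`DTWDistance`, `AgnesClustering`, `PCoA`) and compose with scikit-learn
tooling; module-level functions wrap them.

## Worked example

Simulate a 49-cow herd at the default two-group parameters, run the full
pipeline, and select 10 cows per cluster:

```python
from rumiclust import PipelineConfig, SimConfig, run_pipeline
import pandas as pd

cfg = PipelineConfig(simulate=SimConfig(n_cows=49, n_days=7, seed=7),
                     n_per_cluster=10, out_dir="run")
artifacts = run_pipeline(cfg)
ls = pd.read_csv(artifacts["lsmeans"])
```

The run directory contains every intermediate (distance matrix, merge
history, assignments, ordination, selection, daily phenotypes, LS means,
fitted circadian curves, 2-h correlations, manifest). The LS-mean table for
this seed prints:

```
cluster         HR     LR       p
response
ch4          414.0  431.0  0.2421
ch4_per_dmi   16.6   20.3  0.0000
ch4_per_my    10.5   12.5  0.0001
dmi           25.0   21.3  0.0000
et_min       349.8  274.6  0.0000
my            39.4   34.4  0.0000
rt_min       512.1  419.1  0.0000
```

Read: the HR cluster ruminates ~93 min/d and eats ~75 min/d more, eats
~3.7 kg/d more DM and gives ~5 kg/d more milk, while emitting less methane
per kg intake (16.6 vs 20.3 g/kg) and per kg milk (10.5 vs 12.5 g/kg) —
the daily CH4 difference itself is directional but not significant at this
herd size, exactly the pattern the generator encodes. The selection stage
returned 10 LR and 10 HR cows.

The same run is available from the shell:

```bash
rumiclust run --seed 7 --out run --n-select 10
rumiclust simulate --n-cows 49 --n-days 7 --seed 7 --out herd/
rumiclust distance --sensor herd/sensor.csv --out d.csv
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch at run time: the daily-scale HR−LR cluster gaps in
rumination time, eating time and milk yield obtained by running the complete
pipeline (DTW → clustering → ordination → blocked selection → mixed models)
on a noiseless herd parameterised at the experimental-period cluster means,
and the number of cows per cluster returned by the selection stage on a
default 49-cow herd. Results are written as JSON keyed by target id.
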
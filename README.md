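# armadiel

Camera-trap analysis of nine-banded armadillo (*Dasypus novemcinctus*) diel
activity along an urban–rural gradient. Wildlife increasingly shift their
daily activity to avoid people; this package re-implements, as a tested and
reusable pipeline, a winter camera-trap study of that shift around
Fayetteville, Arkansas: photo records become independent detection events,
each event is classified day/night against monthly solar anchors, landscape
covariates are extracted around each camera, and two models quantify how
human-activity proxies relate to (a) the probability of diurnal activity and
(b) how late after sunset nocturnal activity occurs.

It is written for quantitative ecologists who want the full analysis
runnable end-to-end — including a synthetic-study generator that emulates
the 10-site study design, so every stage works without any field data.

## The analysis

**Detection events.** Photos of the target species at one camera are
collapsed by a 5-minute chaining rule (a photo joins the current event iff
it is within 5 min of the previous photo), and each event is timed at its
first photo.

**Diel classification.** An event in month *m* is DAY iff its clock time
lies in `[sunrise_m, sunset_m)`, where the boundary times are the sunrise
and sunset of the 15th day of *m* at the camera's location, computed from
the NOAA solar equations (zenith 90.833°). Nocturnal events get a timing
response: minutes elapsed from the governing sunset (the previous evening's
sunset for after-midnight events).

**Diurnality model.** A binomial GLMM with logit link:

```
diurnal_ij ~ Bernoulli(p_ij)
logit(p_ij) = β0 + β1·forest_ij + β2·developed_ij + month_ij
            + β3·dist_ij + β4·sound_ij + u_i,    u_i ~ N(0, σ²_site)
```

with forest and developed area (ha within 500 m), distance to downtown
(km), and anthropogenic L50 sound (dB) per camera, month as a 6-level
factor (October reference), and a study-site random intercept integrated
out by adaptive Gauss–Hermite quadrature (15 nodes). Wald F tests are
reported per term.

**Nocturnal timing model.** Ordinary least squares of minutes-after-sunset
on the landscape covariates, nocturnal events only.

## Worked example

Generate the deterministic design fixture (per-site camera counts, trap
nights, detection and diurnal counts equal to the study design) and run the
whole pipeline:

```
armadiel simulate --out study/ --seed 20201015 --fixed-counts
cat > run.yaml <<CFG
photos: study/photos.csv
deployments: study/deployments.csv
landcover_raster: study/landcover.asc
sound_raster: study/sound_l50.asc
output_dir: out/
forest_codes: [1]
developed_codes: [2]
CFG
armadiel all -c run.yaml
```

The site-summary table (`out/site_summaries.csv`) ends with:

```
site_id  trap_nights  n_detections  n_diurnal  pct_diurnal  mean_minutes_after_sunset  mean_dist_downtown_km  mean_sound_db
Total           5193          1209        270        22.33                     311.39                  24.26           7.52
```

i.e. 5193 trap nights and 1209 independent detections of which 270 (22%)
were diurnal; the average nocturnal detection occurred ~311 min after
sunset; detection-weighted site means of distance and sound are 24 km and
7.52 dB. Six of the ten sites are >95% nocturnal (four exclusively so),
while the remote sites (e.g. Bear Hollow, 59% diurnal; Devils Den, 31%)
show substantial daytime activity — the urban–rural behavioural gradient
the models then quantify. `out/glmm_diurnality.txt` holds the fitted GLMM
(positive distance effect, negative sound effect on the log-odds of diurnal
activity), and `out/fig_diurnal_by_site.png` / `out/fig_timing_by_site.png`
the per-site bar charts.

Python API equivalents live in `armadiel.synthetic`, `armadiel.ingest`,
`armadiel.covariates`, `armadiel.models` and `armadiel.summaries`; see
`docs/methods.md` for the underlying conventions and model details.

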
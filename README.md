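# cartizone

Zone-wise femoral cartilage thickness from transverse suprapatellar
ultrasound, with the reliability and group-comparison statistics used for
normative thickness studies.

## The problem

Knee articular cartilage thins in osteoarthritis, and B-mode ultrasound of
the distal femoral cartilage (knee flexed, probe transverse over the
suprapatellar area) is a cheap, safe way to quantify it.  A standard
protocol segments the cartilage band on a still image — the cartilage–bone
interface below, the synovial–cartilage boundary above — marks the centre
of the intercondylar notch, and splits the section into three standardised
zones: **lateral condyle | intercondylar | medial condyle**.  The
intercondylar zone is centred on the notch and spans 4.8 mm on either side
of it (25 % of the imaged cartilage width); thickness per zone is

```
thickness = cross-sectional area / length of the cartilage–bone interface
```

averaged across three repeat images per site.  This package implements that
measurement (`cartizone.quant`), analytic phantoms and synthetic cohorts
with known ground truth (`cartizone.synth`), intra-rater reliability —
ICC(3,1) with one-sided lower bound, SEM %, log-method CV %
(`cartizone.reliability`) — and the between-group inference used to compare
sexes and age bands: pooled t / Mann–Whitney, one-way ANOVA + Tukey–Kramer
or Kruskal–Wallis + Dunn/Bonferroni behind a Brown–Forsythe variance gate,
and Freeman–Halton exact tests for categorical baselines
(`cartizone.compare`, `cartizone.report`).  Every parametric test has a twin
engine that works from per-group (n, mean, SD) summaries alone, so results
published only as tables can be recomputed exactly.

The subject-level data of the normative study this targets were never
deposited; its published per-group summary statistics ship in
`cartizone.normative` and are the inputs for all recomputations.

## Worked example

Measure a flat constant-thickness phantom (38.4 mm wide, 3.0 mm thick,
notch centred — so the outer zones are 14.4 mm wide and the intercondylar
zone 9.6 mm):

```python
from cartizone.synth import PhantomSpec, make_phantom
from cartizone.quant import measure

res = make_phantom(PhantomSpec(profile=3.0))
for m in measure(res.segmentation):
    print(f"{m.zone:13s} area={m.area:6.1f} mm^2  "
          f"interface={m.interface_length:5.1f} mm  thickness={m.thickness:.3f} mm")
```

```
lateral       area=  43.2 mm^2  interface= 14.4 mm  thickness=3.000 mm
intercondylar area=  28.8 mm^2  interface=  9.6 mm  thickness=3.000 mm
medial        area=  43.2 mm^2  interface= 14.4 mm  thickness=3.000 mm
```

Recompute an age-group comparison from published summary moments (right
lateral condyle, four age bands, n = 56/70/47/59):

```python
from cartizone.normative import THICKNESS_BY_AGE_ALL, age_summary
from cartizone.compare import anova_from_summary, tukey_hsd

summ = age_summary(THICKNESS_BY_AGE_ALL, "right_lateral")
an = anova_from_summary(summ)
print(f"F = {an.f:.3f}, p = {an.p:.3f}")
print("significant pairs:", tukey_hsd(summary=summ, anova=an).significant_pairs(0.05))
```

```
F = 4.917, p = 0.002
significant pairs: ['1 > 2', '4 > 2']
```

i.e. the retirement-age band (4) and the young-adult band (1) are
significantly thicker than the middle-adult band (2) at this site.

There is also a CLI: `cartizone simulate phantom|cohort`,
`cartizone quantify --images a.png b.png c.png --notch 19.2,8.1 --spacing
0.05`, `cartizone reliability --cohort readings.csv --site right_lateral`,
`cartizone compare --cohort readings.csv --by age`, and `cartizone run`
for the full simulate → quantify → reliability → compare pipeline with a
provenance record.

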
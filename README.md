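# invasiontrace

Retracing the invasion of a species from historical occurrence records:
did it enter a region once, or several times, and where?

The motivating case is *Oxalis pes-caprae* (Bermuda buttercup), a South
African geophyte long claimed to have invaded the whole Euro-Mediterranean
area from a single plant introduced in Malta. Testing such a "monocentric"
hypothesis takes two independent lines of evidence, both implemented here:

1. **Spatial analysis of first records.** For every territorial unit (TU;
   NUTS-3 or GADM), only the *earliest* dated report is kept — later reports
   of an already-known unit would overweight well-surveyed places. The
   resulting point set (optionally restricted to records up to a year
   cutoff) is partitioned with K-means; the number of clusters k is chosen
   by maximising the mean silhouette width
   `s(i) = (b(i) − a(i)) / max(a(i), b(i))`. Each cluster is then handed to
   **geographic profiling**: a Rossmo criminal-geographic-targeting surface
   scoring every grid cell x against the cluster's observations,

   ```
   score(x) = Σ_i [ d_i > B ] d_i^(−f)  +  [ d_i ≤ B ] B^(g−f) (2B − d_i)^(−g),
   d_i = dist(x, obs_i)
   ```

   normalised to unit mass. Its peak and its top-q probability-mass region
   (the "red area") locate the most probable introduction area of that
   cluster; a Voronoi tessellation on the cluster centroids partitions the
   territory. More than one cluster with distinct origins = more than one
   introduction.

2. **Plastid haplotype frequencies.** Chloroplast microsatellites (cpSSR,
   loci ccmp3/ccmp4) define maternally inherited haplotypes
   (e.g. "122-121"). Per-population frequency tables, monomorphism counts
   and native-vs-invaded contrasts test whether invaded-range diversity is
   compatible with a single founder.

Both analyses are driven either by user CSVs or by the bundled
ground-truth-known simulators (multi-origin invasions with distance-decay
dispersal and time structure; multinomial genotype sampling), so every
stage is testable against a known answer.

## Worked example

```python
from invasiontrace import InvasionOriginModel, synthetic

# synthetic reference dataset mirroring the historical record structure:
# 181 first reports (30 cultivated, 151 wild TU), three introduction centres
rs, truth, scenario = synthetic.reference_invasion()
res = InvasionOriginModel(rs, cutoffs=(1840, 1880, 2010)).fit(seed=1)
print(res.summary())
```

```
Invasion origin analysis
========================================================================
records: 181   seed: 1   restarts: 20   metric: haversine_km

Cluster-number selection (mean silhouette width)
------------------------------------------------------------------------
  until 1840: n= 120  k*=2  [k=2:0.855  k=3:0.567  k=4:0.526  k=5:0.333  k=6:0.348  k=7:0.361  k=8:0.383]
  until 1880: n= 175  k*=3  [k=2:0.727  k=3:0.774  k=4:0.620  k=5:0.468  k=6:0.375  k=7:0.336  k=8:0.386]
  until 2010: n= 181  k*=3  [k=2:0.719  k=3:0.762  k=4:0.606  k=5:0.536  k=6:0.383  k=7:0.347  k=8:0.379]

Most probable introduction areas (geoprofile peaks)
------------------------------------------------------------------------
 cutoff  cluster  n_points  peak_lon  peak_lat  top_region_cells  top_region_q  buffer
   1840        0        76   14.5657   36.3434               632          0.05  25.850
   1840        1        44   -5.0075   37.0834               784          0.05  22.771
   1880        0        45   27.1018   38.5129               662          0.05  26.498
   1880        1        52   -5.1350   37.2214               530          0.05  30.949
   1880        2        78   14.6151   36.2754               492          0.05  30.331
   2010        0        78   14.6151   36.2754               492          0.05  30.331
   2010        1        52   -5.1350   37.2214               530          0.05  30.949
   2010        2        51   27.2386   38.5183               465          0.05  35.852
```

Reading it: with records up to 1840 two clusters are the most homogeneous
partition (silhouette 0.855); by 1880 a third, eastern cluster has
appeared and k = 3 wins (0.774) and stays the answer with all data. The
geoprofile peaks sit next to the three simulated introduction centres at
(−5.3, 37.0), (14.4, 36.2) and (27.1, 38.4) — a multi-origin invasion,
recovered from dated occurrence points alone. `buffer` is the
data-adaptive Rossmo buffer radius B in km; `top_region_cells` the size of
the top-5% "red area" on the 200×200 grid.

The haplotype side, on the bundled 37-population cpSSR survey table:

```python
from invasiontrace import load_builtin_frequencies, haplotype_summary
s = haplotype_summary(load_builtin_frequencies())
print(s.mean_frequency.round(2).to_dict())   # {'122-121': 86.86, '121-122': 6.84,
                                             #  '121-120': 2.41, '120-119': 1.78, '122-120': 2.1}
print(s.monomorphic_total, s.monomorphic_by_region)  # 17 {'invaded': 15, 'native': 2}
```

Haplotype 121-122 is present in 14 invaded-range populations but absent
from the native range — hard to square with a single founder.

Everything is also scriptable from the shell:

```sh
invasiontrace simulate invasion --seed 2 -o sim.csv
invasiontrace cluster sim.csv --until 1880 --seed 2
invasiontrace geoprofile sim.csv --grid 200x200 --q 0.05 -o gp/
invasiontrace haplotypes summary --builtin
invasiontrace run --config run.yaml          # full pipeline + checksum manifest
```

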
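# Methods

## Problem and data model

The package infers the number and location of introduction centres of a
biological invasion from dated, georeferenced occurrence records. A record
is a report of the species in a territorial unit (TU) in a given year,
flagged `cultivated` or `wild`; the year is a *terminus ante quem* — the
species was present no later than that. Before any spatial analysis, the
record set is reduced to **first records**: for every (TU, status) pair
only the earliest report is kept (ties on year broken by lexicographically
smallest record id, a deterministic and auditable rule). Cultivated and
wild streams are kept independent because escape from cultivation and wild
establishment are different events. Analyses are repeated at increasing
year cutoffs (default 1840, 1880, 2010) to trace how the inferred
structure grew through time; `filter_until` is inclusive of the cutoff
year.

Coordinates are one representative point per record, in WGS84 decimal
degrees; input CSVs accept both `.` and `,` decimal separators and `,` or
`;` field separators, because historical tables commonly use the
continental convention. Output always uses `.` decimals.

## Cluster-number selection

Points are partitioned with K-means (Lloyd iterations to convergence, max
300; k-means++ seeding; best of `n_restarts` = 20 restarts by
within-cluster sum of squares; seeded and fully deterministic), via
scikit-learn. The number of clusters is chosen by scanning
k = 2 … min(8, n−1) and maximising the mean silhouette width

    s(i) = (b(i) − a(i)) / max(a(i), b(i)),

where a(i) is the mean distance from point i to the other members of its
cluster and b(i) the smallest mean distance to any other cluster. Points
in singleton clusters get s(i) = 0 (the standard convention); ties across
k go to the smaller k (parsimony). The silhouette statistic is implemented
in-package — the implementation handles the degenerate all-singleton case
the convention requires — and is cross-checked against scikit-learn on
non-degenerate labellings in the tests.

Distances for clustering and silhouette default to Euclidean in raw
degrees, matching the plain coordinate-CSV workflow this analysis chain
historically used; great-circle (haversine, km) is available via
configuration for metric-correct runs. At Mediterranean latitudes the
difference compresses longitudes by ~cos(37°) ≈ 0.8, which does not change
well-separated cluster structure.

## Rossmo geoprofile

Each cluster is profiled independently on a regular lon/lat grid covering
its bounding box plus 10% padding per side (a degenerate, near-pointlike
box is widened to at least ±0.5°). Cell j is scored against every
observation i at distance d_ij:

    score_j = Σ_i [ d_ij > B ] d_ij^(−f)
            + [ d_ij ≤ B ] B^(g−f) (2B − d_ij)^(−g)

and the surface is normalised to sum to 1. Outside the buffer radius B the
score decays as a power law; inside it rises towards the ring d = B — the
buffer-zone behaviour of criminal geographic targeting, which here encodes
that the first *recorded* occurrences tend to sit near, not on, the point
of entry. With f = g the one-observation surface is continuous at d = B
and maximal on the ring.

Defaults, all overridable and all logged with the run:

| parameter | default | rationale |
|---|---|---|
| f, g | 1.2 | conventional decay exponents; f = g keeps the surface continuous at B |
| B | "auto" = half the mean nearest-neighbour distance among the cluster's observations | data-adaptive buffer at the scale of local record spacing; a single-observation cluster has no NN scale and falls back to 10% of the grid diagonal |
| grid | 200 × 200 cells | resolves the red area without dominating runtime |
| metric | haversine (km) | geographically correct at basin scale |
| ε_d | half the grid-cell diagonal (km), never more than B/2 | clamps d → 0 and d → 2B singularities instead of excluding cells, keeping the surface finite everywhere |

The grid is lon/lat-regular; cell-area variation with latitude is ignored
in the normalisation (scores are per-cell, as in pixel-based origin maps).
The "most probable introduction area" is operationalised two ways: the
**peak** cell (argmax, ties to the lowest row-major index) and the
**top-q region** — the smallest set of highest-scoring cells holding at
least q of the probability mass (q = 0.05 by default; 0.10 in recovery
tests). The peak always lies inside the region.

**Hit score.** Localisation quality against a known origin is the fraction
of cells scored at or above the origin's cell — the standard search-cost
measure for geoprofiles. 1/(nx·ny) is optimal; 1 means no signal. It is
used only in simulation, where the truth is known.

**Voronoi partition.** The territory is partitioned by nearest-centroid
assignment (ties to the lowest site index), with optional planar cell
polygons (shapely) for display; assignment, not polygon geometry, is the
authoritative partition, and no spherical polygon geometry is attempted.

## Synthetic data

The invasion simulator draws, per introduction centre, displacement
distances from an exponential kernel (default scale 150 km; gamma
available) with uniform bearings, moved on the sphere by the great-circle
destination formula. The record year is
`start_year + distance / spread_rate + N(0, σ_yr)`, rounded and floored at
the start year (default rate 15 km/yr, σ = 3 yr): records appear later
farther from the origin, as in a spreading wave observed through noisy
reporting. Records within 100 km of their origin are cultivated with
probability 0.5 — introductions typically begin in gardens near points of
entry. TU ids come from snapping to a 0.5° tiling, standing in for
administrative units. Output is deterministic per seed, byte-identical on
rerun, and always passes the package's own record validation; a sidecar
table carries each record's true origin and distance.

Two canned configurations exist:

* `default_three_origin_scenario` — the recovery benchmark: three origins
  (southern Spain, Sicily/Malta, western Turkey) more than 1000 km apart,
  40 points each, 150 km scale. The third origin starts in 1845, so a
  cutoff at 1840 leaves a two-origin problem.
* `reference_invasion` — a *synthetic stand-in* for the historical
  Euro-Mediterranean first-record dataset, generated (fixed seed) to match
  its printed structure: 181 first reports over distinct TUs, 30 cultivated
  and 151 wild, three introduction centres with the eastern one active only
  after 1840. It lets the full pipeline run at realistic size and geometry;
  it is not the historical table itself.

The genotype simulator draws individuals multinomially from per-population
haplotype proportions (or deterministically, by largest-remainder
apportionment, in exact-counts mode so percentage fixtures reproduce
bit-exactly), fills allele sizes per haplotype definition, and can blank
loci at a missingness rate.

What passing simulation tests shows — and does not. The generator produces
isotropic, independently placed points; real first records are constrained
to coastlines, biased by uneven survey effort across countries and
centuries, and dated only as termini ante quem. Recovery rates measured on
the simulator therefore demonstrate correctness of the machinery under the
stated model, not expected accuracy on historical data.

## Haplotype analysis

Multilocus plastid haplotypes are ordered tuples of allele sizes at the
configured loci (default ccmp3, ccmp4), labelled by hyphen-joined sizes.
Individuals missing any chosen locus are excluded from calling and always
reported. Frequencies are per-population percentages kept at full
precision internally and rounded to 2 decimals only on export. Summary
means are arithmetic means over *all* populations (absences = 0), i.e.
column SUM / number of populations; presence counts use frequency > 0; a
population is monomorphic when a single haplotype reaches 100% (within a
0.05 tolerance absorbing printed rounding). The bundled 37-population
survey table stores percentages as printed in its source (comma decimals
normalised); comparisons against printed values use absolute tolerance
0.01 because that source truncates and rounds inconsistently (e.g. 63,63
for 7/11 = 63.636…). No population-genetic statistics beyond frequencies
(no F-statistics, AMOVA or networks) are computed.

## Numerical and design choices

* Year ties, silhouette ties, Voronoi ties, argmax ties: all broken
  deterministically (smallest id / smaller k / lowest index), so every run
  is reproducible and auditable; the pipeline manifest records SHA-256
  checksums of every artifact and a rerun with the same config and seed
  reproduces them byte for byte.
* The raw (pre-normalisation) surface is additive over observations; the
  tests exploit this (surface of A ∪ B equals surface of A plus surface of
  B at fixed extent and B/ε).
* Problem sizes in the test and acceptance workloads — 10×10 grids for the
  oracle comparison, 200×200 for recovery, 50 simulation seeds — were
  chosen so the whole suite completes in well under a minute while keeping
  binomial noise on the reported rates below the asserted margins.

## Known limitations

* Geocoding of historical place names, TU boundary polygons and basemap
  rendering are out of scope; coordinates are taken as given.
* Euclidean-degree clustering is anisotropic away from the equator (option
  documented above); Voronoi *polygons* are planar approximations.
* The Rossmo exponents and buffer are conventions, not fitted quantities;
  inferred "most probable areas" are prioritisation surfaces, not
  probability statements about a generative model.
* Records dated only to a range are reduced to a single earliest defensible
  year by the data model; range arithmetic is unsupported.
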
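# Methods

## Problem and model

`pgdplan` addresses a representation problem in systematic conservation
planning: choose a top fraction of a landscape that retains not just each
species' range but the *differentiated populations* within each range, when
genetic data are unavailable for most taxa. Population structure is
surrogated by **proxies of genetic differentiation (PGD)** — a partition of
the land mask built by subdividing environmental strata (Holdridge life
zones) with historical-isolation cartography. The working assumption is
that two populations in the same proxy share both an environmental regime
(similar selective pressures) and an isolation history (ongoing gene flow),
while populations in different proxies are likely differentiated. Proxies
are deliberately coarse: they capture general phylogeographic trends, not
idiosyncratic per-species patterns, and are a stand-in to be refined as
genomic resources accumulate.

## Pipeline stages

**Grids.** All layers live on one planar grid of square cells (row 0 at the
top-left origin, half-open cell extents, left/top edges inclusive). Nothing
is resampled or reprojected: inputs that do not share the grid spec raise
an alignment error naming the offending field. Area statistics are cell
counts × cell-size²; on the intended metric grid (1 km cells in World
Mercator) cells are equal-area to a good approximation over a national
extent. GeoTIFF I/O is a thin layer over `tifffile` writing the standard
ModelPixelScale/ModelTiepoint/GDAL-nodata tags plus a citation key holding
the CRS identifier.

**Life zones.** Biotemperature is the annual mean of monthly mean
temperatures clamped to [0, 30] °C (months outside that range contribute no
plant growth). Annual potential evapotranspiration is 58.93 mm per °C of
biotemperature; the PET ratio divides it by annual precipitation. Belts use
biotemperature boundaries {1.5, 3, 6, 12, 24} °C and humidity provinces use
the log₂-spaced PET-ratio boundaries {0.125, …, 32}; all intervals are
lower-inclusive/upper-exclusive so boundary values classify
deterministically. The frost-line (warm/cool transitional) split and the
transitional hexagon triangles of the full Holdridge chart are not used:
the basic belt × humidity lattice is the only deterministic, assumption-free
reading, and the subdivision step downstream supplies finer structure
anyway. Occupied (belt, province) pairs are relabeled consecutively from 1
in (belt, province) order; the number of zones is data-dependent.

**Proxy subdivision.** Divider cartography enters as categorical rasters
plus an explicit per-life-zone assignment (which dividers split which
zone) — mirroring the expert choice of "best fitting cartography" per zone;
the phylogeographic literature synthesis behind that choice is input, not
computation. Within a zone, cells are partitioned by the joint divider
class; occupied combinations are relabeled consecutively ordered by (zone,
class tuple), so identical inputs yield identical labelings. Proxies need
not be spatially connected. An optional fragment filter (off by default —
no minimum proxy area is part of the method) merges proxies below a cell
count into their largest 4-adjacent same-zone neighbor, smallest first,
repeating until stable; isolated fragments drop to nodata.

**Features.** SDMs are binarized at a presence-based threshold: the
ten-percentile rule takes the k-th smallest presence suitability with
k = ⌈0.1 n⌉ (lower-value inclusive — no interpolation, so thresholds are
always observed suitabilities), the minimum-training-presence rule takes
the smallest; cells at or above the threshold are presences. Binary
features carry value 1 per occupied cell, so "area represented" equals
value represented. Crossing n taxa with m proxies yields n·m candidate
layers; empty intersections are dropped and, per taxon, the kept layers
tile the SDM∩land exactly. Habitat condition multiplies a feature's values
by its taxon's preference score (1 high / 0.5 low / 0.1 none) over seven
land-cover categories; rainfed/moisture agriculture is split into
less-intensive vs intensive at a 3 t/ha average unit yield (boundary
inclusive on the less-intensive side). Occurrence-only (SSI) taxa enter as
point features with weight 1 and never link a condition layer. IUCN-derived
weights are CR/EN 1, VU 0.8, NT 0.5, DD 0.3, LC 0.2, NE 0.1; an explicit
weight 0 removes a feature from the ranking while keeping it for
evaluation.

**Ranking.** The core-area rule removes, at each step, the cell minimizing
δᵢ = maxⱼ wⱼ·v′ⱼ(i)/Qⱼ(S) over features with positive weight and positive
remaining total Qⱼ. Cell cost is uniform and no connectivity or
boundary-length term is applied. Numerical choices that matter for
reproducibility:

* Qⱼ is recomputed from scratch over the retained set each batch rather
  than updated incrementally — float residue from repeated subtraction
  would otherwise make nearly-exhausted features spuriously dominate δ.
* δ is evaluated as (w·v)/Q elementwise, matching a plain scalar
  transcription of the formula bit for bit.
* Ties break by lowest linear cell index by default (a seeded random
  permutation is available); identical inputs give identical orders.
* `warp` removes that many cells per δ recomputation; warp 1 is the exact
  greedy rule, larger values trade exactness inside each batch for speed.
* An optional edge-only mode restricts candidates to the eroding boundary
  of the remaining area (an approximation device, off by default).

ADMU mode runs the ranking independently inside each planning unit
(proxy); a cell's global position is its within-unit rank quantile with
ties across units broken by unit id, so every top fraction f takes ≈ f of
each unit (± one-cell quantization). This quantile interleave is a
simplification of the administrative-units mode of established
prioritization software, whose internal weighting is not documented
publicly; it preserves the property that motivates the mode (guaranteed
per-unit representation).

A known property of the core-area rule worth stating: with two disjoint
features of unequal weight, the lighter feature's last cells still become
irreplaceable (δ → w as Q → v), so the heavier feature dominates
prefix-wise (never strictly cell-by-cell) and owns the solution core.

**Evaluation.** Representation curves are computed on binary occupancy by
default, with condition-weighted variants available separately — the two
readings of "area represented" are kept apart so both are auditable. The
top-fraction mask takes the round(f·N) highest-ranked cells, so masks at
increasing f nest exactly. Per-taxon proxy representation is the unweighted
mean over the taxon's non-empty per-proxy layers; taxa with no such layers
are excluded and reported, never silently zeroed. Sample-to-proxy
assignment uses cell-center inclusion within a metric radius (5 km in the
validation design; no partial-cell weighting), ties to the smallest proxy
id; the dominant-cluster × proxy contingency table yields an adjusted Rand
index via the standard closed form (membership vectors are retained for
other summaries).

## Synthetic generator

The generator emulates the structure the method assumes: monthly
temperatures follow a north–south gradient (8 → 26 °C annual mean, ±6 °C
seasonal cycle) and precipitation a west–east gradient (400 → 2200 mm/yr),
each plus Gaussian-smoothed white noise (autocorrelation length 4 cells) —
the simplest controllable spatial autocorrelation; dividers and
administrative units are seeded Voronoi partitions; land cover is a
seven-class argmax-of-smooth-fields mosaic; unit yields are uniform on
[1.5, 4.5] t/ha so both sides of the 3 t/ha boundary occur. Default grid:
60 × 60 cells of 1 km — the study size used throughout the examples and the
acceptance script, chosen so a full ranking stays interactive on one CPU.
Each taxon's suitability is a kernel mixture anchored at the centroids of
range proxies drawn proportional to proxy area, masked to those proxies
(ranges are unions of whole proxies); the range grows until it can hold the
occurrence sample (30 points for modeled taxa, above the 20-occurrence
modeling minimum). IUCN categories are drawn from the empirical
frequencies of the 224-taxon assessed inventory (CR 7, EN 47, VU 16, NT 9,
LC 125, DD 20). Genetic samples sit at random range cells; membership
vectors are Dirichlet draws with concentration α on the home proxy's
cluster and 1 elsewhere, so α → ∞ gives pure membership and α = 1 is
unstructured; default α = 20 gives strong but imperfect structure, as in
empirical admixture plots.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: real climate physics and topography; sliver-polygon
and registration noise in source cartography; spatial sampling bias in
occurrences; SDM commission/omission error beyond the thresholding step;
isolation-by-distance gradients within proxies (structure is purely
categorical per proxy); and linked-marker genetic data (only
cluster-membership vectors are produced, since downstream operations
consume nothing else).

## Design choices where the design was open

* Whether the scenario comparison uses extinction-risk weights and habitat
  conditions is exposed as flags; scenario comparisons default to uniform
  weights without conditions (differences then reflect feature structure
  alone), the final-analysis style run enables both.
* Per-taxon mean proxy representation is defined as the unweighted mean
  over the taxon's non-empty per-proxy layers — one concrete reading among
  several possible aggregations, flagged as such in outputs.
* Fragment filtering of the proxy map exists but defaults off.
* Expert-edited removal of overestimated SDM areas is accepted as an
  optional mask input, not computed.

## Limitations

Proxy quality is bounded by the input cartography and the life-zone
classification; no amount of ranking fixes proxies that misplace true
genetic breaks. The greedy rule is a heuristic: it guarantees a hierarchy
(nested solutions at every threshold) but not global optimality at any
single threshold. Desk-scale synthetic landscapes produce zone/proxy/layer
counts far below national-scale analyses; all representation figures in
the examples are properties of the synthetic study conditions, not
predictions for any real landscape.
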
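# Methods

This note records the scientific conventions, numerical choices and known
limitations of the package, in the spirit of a model-description appendix.

## Resistance surface and patches

Land use arrives as a 2-m categorical raster; each class carries a unitless
movement cost per metre traversed.  Two presets reflect common practice for
herbaceous-habitat taxa:

* **insects** (butterflies, orthopterans): habitat 1, favourable elements
  10, unfavourable elements 100, barriers 1000;
* **flora**: all herbaceous classes are habitat (cost 1), forests and tall
  buildings are barriers (1000), everything else 10 — wind-driven seed
  transport is only blocked by tall vertical structures.

Habitat is *defined* as cost = 1.  Patches are connected components of the
habitat mask under 8-neighbourhood (diagonally touching habitat is one
patch; the common landscape-graph convention), with a configurable minimum
size (default 1 cell).  Mosaic habitat classes can be pooled into one class
carrying the arithmetic mean of the composite costs.

Nodata cells are excluded from the movement graph entirely: they are truly
impassable and can isolate a patch (distance +∞, p = 0).  Class-coded
barriers (cost 1000) remain traversable at high cost — a hedgerow of
forest is a strong filter, not an absolute wall.

## Least-cost distances

The cell graph joins 8-neighbours with step weight
`(w_a + w_b)/2 × step length` (step = resolution, ×√2 on diagonals), where
`w` is the cell cost **except that habitat cells contribute zero**.
Consequences, all deliberate:

* distance from a patch is 0 at its own cells — distances are measured
  habitat edge to habitat edge, as in standard cost-distance software;
* a straight corridor of n cells of cost c at resolution r between two
  patches costs exactly `n × r × c`;
* movement *through* an intervening patch is free, so two patches at
  mutual distance 0 behave exactly like their union (PC is invariant to
  merging them), and effective distances are metric (triangle inequality).

Patch-to-patch distances use one multi-source Dijkstra per patch
(scipy.sparse.csgraph); since intra-habitat steps cost zero, a single
source cell per patch is exact.

## Planar graph and effective distances

Every grid cell is assigned to the patch whose habitat cell is nearest
(Euclidean); two patches are joined when their assignment regions share a
4-adjacent border.  Region adjacency of a planar partition yields a planar
graph; corner-touching regions are not joined (4-adjacency guarantees no
crossing edges).  The graph is non-thresholded: no edge is pruned by
distance.  Effective distances d_ij are all-pairs shortest paths over the
edge distances; because p = exp(−k·d) multiplies along a route, the
maximum-probability route is exactly the minimum accumulated-distance path.

## PC and dPC

`PC = Σᵢ Σⱼ aᵢ aⱼ exp(−k dᵢⱼ) / A²` with the i = j terms included
(p_ii = 1) and unreachable pairs contributing 0.  A is the full study-zone
area, so 0 ≤ PC ≤ 1 and PC = 1 only when one patch spans the zone.
`dPC = 100 (PC − PC′)/PC`, where PC′ removes the patch's node, edges and
area but keeps A fixed, and re-solves shortest paths on the remaining
planar edges — a stepping stone therefore loses more than its area share.
Removal can only lengthen paths and removes non-negative terms, so
dPC ≥ 0; a single-patch landscape gives dPC = 100 exactly.

The decay rate is calibrated as `k = −ln(p*)/d*` with p* = 0.05 at the
taxon's dispersal distance d* — the convention used by mainstream
connectivity software when only d* is reported.  Presets: flora 150/500 m,
butterflies and orthopterans 100/300 m (poorly / moderately mobile).
Highly mobile species are out of scope at the ~1-km landscape scale: their
kernel is effectively flat across the window and dPC degenerates to an
area ranking.

Sites inherit the dPC of the patch containing them; a site just outside
any patch (digitisation slack) snaps to the nearest patch within a
configurable tolerance (default 2 cells), otherwise its connectivity is
missing and propagates as NA.

## Community metrics

* **Richness** counts distinct identified taxa; a genus-level record
  ("*Chorthippus* sp.") counts only when no congeneric species-level
  record co-occurs at the site, since it may be the same species.
  Unidentified records never count.
* **Abundance** sums all records, including genus-level and unidentified
  ones.  For plants, abundance is the number of 1-m² quadrats occupied
  (0-10), so a site's plant abundance is total quadrat occurrences.
* **Evenness** is Pielou's `J = (−Σ pᵢ ln pᵢ)/ln S` (natural log),
  undefined (NA) when S < 2.
* **CWM** weights trait values by abundance shares *among trait-known
  taxa*: records with unknown traits are removed before weighting, which
  renormalises the shares.
* **θ_wb = γ/μ(α)**: γ is the pooled species count over the reference
  plots containing the focal species, μ(α) their mean richness, so
  θ_wb ≥ 1 and larger values mean broader co-occurrence (more generalist).
  Two conventions exist for μ(α); the default averages over plots hosting
  the focal species, a variant over all plots is provided.  Duplicate plot
  compositions are counted once — θ is a composition-based index and
  resampling an identical community adds no information (this also makes
  the index invariant to plot duplication).
* **Pollination dependence** is the percentage of informative trait
  databases that list insects among a species' pollen vectors.
* **Genus-trait propagation**: a genus-level record gains a trait value
  iff all congeneric species with known values agree; otherwise it stays
  missing.

## Covariates

Herbicide pressure is the area-weighted mean TFI of field polygons
intersected with a circular buffer (100 m and 300 m) around the site
centroid.  If fields with TFI information cover less than half of the
buffer, the value is missing — never imputed.  The site's own untreated
footprint can be excluded from the informative area.  Buffers are measured
from the centroid by default (a boundary mode would shift results by the
site radius, ~15-50 m).  Floral availability is the mean flowering-plant
cover over the recorded visits (up to 4); vegetation structure is percent
cover of low/medium/high herbaceous layers, validated to [0, 100] and
flagged when the sum exceeds 100.

## Statistical layer

Each response is modelled with exactly three predictors — one herbicide,
one connectivity, one local — by ordinary least squares with Gaussian
errors; at n ≈ 35 sites more terms would overfit.  Continuous predictors
are z-scored (sample SD, n−1) so coefficients are per-SD effects; soil is
dummy-coded with clay as reference, so the reported contrast is
"sandy versus clay".  Rows with any missing input are dropped
(complete cases) and the n used is recorded.  Candidate predictors are
screened so that no retained pair has |r| > 0.3; among feasible
one-per-category selections the screen minimises the maximum pairwise |r|
(ties broken by category order, then name), and logs every excluded pair.
Cross-taxon relations use pairwise-complete Pearson correlations with
exact t-transform significance at the 0.01 level.  No multiple-testing
correction is applied — effects are read as a pattern, not as confirmatory
tests.  Diagnostics translate the usual graphical checks into numbers:
Cook's distance (flag > 4/n), the slope of |residual| on fitted values
(funnel check), and Moran's I of residuals with inverse-distance weights
and a permutation p (999 relabellings by default).

## Synthetic study generator

The generator emulates the study design: a 1 km × 1 km window at 2-m
resolution (250 000 cells); 35 fenced grassland sites of 0.1-1 ha placed
on a jittered regular grid inside a crop matrix; herbaceous margins
(favourable corridors) and forest strips (barriers); fields of ~120 m
tiling the window plus a 300-m apron (agriculture continues beyond the
mapped window) with TFI ~ U[0, 2.1] and ~12% of fields uninformative;
soil clay/sandy (p = 0.375 clay), moisture 1-3, floral cover ≈ 13 ± 9%,
vegetation covers at study-scale means.  Site-level community metrics
follow

    μ = β₀ + β_herb·z(TFI) + β_conn·z(dPC) + β_local·local + N(0, σ)

with default effect sizes and noise chosen on the scale of the study's
fitted models (e.g. butterfly abundance: β₀ = 29, β_herb = −8.84,
β_conn = +9.27, σ = 17.8 — per-SD effects at n = 35).  Integer abundances
are realised by sampling species from rank-biased pools (147 plants, 32
butterflies, 17 orthopterans), distributing the target total over a
geometric rank-abundance series tuned from the evenness target (ratio 1
reproduces J = 1 exactly), capping plant counts at the 10-quadrat maximum,
and degrading a study-scale fraction of records to genus level or
unidentified.  Trait tables follow the study's distributions and
missingness rates.  A single seeded generator drives everything in a
documented order (landscape → fields → site attributes → communities taxon
by taxon), so one seed reproduces the study bit for bit.

What the generator does *not* emulate — hence what passing tests do not
show about real data: spatially autocorrelated soil and management,
temporal turnover between visits, detection error, species-level
spatial population dynamics (abundances are statistical realisations of
site-level expectations, not dispersal simulations), and realistic crop
rotations.  dPC magnitudes are of order 0.1-30% because the window holds
tens of patches; a regional map with thousands of patches yields values
orders of magnitude smaller, but the regression layer z-scores predictors
and is invariant to that rescaling.

## Numerical choices

* Distances and areas in metres / m²; planar metric coordinates
  throughout; cell-centre convention; row-major grids with row 0 at the
  top edge and origin at the lower-left corner.
* Patch ids are assigned in row-major order of first cell — stable and
  deterministic; rankings break dPC ties by patch id.
* z-scoring refuses constant variables by name rather than returning NaN.
* The collinearity screen treats categorical candidates (soil) as always
  co-selectable; they cannot enter a Pearson screen meaningfully.
* Permutation and simulation procedures take explicit seeds; library-level
  randomness always flows from `numpy.random.default_rng(seed)`.
* Problem sizes in the test-suite and acceptance script: oracle
  equivalence on 50 random ≤ 8-patch windows (72 × 72 cells); exhaustive
  path enumeration on 3 × 3 grids plus dense Floyd–Warshall on 5 × 5; sign
  recovery over 500 community redraws and CI coverage over 1000 model
  replicates at n = 35 — sizes chosen so the full chain re-runs in a few
  minutes on one CPU while keeping Monte-Carlo error well below the
  margins tested.

## Known limitations

* File-based orchestration (`run_pipeline` with paths) runs one cost
  table per invocation; multi-taxon runs chain CLI subcommands or use the
  library API.
* Intra-patch distances are zero by construction; software that charges
  cost 1 inside habitat will report slightly longer d_ij (one cell length
  per patch crossing) and marginally smaller PC.
* The Voronoi adjacency is computed in Euclidean metric, not cost metric;
  in strongly anisotropic cost surfaces a cost-space Voronoi could join a
  different (still planar) neighbour set.  The non-thresholded shortest
  paths limit the impact: an absent direct edge is replaced by a two-hop
  path whose length is what the index actually uses.
* GeoTIFF support reads bare single-band TIFF grids; georeferencing tags
  are not interpreted (resolution and origin are passed explicitly).
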
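# patchlink

Graph-theoretic landscape connectivity and community diversity analysis for
networks of small habitat patches embedded in agricultural landscapes.

## The problem

Small semi-natural grassland fragments — road verges, field margins, fenced
industrial plots such as water-abstraction sites — can act as refuges and
stepping stones for plants and insects in intensively farmed landscapes.
Whether they do depends jointly on **landscape** factors (how well connected
each fragment is to the surrounding habitat network, and how much pesticide
pressure surrounds it) and **local** factors (soil, vegetation structure,
floral resources).  `patchlink` implements the full quantitative chain needed
to ask that question:

1. **Resistance surface** — a categorical land-use raster (2-m cells) is
   mapped to per-cell movement costs (1 = habitat, 10 = favourable,
   100 = unfavourable, 1000 = barrier), per-taxon presets included.
2. **Patch network** — habitat patches are connected components of the
   cost-1 mask; a planar, non-thresholded graph joins patches with adjacent
   Voronoi regions, with edge lengths equal to least-cost distances on the
   resistance surface.
3. **Connectivity index** — the probability of connectivity

   ```
   PC = Σᵢ Σⱼ aᵢ aⱼ pᵢⱼ / A²,    pᵢⱼ = exp(−k·dᵢⱼ),   k = −ln(p*)/d*
   ```

   with patch areas *aᵢ*, effective least-cost distances *dᵢⱼ*, landscape
   area *A*, and a negative-exponential dispersal kernel calibrated so an
   organism covers its dispersal distance *d\** with probability *p\** (0.05).
   Each patch is ranked by its importance `dPC = 100·(PC − PC′)/PC`, the
   relative connectivity loss when it is removed; survey sites inherit the
   dPC of the patch containing them.
4. **Community metrics** — per-site species richness, total abundance,
   Pielou evenness `J = H′/ln S`, and community-weighted mean (CWM) traits:
   dispersal, specialization (for plants the co-occurrence index
   `θ_wb = γ/μ(α)`), and insect-pollination dependence.
5. **Covariates** — herbicide pressure as the area-weighted mean treatment
   frequency index (TFI) of fields within 100-m and 300-m buffers (missing
   when under half the buffer is informative), floral availability,
   vegetation-structure classes, soil type.
6. **Inference** — fixed three-predictor Gaussian linear models
   (`response ~ herbicide + connectivity + local`) with z-scored predictors,
   a collinearity screen (|r| > 0.3 excluded), cross-taxon Pearson
   correlation matrices, and diagnostics (Cook's distance, spread-vs-fitted
   slope, Moran's I of residuals with a permutation test).

A seeded **synthetic-study generator** produces a full study system —
raster, fields with TFI, 35 sites inside habitat patches, plant / butterfly
/ orthopteran communities whose site metrics follow a known linear model —
so every stage is testable against embedded ground truth.

## Worked example

```python
from patchlink.synthetic import SyntheticConfig, generate_study
from patchlink.pipeline import analyse_study

study = generate_study(SyntheticConfig(seed=42))   # 35 sites, 1 km², 2-m cells
bundle = analyse_study(study)

conn = study.connectivity["dpc_insect_300"]
print(f"PC (butterflies, d* = 300 m): {conn.pc:.4g}")
print(bundle.fits[("rhopalocera", "abundance")].summary().round(3))
```

prints

```
PC (butterflies, d* = 300 m): 0.001043 over 35 patches
                       beta     se       t      p
term
const                26.886  2.461  10.925  0.000
tfi_300              -1.246  2.524  -0.494  0.625
dpc_insect_300        6.228  2.515   2.476  0.019
floral_availability   2.730  2.511   1.087  0.285
n = 35
```

PC ≈ 1.0e-3 means two organisms dropped at random in the window have a
~0.1% chance of landing in mutually reachable habitat (habitat covers a few
percent of the window, and long inter-patch cost distances shrink p_ij).
The coefficient table reads like a standard regression summary: butterfly
abundance rises by ≈ 6.2 individuals per standard deviation of site
connectivity (p = 0.019) at this seed, while the herbicide and floral terms
are indistinguishable from noise — the generator embedded a positive
connectivity effect and study-scale noise, and the fit recovers it.

The same analysis runs from the shell:

```bash
patchlink synth --seed 42 --out demo/          # write raster, fields, sites, communities
patchlink connectivity --raster demo/landuse.asc --costs demo/costs_insect.csv --dispersal 300
patchlink all --seed 42 --out results/         # full pipeline, tables + run log
```

## Layout

```
src/patchlink/
  landscape.py     rasters, cost tables, patches          (stage 1)
  connectivity.py  planar graphs, least-cost d, PC/dPC    (stages 2-3)
  community.py     richness, evenness, CWM, θ_wb          (stage 4)
  covariates.py    TFI buffers, floral/vegetation covers  (stage 5)
  inference.py     DiversityLM, screen, correlations      (stage 6)
  synthetic.py     seeded study generator with ground truth
  pipeline.py      orchestration + tables + run log
  cli.py           `patchlink` subcommands
docs/methods.md    model assumptions, conventions, limitations
```
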
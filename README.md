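# jackalkit

Quantitative tools for telemetry-and-scat field studies of territorial
canids — written for wildlife ecologists who need the full analysis chain of
a home-range / habitat-selection / food-habits study in one tested package,
and exercised end to end on a golden-jackal population in seasonally dry
deciduous forest.

## What it computes

**Home ranges and density** (`jackalkit.homerange`). Utilization
distributions by bivariate Gaussian kernel on a regular grid, with the
field-standard bandwidth rule: h = 0.8 × h_ref (Worton's reference bandwidth
σ̂·n^(−1/6)), floored by the *ad hoc* bandwidth — the smallest fraction of
h_ref that still yields a single contiguous 95% isopleth with no interior
holes. Home range = 95% isopleth, core area = 50% isopleth; minimum convex
polygons (95/50%) for comparability with older literature. Overlap between
two utilization distributions is the UDOI
(A_overlap · ∫∫ UD₁·UD₂ dx dy; 0 = disjoint, 1 = identical uniform use),
and between polygons the directed percent area overlap. Monthly ranges apply
the ≥ 28-locations-and-≥ 2-weeks inclusion filter; density is
groups × mean adults per group / area.

**Resource selection** (`jackalkit.rsf`). A used–available design (default
1 presence : 10 available within each animal's 100% MCP), distance-to-feature
covariates transformed log(d+1) then standardized, a Pearson-|r| ≥ 0.7
collinearity screen, and a weighted logistic RSF (available weight 1,000)
— plain IRLS, or with a per-animal random intercept of fixed variance 10⁶
plus random slopes estimated by Laplace-approximated marginal likelihood.
Because covariates are distances, β < 0 means selection *for* a feature.
Validation is leave-one-animal-out: withheld available points define ten
equal-area score bins and the area-adjusted presence frequency per bin is
Spearman-correlated against bin rank.

**Diet from scats** (`jackalkit.diet`, `jackalkit.metrics`). Trace items
(≤ 2% of a scat) excluded; scat dry weight allocated to items by visual
volume share; correction factors (g biomass consumed per g dry remains, from
feeding trials) convert remains to percent biomass, alongside percent volume
and frequency of occurrence, by season and pooled. On top of composition:
Levins niche breadth B = 1/Σp², Horn's overlap R₀, availability shares from
ungulate density × adult female mass, and Jacobs electivity
D = (r−p)/(r+p−2rp).

**Synthetic ground truth** (`jackalkit.synthetic`). Seeded generators for
landscapes (random road/stream polylines, forest patches), habitat-biased
movement (bivariate-normal availability thinned by exp(x·β_true), so fitted
RSF coefficients have a known target), scats whose expected reconstructed
biomass equals a configured diet, and group-count density scenarios. Every
stage of the pipeline is validated against these known truths.

## Worked example

The published inputs of a dry-forest jackal study ship with the package
(`jackalkit.reference_data`): the seasonal percent-biomass diet table,
line-transect ungulate densities with adult female masses, and four annual
95% KDE home-range areas.

```python
from jackalkit import metrics, homerange, reference_data as rd

avail = metrics.available_biomass(
    rd.UNGULATE_DENSITY_PER_KM2, rd.UNGULATE_ADULT_FEMALE_MASS_KG
)
selection = metrics.ungulate_selection(
    rd.UNGULATE_CONSUMED_BIOMASS_PERCENT, avail,
    category_total=rd.UNGULATE_CATEGORY_BIOMASS_PERCENT,
)
print(selection.round(3).to_string(index=False))

p = metrics.as_proportions({t: v[2] for t, v in rd.DIET_BIOMASS_PERCENT.items()})
print("Levins B (total diet):", round(metrics.levins_B(p), 2))

mean, se = homerange.summarize_ranges(rd.KDE95_AREAS_KM2)
print(f"mean 95% KDE home range: {mean:.1f} +/- {se:.1f} km^2")
```

prints

```
 species     r     p      D
 banteng 0.000 0.723 -1.000
 muntjac 0.494 0.022  0.955
wild_pig 0.499 0.255  0.488
Levins B (total diet): 5.43
mean 95% KDE home range: 47.1 +/- 2.5 km^2
```

Reading: banteng dominates available ungulate biomass (72%) yet is never
eaten (D = −1, complete avoidance); muntjac is 2% of availability but half of
ungulate biomass consumed (D ≈ 0.95, strong selection); wild pig sits in
between (moderate selection). The diet's effective number of equally used
prey items is ≈ 5.4, and the four collared animals average a 47 km² annual
home range.

## Command line

```bash
jackalkit simulate --out runs/sim --seed 1            # synthetic study with known truth
jackalkit diet --scats runs/sim/scats.csv --out runs/diet
jackalkit homerange --relocations runs/sim/relocations.csv --out runs/hr
jackalkit rsf --relocations runs/sim/relocations.csv \
              --landscape runs/sim/landscape.geojson --out runs/rsf
```

All outputs are plain text (CSV / GeoJSON / ESRI ASCII grid), carry the seed
and a config hash, and are byte-identical on rerun.

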
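# aquaniche

Abiotic niche hypervolumes for freshwater aquaculture: is a farming site
suitable for a species, and which species can share a production system?

`aquaniche` is for aquaculture researchers and planners who want a
data-driven first screen of *abiotic* feasibility. It estimates each
species' realised niche from occurrence records overlaid on gridded
environmental layers, represents the niche as a hypervolume in a reduced
environmental space, and then answers:

- **Site suitability** — does the abiotic vector of a farming location (or a
  directly specified, regulated system) fall inside a species' niche?
- **Polyculture feasibility** — do n species' hypervolumes have a non-null
  intersection, and how do candidate combinations rank by the volume of
  their shared abiotic space?
- **Typical conditions** — per-variable density profiles of the conditions
  each species is observed under, with modes and site markers.

Biotic interactions, economics, and husbandry are out of scope: a compatible
abiotic envelope is necessary, not sufficient.

## Model

For a species with presence cells x₁, …, xₙ (rows of 19 abiotic variables:
temperature, precipitation, soil pH, slope, solar radiation, vapor pressure,
elevation, river flow, plus photoperiod summaries from the CBM daylength
model), the pooled matrix of all species under comparison is standardized
and reduced by correlation-matrix PCA, retaining components with eigenvalue
λ > 1 (Guttman-Kaiser). In the reduced space a one-class SVM with RBF kernel
(ν = 0.01, γ = 0.5 by default) delimits each species' hypervolume; its
decision function f provides the inclusion test f(z) ≥ 0. Volumes and n-way
intersections are estimated by uniform rejection sampling with stored point
clouds and binomial standard errors; a warning is raised when the retained
dimensionality exceeds ln n for a species. See `docs/methods.md` for the
full account.

## Worked example

Fit two synthetic species whose box niches overlap along a temperature
gradient, then assess a site inside the overlap:

```python
from aquaniche import NicheSuitabilityModel, SiteQuery, assess_site
from aquaniche.synthetic import two_species_fixture

fx = two_species_fixture(seed=7)                 # rasters + two occurrence clouds
res = NicheSuitabilityModel(fx.matrices, seed=7).fit()
print(res.summary())
```

```
      species  n_cells  dims   volume dim_warning
Species alpha      258     2  21.1922          no
 Species beta      265     2  20.4334          no

Intersection volume: 5.5671 (SE 0.0804) -> non-null
```

Both niches live in a 2-component space (the two gradients in the synthetic
world); the intersection volume of ≈ 5.6 is non-null, so co-farming is
abiotically feasible somewhere. Where exactly? Ask about a site:

```python
report = assess_site(SiteQuery.at_point(7.25, 7.25), res,
                     layers=fx.layers, grid=fx.grid)
print(report.to_frame().to_string(index=False))
```

```
       species  included
 Species alpha      True
  Species beta      True
<intersection>      True
```

The site's cell (centre 7.25°E, 7.25°N) lies in the longitude band where
both temperature boxes are satisfied, so both per-species verdicts and the
intersection verdict are true. A site at 18.25°E — outside both niches —
returns all-false.

The same workflow is available from the shell (`aquaniche synth / clean /
envmatrix / fit / rank / assess / density`); occurrence tables are CSV
(`species, decimalLongitude, decimalLatitude[, countryCode]`), layers are
single-band WGS84 GeoTIFFs, and environment matrices are CSVs whose columns
are the variable ids listed in `aquaniche.CATALOG`.

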
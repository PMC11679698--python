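# biomon

Analysis toolkit for **trace-metal air biomonitoring surveys** — campaigns in
which biological receptors (strawberry-plant leaves, transplanted lichens,
mosses) are exposed on a spatial grid around suspected pollution sources and
their elemental composition (XRF, ICP) is used to map exposure and apportion
sources. It is written for environmental scientists running such campaigns:
it takes a site×element concentration table with coordinates, a designated
background site, and per-element detection limits, and produces the standard
analysis chain end to end.

## What it computes

**Accumulation factor** (per sample, reference element Al):

    AF_X = (C_X / C_Al)_site / (C_X / C_Al)_background

graded none / minimal / moderate / significant / very high / extremely high at
AF = 1 / 2 / 5 / 20 / 40.

**Enrichment factor** against the upper continental crust (Rudnick & Gao 2003
table shipped, replaceable):

    EF_X = (C_X / C_Al)_sample / (C_X / C_Al)_crust

with mean EF < 10 read as crustal origin, and an element flagged *enriched*
when mean EF > 3 with ≥ 30% of samples above 3.

**Source apportionment**: Spearman screening; Bartlett sphericity; iterative
anti-image MSA elimination (drop variables with MSA < 0.5, recomputing after
each removal, with a keep-list override); KMO; PCA of the correlation matrix
retaining eigenvalues > 1; varimax rotation with Kaiser normalization;
|loading| > 0.5 source assignment.

**Spatial analysis**: global inverse-distance-weighted surfaces
(v₀ = Σ vᵢ dᵢ⁻ᵏ / Σ dᵢ⁻ᵏ, k = 2) classed by sample-value quintiles and
exported as ESRI ASCII / GeoJSON; concentric-crown profiles around a point
source with an exponential decay fit c = a·e^(−b·d); Kruskal–Wallis quadrant
comparisons.

**Biomonitor comparison** (Model II): Shapiro-routed paired t / Wilcoxon tests
of the two biomonitors' EFs, and major-axis regression with permutation tests
for the association and for slope ≠ 1. Left-censored (< DL) concentrations are
substituted by DL/2.

A synthetic-survey generator (`biomon.synth`) plants a four-component
structure — geogenic dust, a steelworks point source with exponential decay, a
traffic line source, root-uptake nutrients — over a 49-site grid with a paired
lichen survey, so the whole pipeline is testable without field data.

## Worked example

```python
import biomon

leaf_raw, lichen_raw, truth = biomon.generate(seed=3)
leaf = biomon.impute_censored(leaf_raw)

af = biomon.accumulation_factor(leaf)
print(af.mean_af[["Fe", "Cr", "Si"]].round(2))
# Fe    5.20
# Cr    5.65
# Si    1.17

sol = biomon.apportion(leaf)
print(round(sol.kmo, 3), sol.n_components)
# 0.706 4

prof = biomon.crown_profile(leaf, "Fe", truth.source_locations["steelworks"])
print(f"b = {prof.fit_b:.3f} /km, r2 = {prof.r2:.3f}")
# b = 0.461 /km, r2 = 0.977
```

The accumulation factors separate the planted steelworks tracers (Fe, Cr well
above the AF = 2 pollution threshold) from geogenic Si (≈ 1); the adequacy
statistics admit the data for PCA and four rotated components are retained;
and the crown profile recovers the planted exponential decay of Fe away from
the stack (0.5 km⁻¹) with a strong log-linear fit.

The same run is available from the shell:

```sh
biomon synth --seed 3 --out scratch/demo
biomon run --config examples/pipeline.yaml
```

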
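# Methods

This note documents the statistical procedures implemented in `biomon`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic surveys do and do not establish about real campaigns.

## Data model and censoring

A survey is a site×element matrix of concentrations in mg·kg⁻¹ dry weight
(one internal unit; g·kg⁻¹ columns are converted on ingest to avoid silent
10³ errors), with exactly one designated background site. Below-detection
(left-censored) cells — encoded in files as a `<`-prefixed token or an empty
cell, with a strict mode that rejects empties — carry a boolean mask and are
substituted by DL/2 (`impute_censored`), the conventional single-value
substitution for mapping and ratio statistics. Imputation is idempotent and
returns a new survey. Descriptive statistics (`summarize`) use the
*quantified* values only and report `n_above_dl`, matching how
detection-limited elements are normally tabulated; downstream ratio and
multivariate stages use the imputed matrix, and accumulation/enrichment
results flag every value that involves an imputed cell. The background site
is excluded from all descriptive and multivariate statistics; it enters only
as the accumulation-factor denominator and in the background-comparison
tests.

## Accumulation and enrichment factors

Both are computed per sample from Al-normalized concentration ratios: AF
against the background site, EF against an average upper-continental-crust
composition (Rudnick & Gao 2003 values shipped as an editable CSV; the
provenance label is carried into outputs). Al is treated as purely geogenic,
so AF and EF of the reference element are identically 1. Mean EF is the mean
of per-sample EFs, not the EF of mean concentrations. AF grade boundaries
follow the conventional overlapping interval labels ("2–5", "5–20", ...);
boundaries are resolved deterministically as ≤1 none, (1,2) minimal, [2,5]
moderate, (5,20] significant, (20,40] very high, >40 extremely high, so AF =
2 is moderate and AF = 1 is no accumulation. The modified coefficient of
variation (sd/median, per element over exposure sites) is scale invariant and
flags spatially heterogeneous, anthropogenically influenced elements.

## Sampling adequacy and PCA

PCA operates on the correlation matrix (z-scored variables), since element
concentrations span four orders of magnitude. Partial correlations are
obtained from the inverse correlation matrix Q = R⁻¹ as
−Q_ij/√(Q_ii Q_jj); the per-variable MSA (anti-image diagonal) is
Σr²/(Σr² + Σq²) over off-diagonal cells, and KMO is the same ratio summed
over the whole matrix (for two variables the partial equals the correlation,
so KMO = 0.5 exactly). Variable elimination is iterative — drop the lowest
MSA below the 0.5 threshold, recompute, repeat — with the dropped variables
and their MSA at drop time recorded for audit, and a keep-list override for
variables retained on substantive grounds despite a low MSA. A variable
orthogonal to all others has an undefined (0/0) MSA, reported as NaN and
never auto-dropped. One property worth knowing: a variable whose correlations
with a tight block are small but *uniformly of one sign* can show a high MSA
(its partials shrink faster than its raw correlations); the familiar
"independent variables get eliminated" behavior arises from the mixed-sign
chance correlations real noise produces.

Components with eigenvalue > 1 are retained and varimax-rotated with Kaiser
row normalization, using the pairwise-rotation algorithm; sweeps stop when
the criterion gain falls below 1e-9 (1000-sweep cap with a warning).
Rotation preserves communalities to 1e-9 by construction. Each component is
sign-flipped so its largest-magnitude loading is positive, and components are
reported in decreasing order of rotated variance; explained variance per
component is recomputed after rotation as the column sum of squared loadings
over the number of variables. `PcaSolution.from_loadings` rebuilds
communalities, assignments and variance totals from a printed loading table,
which is how published results are audited. Spearman p-values use the
t approximation for n ≥ 10 and exact rank-permutation enumeration below.

## Spatial analysis

Coordinates are projected with an equirectangular approximation about the
mean latitude (R = 6 371 000 m); over a few-kilometre grid this differs from
great-circle distances by well under a metre (a warning is raised past
100 km). IDW is global — every sample contributes with weight d⁻ᵏ, k = 2 —
so surfaces are convex combinations bounded by the sample extremes and exact
at sample locations (ε = 1e-6 m). Quintile class edges come from the
*measured station values*, not the interpolated grid, using
linear-interpolation percentiles and right-closed intervals; the default
cell size (65 m) is a tenth of the 650 m sampling-cell width. Crown profiles
assign sites to right-closed rings (default edges 1–5 km), take arithmetic
ring means, and fit ln(mean) on ring midpoints by ordinary least squares
(a = e^intercept, b = −slope, r² on the log scale); midpoints rather than
outer edges are the configurable default, and log-linear OLS rather than
nonlinear least squares mirrors the standard "exponential trendline + r²"
workflow. Quadrants are bearing-based (NE = [0°, 90°) and clockwise on);
the omnibus test is tie-corrected Kruskal–Wallis with unadjusted two-group
follow-ups (Bonferroni available by flag).

## Biomonitor comparison

Paired comparisons of the two biomonitors' per-site EFs are routed by
Shapiro–Wilk at α = 0.05 on both samples: paired t when both pass, Wilcoxon
signed-rank with Pratt zero handling otherwise. The regression surface is
the EFs, as neither biomonitor is an error-free predictor: the major axis
(first principal axis of the 2×2 covariance) treats the variables
symmetrically, and swapping them maps the slope to its reciprocal. Its 95%
CI uses the angular method (limits tan(θ ± arctan√(H/(1−H))),
H = F₁,ₙ₋₂·l₁l₂/((n−2)(l₁−l₂)²)). The association p-value permutes one
variable with |r| as the statistic, two-tailed. For the slope = 1 test the
null hypothesis makes the pair coordinates exchangeable, so the null is
built by random within-pair swaps; the statistic is |corr(y−x, y+x)|, which
is zero exactly when the major-axis slope is 1 (s_yy = s_xx). A log-slope
statistic was considered and rejected: under the swap null on ratio-scale EF
data the swapped cloud is X-shaped and the MA slope ill-conditioned, which
destroys power, while the correlation statistic is calibrated (measured
type-I 5.4% at α = 0.05 over 500 seeds) and detects planted slope ratios
essentially always at n = 40. Both p-values use (count+1)/(n_perm+1)
(super-uniform under the null); n_perm defaults to 999 and every run is
seeded.

## Synthetic surveys

The generator emulates an urban-industrial campaign: 49 exposure sites, one
per cell of a 7×11 grid of 650 m × 620 m cells (4.55 × 6.82 km), plus a
background site 5 km outside the grid whose composition equals the
background profile exactly. Log-concentrations mix four latent components
multiplicatively — positivity and lognormal behavior come for free, and
z-scored PCA can recover the structure:

* **geogenic** (Al, Si, K 1.0; Cl 0.9; Mg 0.6), spatially unstructured site
  scores ~ N(0, 0.7);
* **steelworks** (Cr, Fe 1.0; Mn 0.8; Ti 0.25), a point source whose
  log-space score is amplitude − b·d (amplitude 2.5, b = 0.5 km⁻¹), i.e.
  concentration decays exponentially at exactly b for unit loading — chosen
  over a score of e^(−b·d) precisely so that the crown profile's exponential
  model is the data-generating model and the planted b is a recoverable
  target;
* **nutrients** (P 1.0; S 0.9; Mg 0.6), unstructured, N(0, 0.9);
* **traffic** (Zn, Pb 1.0; Ti 0.6), a north–south road corridor on the west
  side with e-folding width 0.8 km and amplitude 1.8.

"Uniform" components are spatially *unstructured* (independent N(0, amplitude)
site scores), since a spatially constant score would carry no variance for
the multivariate stages to find. Both spatial components also get a per-site
N(0, 0.2) score scatter modelling exposure heterogeneity (shielding,
mounting, micro-siting); it is shared by all elements of the component, so
within-group correlations stay high while the two deterministic spatial
patterns decorrelate (their score correlation is ≈ −0.13 with the
north–south corridor; a corridor parallel to the rings of the point source
would instead confound the two sources, which design simulations showed
merges them into one bipolar rotated component). Element-level lognormal
noise is σ = 0.3. Cr and Pb are left-censored at DLs of 3.0 and 2.5 mg·kg⁻¹
against background levels of 1.5 and 3.0, giving the partial censoring
typical of XRF leaf data. The lichen survey is the leaf survey times
element-specific accumulation ratios (lichens higher in Ti, Cu, Pb, Ca, Zn,
Br; leaves higher in K, Mg, P, S, Si, Fe, Mn) with independent σ = 0.3
noise; the ratio magnitudes are plausible rather than calibrated, and they
deliberately produce EF slopes ≠ 1 for the comparison module.

Under these defaults (design simulations, 50 seeds): the Fe crown fit
recovers the planted decay within 20% in ≈ 94% of seeds; varimax PCA on the
13 structured elements retains exactly four components with each planted
group assigned to its own component in ≈ 100%; and the Zn EF slope ≠ 1 is
detected at n = 40 in 100%. When the *full* MSA-elimination chain runs first,
a pair of the nine unstructured panel elements occasionally survives
screening and contributes a fifth eigenvalue just above 1 — the familiar
Kaiser-criterion overextraction on noise, visible in the audit trail rather
than hidden.

What passing these tests does **not** show: real deposition plumes are
anisotropic (wind-rose driven), exposure periods weather the receptors
(wash-off, growth dilution), lichen and leaf uptake differ mechanistically
rather than by a fixed ratio, and measurement error is element- and
level-dependent rather than homoscedastic in log space. The synthetic
recovery results validate the *procedures*, not any field conclusion.

## Pipeline

`run_pipeline` executes impute → descriptives → AF/EF/CV → background tests
→ Spearman → PCA → spatial → comparison from a schema-validated YAML config
(unknown keys rejected); any stage failure aborts with a stage-named error.
Because the design has a single background site, the background comparison
is a one-sample test of the site−background differences (Shapiro-routed
t / Wilcoxon); a constant nonzero difference vector falls back to the exact
sign-test p-value 2·(1/2)ⁿ. α is 0.05 throughout with no multiple-testing
correction by default (Bonferroni available for quadrant follow-ups). All
randomness flows from the config seed, and re-running an identical config
reproduces byte-identical CSVs. Problem sizes used by the test suite and the
acceptance script — 25-seed recovery cohorts, 199–999 permutations, 10-seed
acceptance summaries — were chosen to keep estimates stable at a few percent
while the whole suite runs in seconds.

## Known limitations

* Isotropic IDW and crowns; no kriging or wind-sector weighting.
* DL/2 substitution biases low-concentration statistics; no MLE/Kaplan–Meier
  censored estimators.
* Orthogonal rotation only; correlated sources (e.g. co-located industry and
  traffic) will smear across components.
* The equirectangular projection is unsuitable beyond ~100 km extents.
* The MA slope CI assumes bivariate normality; for heavy-tailed EFs the
  permutation tests are the more trustworthy inference.
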
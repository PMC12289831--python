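# Methods

This note records the models, conventions and open design choices behind
`soilpte`, in the order the pipeline runs them. Units are µg g⁻¹ (dry
weight) for concentrations and metres for coordinates throughout.

## Data model and censoring

A survey is a site-by-element table with projected planar coordinates,
elevation and a land-use class. Values below the analytical detection limit
(DL) are stored *at the limit with a flag* rather than imputed at read time,
because different stages legitimately want different policies: summary
panels report censored values at the DL (with a separate `n > DL` count),
log-based stages substitute DL/2 by default, and the correlation stage
drops any element censored in more than 30% of sites (in the packaged
detection limits that removes Hg and Sb on typical surveys). Every
substitution is logged in an `ImputationRecord` and echoed in the run
manifest, so the policy behind any number is auditable. Full EM-style
censored-lognormal estimation is deliberately out of scope; DL/2 is the
standard survey convention and the policy is a config switch.

Coordinates are treated as planar metric (a projected CRS is assumed). At a
study extent of a few tens of km² geodesic corrections are far below the
sampling noise, so no reprojection machinery is included.

## Compositional treatment

Concentration vectors are compositions: only relative information is
meaningful and the constant-sum closure induces spurious negative
correlation among raw parts. All multivariate stages therefore operate on
centred log-ratio coordinates,

    clr_ij = ln( x_ij / g(x_i·) ),   g = row geometric mean,

which are zero-sum by construction and invariant to rescaling a sample by
any positive constant. The closure makes the clr covariance (and
correlation) matrix exactly singular along one direction; `soilpte`
*truncates* that null direction instead of ridge-regularising it — the
trailing eigenvalue is reported as ≈ 0 and never retained, partial
correlations for the KMO index use the Moore–Penrose pseudo-inverse, and
Bartlett's statistic uses the pseudo-determinant over the retained
eigenvalues (the classical p(p−1)/2 degrees of freedom are kept). This is
exact rather than approximate and leaves no tuning constant.

Correlations are computed on log10 data (the base only rescales columns, so
Pearson r is base-independent). The robust matrix derives from the minimum
covariance determinant scatter at support fraction 0.75 (seeded, so
deterministic); it runs on the same log matrix as the Pearson stage so the
two are directly comparable — where the two matrices disagree, outliers are
driving the plain estimate.

## clr-PCA

clr variables are standardised to unit variance before eigendecomposition
so eigenvalues live on the correlation scale; without this the Kaiser
"eigenvalue > 1" retention rule has no meaning. Retention is strict
(an eigenvalue of exactly 1 is not retained). The sign of each component is
fixed by making its largest-magnitude loading positive; for trend analysis
components are re-oriented chalcophile-positive (`results.orient(...)`), a
pure relabelling that flips no diagnostic.

Diagnostics follow standard chemometric practice:

* **KMO / Bartlett** as above.
* **Leave-one-out RMSE**: each site is held out, the PCA refit, the row
  projected onto the retained components and reconstructed; the RMSE of all
  residuals (in clr units) is expressed as a percentage of the pooled clr
  standard deviation. The normalisation is a convention of this package and
  is stated here because several incompatible "% RMSE" definitions
  circulate.
* **Hotelling T² / Q residual** at a 95% limit: T² sums squared retained
  scores over their eigenvalues with the F-based limit
  A(n²−1)/(n(n−A))·F(A, n−A); Q is the squared reconstruction residual with
  the Jackson–Mudholkar limit computed from the discarded eigenvalues (the
  Q limit is skipped, with a note, when everything is retained). A site
  beyond either limit is flagged.

Factor rotation is not offered: the components are interpreted unrotated.

## Clustering

k-means (k-means++ initialisation, 50 restarts, seeded) runs on the
*retained* component scores, not the full clr space — the discarded
dimensions are mostly noise and would dilute the partition. The number of
clusters is the silhouette-width argmax over k = 2…6, with the gap
statistic (50 uniform-box reference draws, one-SE rule) and a fixed
four-index validity panel (silhouette, Calinski–Harabasz, Davies–Bouldin,
gap) recorded as votes; the panel's composition is configurable and any
disagreement is preserved in the report rather than resolved silently. An
isolated hotspot may form a legitimate singleton cluster (its silhouette
width is 0 by the usual convention); a candidate k that forces *every*
point into its own cluster is marked invalid.

## Variogram and kriging

The empirical variogram is the classical Matheron estimator on equal-width
lag bins to half the maximum pair distance; bins with fewer than five pairs
are flagged unreliable. Model families are spherical (default, with range
= the actual correlation length), exponential and gaussian (both using the
practical-range convention, 95% of the sill at the stated range). Fitting
is weighted least squares with Cressie weights (pair count / model value²),
bounded, with a coarse grid search as a flagged fallback.

Ordinary kriging solves the full dense system (all sites in the
neighbourhood — appropriate at survey scale) with the unbiasedness
constraint, returning prediction and kriging variance on a regular grid
(default 100 m cells) masked beyond a 250 m buffer of the sample convex
hull to avoid unsupported extrapolation. The interpolated quantity is the
site-level *score* of a principal component (maps need a site-indexed
value; loadings are element-indexed), though any per-site variable can be
kriged.

## Ecological risk

For element i at a site, E_i = C_i/B_i against the locally derived
background table, Er_i = Tr_i·E_i with the Håkanson toxic-response weights
(Sb 7, As 10, Cd 30, Co 5, Cr 2, Mn 1, Hg 40, Ni 5, Pb 5, Cu 5, Tl 1, V 2,
Zn 1, and Sn 1 by analogy with other low-toxicity metals), and
RI = Σ_i Er_i over the full 14-element panel (at background concentrations
RI = ΣTr = 115). RI classes use the original 150/300/600 boundaries and Er
classes the standard 40/80/160/320 cut-offs; a value exactly on a boundary
joins the *higher* class (the interval notation "150–300" is ambiguous;
this package's convention is documented and tested). Censored cells enter
through the active censoring policy (default DL/2), recorded on the result.

Enrichment factors are direct ratios to a background or baseline median —
no crustal normaliser element — matching how survey-versus-baseline
comparisons are normally quoted; the packaged baselines are the FOREGS
European topsoil, GEMAS European agricultural and Italian agricultural
median rows. Regulatory screening compares reported values strictly
against the Italian CSC^A (residential) and CSC^B (industrial) levels; Mn
has no statutory value and is listed as skipped.

## Trend validation

A real point source should show three fingerprints, bundled by
`decay_validation`: (i) chalcophile-positive PC1 scores falling with
distance from the source — Pearson r plus the Theil–Sen slope (median of
all pairwise slopes, rank-based CI), which a single hotspot cannot move;
(ii) higher chalcophile enrichment in the high-score cluster; (iii) higher
scores on industrial land (one-way ANOVA). Under the chalcophile-positive
orientation a plume implies a *negative* distance slope; the package
standardises on that sign convention. The slope is reported in raw score
units per km by default; a log transform of shifted scores is possible but
off by default, since "log-units per km" is not a self-defining scale.
Significance here ignores spatial autocorrelation (as the classical tests
do); spatially corrected inference is noted as future work.

## Synthetic surveys

The generator emulates the survey design the pipeline assumes, with every
parameter recorded in a `GroundTruth` for recovery tests:

* **Layout**: four quadrant quotas (default 11 each, 44 sites) placed by
  rejection sampling with ≥ 250 m spacing in a 5.3 km square (~28 km²),
  source at the centre; industrial land within 1 km of the source, an
  urban patch in the north-west, agricultural elsewhere.
* **Model**: C_ij = exp(litho_ij) + A_j·exp(−d_i/λ_j)·ε_ij. The lithogenic
  term has log-median equal to the local background (so the background
  *is* B), log-SD 0.25 (mafic set) / 0.20 (others), and a shared
  unit-variance Gaussian field with exponential covariance, loading 0.7 on
  the mafic-affine elements and 0.25 elsewhere. The plume is exponential in
  distance (e-folding length 1200 m, matching a cluster of impacted sites
  within ~1.5 km of the source) with lognormal noise of CV 0.3. Amplitudes
  (As 60, Cd 0.35, Cu 30, Pb 40, Zn 150, Hg 0.04, Sb 0.10, Sn 1.5 µg g⁻¹)
  are a convention chosen so the default survey's summary panel lands in
  realistic peri-urban ranges — medians a few-fold above background for
  plume elements — not an estimate of any real flux.
* **Censoring**: values below the packaged DLs (Cd, Hg, Tl 0.10; Sb 0.50)
  are stored at the limit and flagged. Hg and Sb log-medians sit below
  their DLs (0.09 and 0.40) so surveys reproduce the regime where those
  two elements censor in well over 30% of sites and drop out of the
  correlation panel.
* **Hotspot**: the site nearest the source has its chalcophile
  concentrations multiplied by 10 — a maximum an order of magnitude above
  the mean, the signature of a waste-disposal point — applied after the
  field so it is a genuine multivariate outlier.

Two generator constants were *calibrated once* against the package's own
null requirements and then frozen: the shared-field range (600 m) and the
loading split (0.7/0.25). The reason is a clr subtlety: a field loaded
equally on all elements cancels exactly in clr (it is a row rescaling), so
only the loading *contrast* survives into clr-PCA; a long-range contrast
makes the null-scenario PC1 spuriously correlate with distance from any
fixed point. The chosen values give |r| < 0.3 in 95% of zero-amplitude
surveys while keeping visible spatial autocorrelation and a clear Cr–Ni–V
correlation cluster.

What passing tests on these surveys do **not** show: real soils have
non-stationary backgrounds (alluvial vs foothill parent material),
anisotropic dispersal (prevailing winds, river transport), multiple
overlapping sources and analytical drift. The generator deliberately
models none of these, so recovery results bound performance under the
pipeline's own assumptions, not under field conditions.

## Numerical conventions and degenerate inputs

Percentiles use linear interpolation between order statistics. CV is
100·SD/mean with the n−1 SD. Lilliefors p-values come from the
table/approximation method (deterministic); the normality flag requires
both KS and Lilliefors to be non-significant at α = 0.01. Constant columns
skip the distribution tests with a reason, make correlation pairs
undefined (NaN), and abort PCA with an error. Duplicate kriging sites are
averaged before solving; coincident-only layouts are an error. Theil–Sen
skips x-ties and errors when all x coincide. ANOVA excludes groups with
fewer than two members. The pipeline refuses surveys with fewer than 10
sites with a single clear message instead of failing mid-stage.

Problem sizes in the test-suite and acceptance script — 44-site default
surveys, 200 sites for decay-length and variogram recovery, 20 seeds for
detection-rate estimates — were chosen as the smallest sizes at which the
estimated quantities are stable, and run in seconds.

## Known limitations

* Substituted DL/2 values bias clr coordinates of heavily censored
  elements; the `exclude` policy is the honest alternative and is the
  default for correlation work.
* KMO/Bartlett on pseudo-inverted singular correlation matrices are
  descriptive, not exact-distribution tests.
* Kriging assumes second-order stationarity and isotropy of the score
  field; no co-kriging or external drift.
* No multiple-testing correction is applied to the correlation p-values —
  they are descriptive, as conventionally reported in survey tables.
* Human-health risk (dose models), geo-accumulation and Nemerow indices
  are out of scope.
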
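# Methods

This note documents the models, numerical choices and known limitations
of `eemsom`, in the order data flows through the package.

## Data model

An EEM is a rectangular wavelength grid with an explicit boolean mask;
unmeasured cells (non-rectangular synchronous-scan coverage, the
physically empty region λem ≤ λex) are masked, never zero-filled. All
multivariate statistics operate on the coordinates jointly measured
across the data set (the intersection of per-sample masks). The
canonical linearisation orders coordinates excitation-major ascending;
it is deterministic and shared by every module, so a column index in the
N×P matrix always means the same (λex, λem) pair. Wavelength grids are
compared with a tolerance of 1e-9 nm — instruments report integer
nanometres, so exactness would be safe, but a tolerance avoids
float-text artifacts in CSV round-trips. EEM files round-trip losslessly
(full `repr` precision, `float_precision="round_trip"` parsing); masked
cells serialise as empty fields.

Processing state is tracked on the EEM (`raw → corrected →
raman_normalised → max_normalised`) and may only advance, which
mechanically prevents double normalisation.

## Correction chain and optical indices

Stage order: spectral correction → Raman normalisation → inner-filter
correction → blank subtraction → (indices) → max-normalisation. The
blank is taken through the same correction and normalisation stages
before being subtracted. Choices that were genuinely open:

* **Integration rule.** Raman area and the HIX emission windows use the
  composite trapezoid (a point-sum variant is available for HIX);
  window endpoints off the grid are linearly interpolated, never
  extrapolated.
* **Inner-filter formula.** The standard absorbance form for a 1-cm
  cell, I′ = I·10^((A(λex)+A(λem))/2), with absorbance rescaled to 1 cm
  and linearly interpolated. Negative absorbances are clipped to zero
  with a warning; a total absorbance above 1.5 triggers a reliability
  warning rather than an error.
* **Index wavelengths** snap to the nearest grid point within 2 nm
  (logged), tolerating 5-nm-bandwidth instruments without silent
  extrapolation.
* **Negatives after blank subtraction are retained** (counted and
  logged): max-normalisation and SOM training tolerate them, and
  clipping would bias FRI volumes.
* HIX and FI are ratios and therefore invariant to the final
  max-normalisation; they are computed just before it.

## Q-mode SOM

Online Kohonen training on a hexagonal grid (offset rows, unit spacing
1). Schedule: learning rate linear 0.05 → 0.01 over all presentations;
bubble (0/1) neighbourhood whose radius starts at the ⅔ quantile of
pairwise unit distances and decreases linearly to exactly zero at one
third of the presentations — afterwards only the winner adapts. The
bubble kernel matches that winner-only end state; a Gaussian kernel was
deliberately not used. The codebook initialises from distinct random
data rows. Presentation order reshuffles every epoch from the schedule
seed; training is bit-reproducible given (data, grid, schedule). The
inner loop is JIT-compiled (numba) so that study-scale experiments run
in seconds.

Defaults: 100 epochs at the module level (the end-to-end pipeline uses
30 Q-mode / 15 R-mode epochs — at the package's problem sizes recovery
quality was verified insensitive to longer training, and shorter R-mode
training keeps prototypes closer to the data's cluster structure). Grid
size: ≈ 5√N units, rows:columns ≈ √(λ₁/λ₂) of the two leading
covariance eigenvalues (truncated SVD; rank-deficient covariance falls
back to a square grid with a warning). `stable_grid_size` offers the
alternative criterion of the largest candidate whose SSIntra
coefficient of variation over seeded runs stays below 5%.

BMU ties break to the lowest unit index (determinism). Cluster labels
from the complete-linkage cut are renumbered by decreasing cluster size
(ties by lowest member index), giving a stable nomenclature in which
singleton "outlier" clusters take the last labels.

## Stability diagnostics

For each leave-one-out subset, M = 50 maps are trained with seeds
derived deterministically from a master seed via
`SeedSequence(master, spawn_key=(subset, run))`, so every reported
average is exactly reproducible. Quantization stability reports the
per-subset mean and CV of SSIntra, the across-subset mean and median,
and 1.5·IQR outlier flags; note that on very homogeneous data the IQR
is tiny and the rule can flag fluctuations of a fraction of a percent.
Neighbourhood stability q_ij is the fraction of runs in which the two
samples' BMUs lie within grid radius r; the random-map reference is
Binomial(M, p_r) with p_r the fraction of *ordered* unit pairs
(including u = v — two samples can share a unit) within r. Histograms
are produced per subset and pooled, grouped into outlier/regular
subsets; a shuffled-BMU control (per-run permutation of samples over
their BMUs, preserving occupancy) provides the null comparison.

Scale caveat: the validation fixture uses 20 samples on a 3×3 map
(≈ 2 samples per unit, mirroring the occupancy of field-scale maps).
On any map this small a radius-2 bubble covers ~90% of ordered unit
pairs, so the radius-2 histogram comparison is nearly degenerate —
empirical and shuffled histograms coincide within noise; radius 1
(p_r ≈ 0.5) is the informative diagnostic at this size. Maps large
enough to make radius 2 informative would leave most units empty at
N = 20.

## R-mode analysis

Component planes are the transposed Q-mode codebook. Pearson
correlations are computed after z-scoring each plane (a no-op for
Pearson, retained for fidelity to the published recipe); zero-variance
planes receive r = 0 off-diagonal with a warning instead of NaN. The
R-mode SOM trains on the correlation matrix's rows with the same
engine; its grid again comes from the eigenvalue-shaped heuristic.
Units (not raw coordinates) are the silhouette objects, under Euclidean
distance on the codebook, with s = 0 for singletons; this matches the
magnitudes of negative-silhouette counts reported for field data. The
selection rule — candidates within δ = 0.05 of the best mean
silhouette, then fewest negatives, then larger mean, then smaller k —
reproduces the published four-component choice from the printed
statistics (δ below ~0.03 would flip that example to k = 3; δ is
configurable and logged). Clustering operates on codebook distances;
clustering on U-matrix neighbourhood distances (Vellido-style) is noted
as future work for high-resolution grids.

Component ids are renumbered by ascending mean emission wavelength of
their member coordinates, so C1 is the shortest-emission (protein-like)
component and the ordering echoes the protein → humic progression.

**FRI.** Regions are arbitrary unions of grid cells, so the
multiplication factor is defined from cell areas on the mask:
MF_i = (total masked cell area)/(region cell area), with per-point cell
widths from midpoint spacing (`np.gradient`). The default integration is
the classical Riemann cell sum; a composite-trapezoid alternative is
provided and agrees within 5% on smooth peaks at 5-nm grids — the
Riemann rule's known bias against narrow protein-like regions motivates
offering both.

## Synthetic data

Fluorophores are Gaussian products in (λex, λem), optionally with a
secondary excitation peak, scaled to unit maximum and zeroed where
λem ≤ λex. The default scenario plants four fluorophores at classical
peak positions — B (275/310, σ 12/15), T (275/340, σ 12/20), A (250/430,
σ 20/40, secondary excitation 230) and C (340/440, σ 25/45) — on the
default grid (excitation 230–410 nm, emission 310–530 nm, 5-nm steps).
Loadings are log-normal with median 1 and log-sd 0.5 (a realistic
concentration spread of roughly a factor of e±0.5), correlated through a
Gaussian copula: 0.6 within the humic pair, 0.5 within the protein
pair, 0.1 across groups. Noise is additive Gaussian at 2% of each
sample's maximum signal, clipped at zero because fluorescence
intensities are physically non-negative. Outlier samples (default 3)
each receive a distinct extra peak at 3× the median total loading,
emulating industrial effluents. Ground truth labels each coordinate
with the argmax kernel where the strongest kernel reaches 0.05;
weaker coordinates are background, excluded from recovery scoring.

What the generator does *not* emulate: Rayleigh/Raman scatter ridges,
wavelength-dependent noise, inner-filter distortion, or the smooth
continuum of real DOM spectra. The last point matters for
interpretation: planted components form crisp correlation blocks with
few boundary coordinates, whereas field EEMs grade continuously between
fluorophores. Consequently the silhouette-based component-count
selection behaves differently than on field data — on synthetic
surveys the coarse protein/humic dichotomy (k = 2) often carries the
fewest negative silhouettes and wins the selection rule, while the
four-block structure is recovered cleanly (median coordinate ARI ≈ 0.85)
once the planted component count is imposed. Passing recovery tests at
fixed k therefore demonstrates that the map and correlation stages
preserve the planted structure; the automatic k selection is validated
by the published worked example, not by the synthetic scenario.

## Problem sizes

The validation experiments are sized for a single CPU: 25 replicates of
150 samples on the 5-nm grid (≈ 1 400 coordinates, ≈ 60-unit Q-mode and
≈ 190-unit R-mode maps) for component recovery, and 20 samples × 50
runs per LOO subset for the stability suite. Together they complete in
about one minute.
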
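# Methods

This note documents the models, parameter choices and numerical decisions
behind `fabprofile`, and what the synthetic-data tests do and do not
establish.

## Signal model

A Fab clone is an intact protein species of average (not monoisotopic)
neutral mass `M` in the 45–52 kDa window. At the instrument resolving powers
used here (≤ 10 000 m/Δm) the isotope envelope is unresolved, so every
charge state is modelled as a single Gaussian. In positive electrospray the
clone appears at

    m/z(M, z) = (M + z·m_p) / z,   m_p = 1.007276 Da,

for a contiguous range of charges, with peak FWHM = m/z / R where R is the
instrument resolving power. Chromatographically a clone elutes as a Gaussian
in retention time. The observed MS1 run is the sum of all clones' envelopes,
an optional broad unresolved background, and noise.

## Sliding-window preprocessing

The region of interest (default 10–50 min) is partitioned into windows of
`slice_width` 0.3 min with `slice_overlap` 0.05 min; window k starts at
`roi_start + k·(width − overlap)`, generation stops when coverage reaches
`roi_end`, and the final window is clipped there. Windows are half-open
`[start, end)`, the last closed, so a boundary scan belongs to exactly one
of two adjacent windows. With the defaults the 40 min region yields exactly
160 windows.

Scans are linearly resampled onto one uniform m/z grid (`mz_spacing`,
default 0.1 Th) before point-wise averaging; the processing order is fixed:
average → baseline-subtract → smooth → deconvolute. Empty slices are
skipped, not interpolated.

**Baseline.** The vendor "flatness" knob has no published formula. Here
flatness f ∈ (0, 1] maps log-linearly to a length scale L(f) = 10^(1+2f) Th
over [10, 1000] Th (f = 0.8 → ≈ 400 Th), and the baseline is estimated by
asymmetric least squares: minimize Σ w_i (y_i − b_i)² + λ Σ (Δ²b)_i² with
λ = (L / 2πΔx)⁴, weights `asymmetry` (default 0.1) above the baseline and
1 − asymmetry below, re-evaluated for 10 rounds, solved as a pentadiagonal
banded system. The effective stiffness under peak regions is λ/asymmetry,
so the cut-off there is L·asymmetry^(−1/4) ≈ 700 Th at the defaults — still
below the ~800 Th width of the unresolved background hump, which is
therefore tracked to a few percent, while charge-state peaks three orders
of magnitude narrower are passed under essentially untouched (apex retained
within 5 % in tests). The mapping is documented and tested for monotonicity
(higher flatness → stiffer baseline), *not* for equivalence with any vendor
implementation.

**Smoothing.** Gaussian convolution with FWHM `smooth_width` (0.2 Th),
σ = width/2.3548, applied `smooth_iterations` (1) times; total intensity is
conserved to 0.1 % away from grid edges.

## Charge-state deconvolution

The zero-charge spectrum x(M) ≥ 0 on the uniform mass grid (45 000–52 000 Da,
0.1 Da — "data point spacing 0.1" is read as the output grid spacing) is
inferred under the forward model

    ŷ(mz) = Σ_M Σ_z x(M) · (1/n_z) · g(mz; m/z(M, z), FWHM = mz/R),

with a uniform charge prior over [charge_min, charge_max] (default 12–60;
the envelope simulator uses the observed 22–42 range, and the solver is
robust to the prior being wider than the truth). The 1/n_z normalization
puts deconvoluted intensity on the scale of a species' total observed
envelope intensity — the scale on which the absolute peak-picking threshold
of 500 counts operates.

The solver uses multiplicative Richardson–Lucy-type updates
x ← x ⊙ (Aᵀ(y/ŷ)) ⁄ (Aᵀ1) from a uniform start, stopped when the relative
L1 change falls below `convergence_tol` (1e−4) or after `max_iterations`
(100). Updates preserve non-negativity and exact linearity in the input
scale. This is a contract-level replacement for proprietary
maximum-entropy deconvolution: on noiseless single-species inputs the
dominant output peak centroid is sub-ppm to few-ppm accurate (mean < 5 ppm
over random fixtures, the same order as the ~6.8 ppm average error reported
for real cross-platform data) and carries ≥ 90 % of the output intensity;
internals are not matched.

Implementation: for each charge the mass grid maps linearly to m/z, stored
once per configuration as a stacked sparse scatter matrix; the Gaussian
peak shape is applied per charge as a 1-D convolution with σ evaluated at
the centre of that charge's m/z span (its variation across one envelope is
~±15 %; a symmetric kernel does not bias centroids). The operator is cached
across slices.

**Peak picking.** Local maxima with apex ≥ `peak_intensity_threshold` (500)
are processed tallest-first; maxima closer than one window — window width
mass/`peak_resolving_power` (6 500 → ≈ 7.4 Da at 48 kDa) — merge into the
taller one. Each surviving apex is centroided by intensity-weighted mean
over its window. Reported intensity is apex *height* (vendor "absolute
intensity threshold" semantics are height-like); this is a documented
choice, as is the centroiding rule standing in for the unpublished vendor
"Sum Peak" algorithm.

## Clone assembly

Per-slice peaks are merged by greedy intensity-ordered clustering: the most
intense unassigned peak seeds a cluster, which absorbs unassigned peaks
within `merge_ppm` (50) of the running intensity-weighted mean mass and
within `merge_max_rt_gap` of the nearest member — except peaks from a slice
already in the cluster, since two masses resolved within one slice are
distinct species by construction. Ties break by lower mass then lower slice
index, making the result deterministic and input-order independent. Clone
mass is the intensity-weighted member mean (a documented choice; uniform
averaging would also be defensible), intensity the apex member's, RT the
apex slice's. `merge_max_rt_gap` is unbounded by default (the 2 min cap
belongs to the Orbitrap-style configuration, together with 30 ppm). No
minimum-slice-count filter is applied.

## Similarity scoring

Profiles are reduced to the `similarity_top_n` (100) most intense clones.
Candidate cross-profile pairs within `similarity_tolerance` (1.5 Da) are
sorted by ascending mass difference — ties by the smaller, then larger,
member mass, a symmetric key, so score(a,b) = score(b,a) exactly — and
matched one-to-one greedily. Unmatched clones contribute one-sided vector
entries. The score is the cosine of the matched intensity vectors, clipped
to [0, 1]; intensities enter untransformed (no square-root, rank or floor
transform). An empty or all-zero side scores 0 by convention; identical
aligned vectors score exactly 1. The reference implementation this mirrors
bins masses rather than matching one-to-one; one-to-one matching was chosen
because it is symmetric and deterministic, with identical tolerance
semantics.

## Synthetic runs

`make_repertoire` draws masses uniformly in the configured mass window and
abundances log-uniformly over two orders of magnitude; elution centres are
uniform in the RT window with σ = 0.1 min. Neither the elution width nor
the abundance distribution is quantified in the source setting; both are
stated assumptions. The charge envelope is a truncated discrete Gaussian,
centre 32, σ 4, bounds 22–42, matching observed denatured-Fab envelopes.
The unresolved background is one broad Gaussian (centre 1500 Th, FWHM
800 Th, amplitude user-set, default 0) standing in for the elevated
baseline seen at 1000–2000 m/z in serum runs; noise is additive
half-normal per grid point (no shot noise). Rendering is deterministic
given the seed.

The absolute abundance scale (default 1e5–1e7 arbitrary units) is chosen so
that the weakest clone's deconvoluted apex sits roughly ten-fold above the
absolute reporting threshold of 500 counts: recall experiments measure the
pipeline's ability to recover reportable clones, and in real data all
counted clones exceed the reporting threshold by construction.

What a green synthetic test does **not** establish: performance on real
serum complexity (hundreds of co-eluting clones with correlated elution),
isotope structure, adducts, chromatographic tailing, detector saturation,
or cross-run RT drift. Desk-scale scenarios use shortened elution regions
(e.g. 10–13 min) purely to bound runtime; slice geometry, grids and all
thresholds are the published values.

## Numerical details and edge cases

- All retention times are minutes everywhere; seconds in mzML scan times
  are converted on read.
- m/z sampling: at 0.1 Th spacing the narrowest (highest-charge) peaks are
  below Nyquist (σ ≈ 0.5 grid steps at 42+). Centroids of symmetric peaks
  remain accurate; tests of the exact mass–m/z round trip use a finer grid
  to separate model correctness from grid aliasing.
- Zero input spectra deconvolute to zero without iterating; non-finite or
  negative intensities are rejected.
- Empty-overlap similarity pairs score 0, not NaN; `top_n` ties at the
  cutoff keep the lower mass.
- Config files are flat `key = value` text; unknown keys and invariant
  violations raise errors naming the key; `merge_max_rt_gap` accepts
  `inf`/`unbounded`.
- Clone tables round-trip losslessly to the documented precision (masses
  to 0.1 mDa, RT to 0.1 mmin, intensities to 6 significant digits).

## Known limitations

- The deconvolution is maximum-likelihood, not entropy-regularized; on
  noisy data it will happily produce spiky solutions, and closely spaced
  species (< ~2 Da) merge into single peaks at these resolving powers.
- The per-charge constant-σ approximation slightly mis-weights envelope
  edges for species far from the mass-window centre (no observed centroid
  bias).
- Greedy clone merging is deterministic but, like any greedy partition,
  not globally optimal; near-threshold mass pairs can split differently
  than an exhaustive method would.
- mzML support covers the MS1 profile subset this pipeline consumes
  (32/64-bit float arrays, zlib or uncompressed); vendor raw formats are
  out of scope.
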
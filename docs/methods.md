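# Methods

This note documents the models, estimators and numerical conventions behind
punctakit, the defaults and why they were chosen, and what the synthetic-data
tests do and do not establish about real microscopy data.

## Synthetic movie model

The generator emulates single-plane spinning-disk movies of endocytic puncta
at the basal plasma membrane.  Events nucleate as a homogeneous spatial
Poisson process at rate `event_rate` (events·µm⁻²·s⁻¹), live for a
truncated-normal lifetime (hard minimum of one frame), and are imaged as
isotropic 2-D Gaussians (sd `psf_sigma_px`, peak `amplitude_photons`) on a
constant background, with per-pixel Poisson photon noise followed by additive
Gaussian readout noise (camera gain fixed at 1 ADU/photon, since every
downstream statistic is intensity-scale invariant).

Defaults and their provenance:

| parameter | default | rationale |
|---|---|---|
| `pixel_size_um` | 0.13 | EMCCD with 13 µm pixels behind a 100× objective |
| `frame_interval_s` | 1.0 | typical streaming interval for recruitment imaging |
| `n_frames` | 120 | 2 min, several event lifetimes |
| `lifetime_mean_s`, `lifetime_sd_s` | 42, 5 | endocytic events last ~35–50 s |
| `event_rate` | 0.0012 | gives `rate × lifetime ≈ 0.05` dots/µm² steady state, the observed regime for strongly recruited proteins |
| `psf_sigma_px` | 1.3 | diffraction-limited spot at ~0.13 µm/px |
| `amplitude_photons`, `background_photons`, `readout_noise_sd` | 200, 20, 2 | peak SNR ≈ 13; order-of-magnitude choices (no quantitative SNR is published for this kind of data), all exposed in `SimulationParams` |
| `coloc_fraction`, `lag_s` | 0.5, +1.0 | half of channel-A events have a channel-B partner appearing 1 s later |

A truncated normal was chosen for lifetimes as the simplest two-parameter
family with hard positivity.  Partnered events share the exact position
(optional `jitter_sd_px`), reflecting that coupled proteins decorate the same
structure.

**Burn-in.**  Event onsets are sampled over `[−burn_in, duration)` with
`burn_in = lifetime_mean + 3·sd` by default, so the movie opens in steady
state and the density invariant `density → event_rate × mean lifetime` holds
from frame 0.  The count of onsets *inside* the movie window remains Poisson
with mean `rate × area × duration`.  Events extending past either end are
clipped at render time, never wrapped.

`simulate_shock_movie` models an acute perturbation by superposing a second
event process at `(rate_factor − 1) × event_rate` from the shock time onward.
Density then relaxes toward `rate_factor ×` baseline with a time constant set
by the lifetime: the expected increment at time *u* after the shock is
`rate · E[min(u, L)]`, so a 90 s post window after a 2× step averages ≈1.8×
baseline rather than 2× — visible in the shock analysis script's output and
accounted for when interpreting window means.

**What the generator does not model:** lateral diffusion or drift of puncta,
membrane tubulation, 3-D PSF and defocus, photobleaching, cell-shape changes
during perturbation, and non-uniform background.  Passing tests therefore
demonstrate correctness of the estimators under these idealized conditions,
not robustness to every artifact of real movies.

## Wavelet detection

The à trous transform uses the separable B3-spline kernel `[1,4,6,4,1]/16`
with `2^(j−1) − 1` zeros inserted between taps at scale *j*; detail planes
are differences of successive smooths, so reconstruction is exact by
construction (verified to <1e−9 against the input, and the planes to <1e−10
against a direct dilated-kernel convolution).  Borders are mirror-reflected,
which avoids the edge gradients that would otherwise inflate the noise
estimate.

Per-plane noise is estimated robustly as `MAD/0.6745`; sparse bright spots
perturb this by well under 10%.  The binary support takes `w_j > k·σ_j` on
scales {2, 3} combined with AND (the positive multiscale product of
hard-thresholded planes) by default — scale 1 is noise-dominated at a 1.3 px
PSF, and the AND suppresses single-scale noise excursions to <0.5% of pixels
on pure noise.  OR combination is available (`use_multiscale_product=False`).
Because both the coefficients and the MAD scale linearly with intensity, the
support is invariant under multiplication of the frame by any positive
constant, and raising `k` can only shrink it.

Components are 8-connected, labeled in raster order for determinism, with
`min_area_px = 4` rejecting single-pixel noise.  Centroids are
intensity-weighted means over the component's raw-frame pixels; no Gaussian
fitting is attempted.

**Resolution limit.**  At the default density, essentially all detection
misses are pairs of events closer than ~8 px whose supports merge into one
component; the matched recall is 0.95 ± 0.03 per movie (precision ≈0.99,
centroid RMSE ≈0.25 px at ≤2 px gating).  Deblending merged components was
deliberately left out: a punctum is defined as one connected component of
the mask, which keeps the mask, the puncta table and the overlap images
mutually consistent.  The density estimator consequently undercounts by
roughly the merge rate (~4–5% at 0.05 dots/µm², more at higher densities).

## Colocalization scores

The overlap percentage is `100·|A∧B|/|A∨B|` (a Jaccard index in percent):
the analysis constructs exactly the AND ("overlap") and OR ("sum") images,
and this is the only scalar using both.  It is symmetric, bounded in
[0, 100], defined as 0 when both masks are empty; per movie, frames with an
empty OR image carry no information and are excluded from the average.  A
directional object-based alternative — the fraction of reference-channel
puncta whose component touches the other channel's mask — is provided
(`object_overlap_fraction`) since "overlap of X with Y" phrasing is
directional; the pixel-based score remains the headline metric.

Spatial cross-correlation correlates the *wavelet-denoised* images (sum of
significant detail coefficients) rather than raw frames (background would
dominate) or binary masks (near-binary images flatten the profile): for each
integer shift `d` along one axis, Pearson correlation is computed on the
overlap region only, with constant regions reported as missing.  Shift 0
equals the textbook Pearson coefficient exactly; swapping the channels
mirrors the profile.  Default range ±20 px along x; per-movie profiles
average the per-frame profiles over frames with defined values.

## ROIs, traces and the lag estimator

ROI construction follows the dual-channel recipe: each channel's mask stack
is projected over time (pixel true if ever significant), and the AND of the
two projections is split into 8-connected components (≥ `min_area_px`).
This is the reading of "OR then AND" that yields regions where *both*
proteins appear, which is what per-ROI dual-channel traces require.  Traces
are unweighted means of the **raw** stacks over the ROI pixels — the wavelet
transform only decides *where* to measure, never *what*.

The per-ROI cross-correlation z-scores each channel over the full trace
(population sd), then averages lagged products with the `1/N_τ`
normalization over the valid overlap.  This estimator is bounded by 1 at lag
0 (where it equals the Pearson coefficient) and tie-free in practice; at
extreme lags on short traces the valid-window variance can differ from the
global variance, so |r| is not mathematically capped at 1 — values are not
clipped, keeping exact agreement with the brute-force reference
implementation (<1e−12).  Zero-variance channels exclude the ROI.  Peak lags
break ties toward 0 and then toward positive lag: deterministic, and
conservative about claiming a recruitment order.  Default `max_lag` is ±10
frames; the pipeline clamps it for very short movies.

**Aggregation matters.**  With 42 s lifetimes and 1 s frames, the expected
margin between the aggregate correlation at the true ±1-frame lag and at lag
0 is only ~0.008 with a per-ROI spread of ~0.06, so single movies with a few
dozen ROIs recover ±1-frame lags unreliably.  Lag analyses therefore pool
ROI profiles across several movies (cells) — a few hundred ROIs resolves
every programmed lag in {−2, −1, 0, +1, +2} frames exactly, the same
across-cell pooling used for real recruitment-order measurements.

## Densities and perturbation summaries

Puncta density divides the per-frame count of puncta whose centroid falls in
the cell-footprint mask by the footprint area (`|mask| · pixel_size²`).  For
recorded movies without a mask, the default footprint is an Otsu threshold
of the temporal mean image, morphologically closed (radius 5 px); for
synthetic fields, which have no cell boundary, the footprint is the whole
field.  Pre/post summaries average density over `[t−30 s, t)` and
`(t, t+90 s]` by default, mirroring the acute-shock acquisition protocol;
drug-style comparisons with an incubation gap are handled as two separate
acquisitions (two traces), never as one continuous recording.  Shock
response curves divide each cell by its pre-shock baseline mean and take the
point-wise median across cells, with zero-baseline cells excluded and
flagged.

## Statistics

Normality is screened per group with a one-sample KS test against a normal
with the *sample's* mean and sd — a Lilliefors-style shortcut whose nominal
p-values are approximate; it is used only as a gate, not reported as an
exact test.  The F-test on the variance ratio (two-sided, from the F
distribution) is recorded but does not change the test choice.  Unpaired
comparisons use Mann–Whitney U; paired ones use the paired *t* when both
groups pass the gate and Wilcoxon matched-pairs otherwise, with both paired
results retained in the record.  All-zero paired differences are reported as
degenerate with p = 1 rather than an error.  The unpaired branch's type-I
error is calibrated: 4–6% rejections at α = 0.05 over 2000 null simulations.
Box summaries use linear-interpolation quartiles and min/max whiskers.

## Problem sizes and determinism

Tests and the acceptance script run on 96–192 px fields with 12–120 frames
— large enough for several hundred events/ROIs per condition while keeping
a full run to minutes on one CPU; the defaults above are used unchanged
wherever a condition's value matters.  All randomness flows through numpy
`SeedSequence` children of a single seed: identical configurations produce
byte-identical movies, tables and manifests (timestamps are kept out of all
outputs; the config hash excludes the output directory).

## Known limitations

- No frame-to-frame linking: per-event lifetimes and dwell times are out of
  scope; ROIs aggregate all events at a site.
- Merged near-neighbor puncta are counted once (see above).
- The spatial CCF is 1-D (x by default; y available); a full 2-D profile is
  exposed only through calling both axes.
- The Otsu footprint is a heuristic; for quantitative density work on real
  cells, supply a curated mask.
- OME-TIFF support covers physical pixel size and time increment; multi-
  sample or multi-channel files must be split per channel upstream.
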
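# punctakit

Quantitative analysis of two-channel fluorescence time-lapse movies of
diffraction-limited **puncta** — the spot-like structures formed at the plasma
membrane by endocytic proteins (clathrin, dynamin-2 and their partners) during
clathrin-mediated endocytosis.  The package answers the questions such movies
are recorded for: *do two proteins occupy the same structures?* and *which one
is recruited first, and by how much?* — plus *how does puncta density respond
to a perturbation?*  Because raw imaging data of this kind is rarely shared,
punctakit includes a synthetic movie generator with full ground truth, so
every analysis is testable end to end with no external data.

Intended users are cell biologists and image analysts working with
single-plane spinning-disk/TIRF movies (one channel per file, pixel size
~0.13–0.22 µm, frame interval ~1 s).

## Methods at a glance

**Spot detection (à trous wavelet).**  Each frame is decomposed with the
undecimated B3-spline wavelet transform: iterated smoothing with the kernel
`[1,4,6,4,1]/16`, dilated by inserting `2^(j−1) − 1` zeros at scale *j*, with
detail planes `w_j = c_{j−1} − c_j` so that `frame = c_J + Σ_j w_j` exactly.
Puncta-scale structure lives in planes 2–3; a pixel is significant at scale
*j* when `w_j > k·σ_j` with `σ_j = MAD(w_j)/0.6745` and `k = 3` by default.
The AND of the selected planes is the binary **wavelet mask**; its
8-connected components (≥ 4 px) are the detected puncta, with
intensity-weighted centroids from the raw frame.

**Colocalization.**  For two detected channels, the AND of the masks is the
"overlap" image and the OR the "sum" image; the **overlap percentage** is
`100·|A∧B| / |A∨B|`.  The **spatial cross-correlation** profile is the
Pearson correlation of the wavelet-denoised channels as a function of an
integer lateral pixel shift: coincident structures peak at shift 0.

**Recruitment kinetics.**  Pixels ever significant in *both* channels define
"island-like" ROIs (8-connected components of the AND of the temporal
occupancy projections).  Per ROI, mean raw intensities give a two-channel
trace, and the normalized **temporal cross-correlation**

    r(τ) = (1/N_τ) Σ_t  ẑ_ref(t) · ẑ_query(t+τ),   τ ∈ [−max_lag, +max_lag]

(ẑ = globally z-scored trace) is aggregated across ROIs as mean ± s.e.m.
A peak at **positive lag means the reference channel is recruited first**.
Puncta density is reported as **dots/µm²** of cell footprint, with pre/post
window means (30 s / 90 s by default) and baseline-normalized median curves
for acute perturbations such as hyperosmotic shock.

**Statistics.**  Group comparisons follow a normality-gated flow:
Kolmogorov–Smirnov per group and an F-test for variances are recorded;
unpaired data gets Mann–Whitney U, paired data a paired *t*-test when both
groups pass normality and the Wilcoxon matched-pair signed-rank test
otherwise.  Significance codes: ns (p>0.05), \*, \*\*, \*\*\* at 0.05, 0.01,
0.001.

## Worked example

Simulate one fully coupled acquisition (channel B delayed by +1 s relative
to channel A), run the whole pipeline, and read the headline numbers:

```python
import punctakit as pk

cfg = pk.RunConfig(
    simulation=pk.SimulationParams(seed=8, coloc_fraction=1.0, lag_s=1.0,
                                   field_height_px=128, field_width_px=128),
    out_dir="demo_run", seed=8,
)
run_dir = pk.run_pipeline(cfg)
print((run_dir / "manifest.json").read_text())
```

The manifest reports, among others:

```
"overlap_percent":            82.6     # AND/OR overlap of the two mask stacks
"spatial_ccf_peak_shift_px":  0        # channels coincide laterally
"peak_lag_s":                 1.0      # reference (A) leads by 1 s, as programmed
"n_rois":                     43
"mean_density_A_per_um2":     0.0433   # ~0.05 dots/µm² steady-state regime
```

`overlap_percent ≈ 80` because every A-punctum has a B-partner; at a coupling
fraction of 0.5 the same readout drops to ~32 %, and to ~1 % for uncoupled
channels (see `analysis/03_colocalization.py`).  `peak_lag_s = 1.0` recovers
the programmed recruitment delay with the reference-leads-positive sign
convention.

The same steps run from the shell:

```bash
punctakit simulate --seed 8 --coloc-fraction 1.0 --lag-s 1.0 --out sim
punctakit kinetics sim/movie_A.tif sim/movie_B.tif --out lag_profile.csv
# → peak lag +1.00 s over 43 ROIs
```

The numbered scripts under `analysis/` rerun the full study on synthetic
data — detection benchmarking, overlap dose–response, lag recovery across
programmed delays, shock-response density kinetics and the statistics — each
printing what it found and writing tables under `results/`.

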
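# Methods

`embryoqpi` implements a label-free computational pipeline for grading
pre-implantation (day-5 mouse) embryo health from quantitative-phase
z-stacks: 3D nucleus instance segmentation of a nucleus-channel volume,
per-nucleus dry-mass and shape features, a scattering-spectrum bandwidth
biomarker of the nucleus arrangement, and a small neural classifier with
max-voting aggregation. This note records the models, the assumptions,
the numerical choices and the limits of what the synthetic tests show.

## Dry mass from phase

Quantitative phase imaging measures the optical path-length delay
φ(**r**) (radians) through the sample. Because the refractive index of
biological material rises linearly with the concentration of non-aqueous
material (protein/DNA), the dry mass of a region is proportional to the
integrated phase:

    M = λ / (2πγ) ∫ φ(r) d³r        [pg]

with λ the illumination wavelength (default 0.488 µm) and γ the
refractive-index increment expressed in µm³/pg. Discretely, the integral
is Σφ·v_voxel with v_voxel in µm³. Dry-mass density is ρ = M/V with V
the segmented nucleus volume; ρ = M/V holds exactly in every record (no
recomputation drift). γ is not a measured quantity here; the default
0.2 µm³/pg is the standard protein value (0.2 ml/g) and is exposed in
the configuration. Absolute densities therefore carry a γ-scale
uncertainty; all class comparisons are ratio-based and unaffected.

## Phase reconstruction (GLIM)

A gradient light interference microscope records four intensity frames
per field at modulator shifts nπ/2: I_n = A + B·cos(φ_g + nπ/2), where
φ_g is the phase *gradient* along the DIC shear axis. The gradient is
recovered as atan2(I₃−I₁, I₀−I₂) ∈ (−π, π]; pixels with zero modulation
(all four frames equal) are defined as gradient 0 and flagged. The phase
image is obtained by spectral inverse differentiation along the shear
axis: divide the 1-D spectrum by i·2πu with the DC term zeroed, and
reintegrate the per-line mean gradient — which the spectral division
cannot represent — as an explicit linear ramp. Output phase is defined
up to a constant and is mean-centred. Periodic wrap-around at line edges
is inherent to the spectral route; no background or halo correction is
attempted. The shear axis and a gradient sign flip are configuration
options (the acquisition geometry fixes them in practice).

## 3D nucleus segmentation

Segmentation is a two-step procedure operating on the nucleus-channel
stack (a fluorescence stain or the output of a nucleus-prediction
network).

**Per z-section (2D).** Median filter (19 px window at the reference
calibration, edge-replicated), min-max normalization to [0,1], then a
conjunction of a hard threshold (0.2) and an adaptive local-mean
threshold: foreground iff value > 0.2 and value > local mean × (1 +
(0.5 − sensitivity)), sensitivity 0.55 over a 145 px window (local mean
by edge-replicated uniform filter). The adaptive factor convention makes
higher sensitivity admit more foreground. Cleanup: opening with a 3×3
disk (smallest symmetric element), removal of components below 400 px²,
watershed seeded at Euclidean-distance-transform maxima (minimum peak
separation 30 px, raster-order tie-break), then removal of objects that
are *both* under 60 px equivalent diameter *and* under 0.8 solidity —
read as a conjunction because the filter targets over-segmentation
artifacts, and a pure diameter cut would delete genuine polar
cross-sections of ~5 µm nuclei.

Two numerical guards are ours: (a) a slice whose post-median dynamic
range is below 20% of the volume-wide range is flagged empty —
otherwise per-slice min-max normalization amplifies pure-noise sections
above the hard threshold; the 20% sits an order of magnitude above the
post-median noise range and far below any slice with real signal.
(b) `segment_stack` runs the median filter through a histogram-based
rank filter on the stack quantized to 8 bits over the volume range
(~0.4% amplitude quantization, well under the 0.2 threshold scale); the
float median remains available (`exact=True`) and is the per-slice
contract.

**Linking (3D).** Per-slice centroids are linked along z greedily in
order of increasing distance (ties to the lower trajectory id), within a
50 px radius; z-gaps up to 5 µm are bridged (bridged sections stay
background — volumes are unaffected), larger gaps start a new nucleus.
Trajectories containing two nuclei stacked along z are split at
plateau-aware strict local minima of the dense per-z area profile
(bridged gaps contribute zero area) when the minimum is below 0.6× the
smaller flanking maximum AND either (i) the minimum is a zero-area gap —
the nuclei are physically separated — or (ii) the distance-from-first-
centroid profile shows a transition: a local extremum within ±1 slice,
or a boundary increment exceeding twice the median increment elsewhere.
The step detector matters because the centroid hop between two stacked
nuclei is a monotone step, not an extremum. Cuts are applied at every
accepted minimum; parts shorter than the minimum z-depth are *kept* and
left to the downstream depth filter — rejecting such cuts lets a chained
single-slice stray detection drag a genuine nucleus below the extent
filter. Splitting recurses, so several stacked nuclei separate in one
pass.

Surviving trajectories are painted into a 3D label volume, ordered by
first z-appearance (so the maximum-value z-projection is a nucleus count
map whose global maximum equals the nucleus count), and filtered in the
anisotropic pixel domain: volume within [5000, 250000] voxels, z-depth
≥ 3 sections, extent (volume / bounding-box volume) ≥ 0.14. The three
filters commute. Finally the volume is resampled to isotropic physical
space: the z-axis is upsampled by lateral_px_per_µm × z_step_µm (11 at
the reference calibration) with the pixel-centre convention (an
n-section stack yields round(n·f) sections; output section j samples
position (j+0.5)/f − 0.5), labels nearest-neighbour (label set
preserved), phase linearly.

All pixel-domain parameters above are tied to the reference calibration
of 11 px/µm and 1 µm z-step; `Seg2DParams.scaled()` /
`Link3DParams.scaled()` rescale lengths by s = px_per_µm/11, areas by
s², voxel counts by s²·(1 µm/z-step), leaving thresholds, sensitivities
and physical (µm) parameters untouched.

## Nucleus features

Computed on the isotropic volumes: V = voxel count × voxel volume; S =
area of the triangulated isosurface (marching cubes at level 0.5 of the
mask smoothed with a Gaussian of σ = 0.6 voxel); sphericity Sp =
π^{1/3}(6V)^{2/3}/S. The smoothing choice is an estimator decision: raw
binary marching cubes overestimates a digitized sphere's area by ~9%
(Sp ≈ 0.92), while σ = 0.6 gives Sp between 0.978 and 1.004 for spheres
of radius 6–40 voxels and ≈ 0.85 for a cube (exact value 0.806) —
accurate where objects are near-spherical, mildly biased for sharp
corners, which real nuclei do not have. Degenerate objects too thin for
the smoothing (e.g. one voxel) fall back to the raw binary isosurface.
Records with Sp > 1 are under-resolved or under-segmented clusters and
are excluded with a logged count.

Compartments: the embryo centre is the centroid of nucleus centroids and
the radial scale the maximum centroid distance; nuclei with normalized
radius > 0.7 are trophectoderm (TE), those at or inside 0.7 inner cell
mass (ICM) — the boundary value itself maps to ICM. A fitted sphere was
the alternative centre definition; the centroid convention is simpler
and exact on the synthetic geometry. The normalized dry-mass-density map
sets each nucleus voxel to its mean ρ, blurs with σ = (1,1,3) voxels in
(x,y,z) and normalizes by the volume maximum.

## Scattering-spectrum bandwidth (bw3dB)

The nucleus arrangement is modelled as identical repeating units:
F(r) = F₀(r) ∗ Σₙ δ(r−rₙ), whose Fourier transform factorizes into a
form function (one unit) times the structure function S(q) = Σₙ
exp(i rₙ·q). Replacing every nucleus by a unit-radius sphere (here: the
centre voxel plus its 6 face neighbours) removes size/shape variability,
leaving only the spatial arrangement. The model volume is a 256³ grid:
the lateral axes are downsized so the field of view fills the grid,
while the z-axis keeps the 1 µm acquisition pitch and is zero-padded to
256 — this samples the low radial frequencies finely along k_z. The
padding is load-bearing: with an isotropic mapping the radial shell
width (k_max/255) is *smaller* than the k-grid spacing 2π/extent, the
first shells contain no frequency samples, and the bandwidth degenerates
to the constant 0.5·k_max/255 for every embryo.

The unnormalized 3D FFT power |F(q)|² is shell-averaged into 256 radial
|k| levels (DC alone in bin 0; membership by half-open interval), in
physical units rad·µm⁻¹ via per-axis 2π·fftfreq(n, d=spacing). bw3dB is
the smallest k past the peak at which the power first falls to 50% of
its peak, linearly interpolated between the straddling bins; if the
power never crosses half-peak, the maximum k is reported with a flag.
The FFT normalization convention does not affect bw3dB (a ratio
statistic). Few, compactly arranged nuclei (growth-arrested embryos)
spread power over a wider band than many dispersed nuclei (expanded
blastocysts): in paired synthetic arrangements with equal counts, the
compact one yields the larger bandwidth in 20/20 seeds.

## Health grading (feature-based model)

Per-nucleus feature vector, in frozen order: (bw3dB, nucleus count,
dry-mass density, surface area, sphericity) — the first two are
embryo-level and repeat across an embryo's rows. The classifier is a
fully connected 5→10→2→2 network, ReLU hidden activations, softmax
output, trained full-batch with L-BFGS on cross-entropy plus L2 (λ =
1e−6 on weights, not biases), Glorot-uniform initial weights and zero
biases. Features are z-scored with training-split statistics (applied
identically at prediction time); quasi-Newton training on raw
heterogeneous scales is ill-conditioned. Early stopping: validation
patience 20 evaluations, gradient tolerance 1e−9, relative loss
tolerance 1e−9; the returned model is the one at minimum validation
loss. Identical data, configuration and seed reproduce identical
weights. The seed is a configuration default and is never selected on
test performance.

Embryo grades come from max-voting the per-item predictions: the most
frequent class wins, the confidence probability cp is the mean
prediction score over the majority-class items, and an exact tie is
resolved to S (down-grading is the acceptable error direction) and
flagged. The sparse-subset protocol thins per-slice predictions by z
position (next kept slice ≥ step above the previous) and refuses
selections with fewer than 7 slices or spacing above 10 µm — 6 slices
are avoided because an even split can tie — unless forced.

## Statistics

Every feature is gated by a per-group Lilliefors normality test (5%
level; statsmodels' implementation, which uses the standard
approximation of the null distribution): non-normal features get
Kruskal–Wallis (0.1% level) with Dunn's pairwise z-tests (tie-corrected
rank variance) and Holm adjustment; normal features get a Levene
variance check, one-way ANOVA and pairwise t-tests with Holm. The TE vs
ICM mean-density comparison is Kruskal–Wallis at α = 1e−4. Fully tied
data short-circuits to p = 1 (the rank statistic is undefined).
Constant samples fail the normality gate by definition (p = 0,
flagged). On 1000 null simulations the gated omnibus procedure rejects
at or below the nominal level.

## Synthetic embryos: what they emulate, and what not

The generator builds three embryo classes with exact ground truth:

* **Healthy blastocyst** — 40–55 nuclei (radius 2.6–3.4 µm, mild
  ellipticity) in a 32 µm embryo: 30% on an outer TE shell (0.78–0.92
  of the embryo radius), the rest in an ICM core (≤ 0.60), TE/ICM mean
  density 0.125/0.100 pg·µm⁻³ (25% contrast), no fragmentation.
* **Intermediate blastocyst** — 24–36 nuclei, 28 µm, same structure,
  10% fragmentation.
* **Sick (growth-arrested cleavage)** — 6–14 nuclei (3–4 µm) filling a
  compact 20 µm ball, uniform density 0.12 pg·µm⁻³ (no TE/ICM
  contrast), 45% of nuclei rendered as clusters of 2–4 overlapping
  small spheres (the bimodal sphericity/volume pattern of fragmenting
  nuclei).

Per-nucleus density varies by 8% (relative s.d.). Placement is random
sequential with ≥ 2 µm surface separation; failure after bounded
retries raises a diagnostic. The phase volume is the dry-mass relation
inverted voxel-wise (φ = 2πγρ/λ), a composite field: nuclei replace —
not add to — a smooth parabolic cytoplasm blob (peak 0.04 pg·µm⁻³), so
ground-truth mass equals the phase integral over the nucleus support
exactly, plus Gaussian phase noise (0.02 rad). The nucleus channel is
density-proportional intensity with a weak cytoplasm leak (3% of peak —
nucleus-prediction outputs are specific) and relative noise 0.1 (SNR
10) by default; the segmentation-recovery benchmark runs at SNR 5.

Not emulated: optical wave propagation, speckle/halo, the DIC image
formation, chromatin texture, nucleus shape irregularity beyond
ellipsoids/fragment unions, and any distribution shift between fixed
and live embryos. Passing tests therefore demonstrate the correctness
and internal consistency of the pipeline under controlled geometry and
noise — not field performance on real micrographs.

## Problem sizes and accuracy on the synthetic cohorts

Synthetic cohorts in the tests and the reproduction script are imaged
at 4 px/µm laterally (reference: 11 px/µm) with all pixel-domain
parameters rescaled, a choice that keeps a 70-embryo cohort within
minutes on one CPU while preserving every algorithmic property; the
printed reference thresholds are unit-tested verbatim at the reference
calibration. Two quantified consequences of the 1 µm z-step conditions:
recovered per-nucleus density is biased about −6% (nuclei span ~6
z-sections; linear z-interpolation of phase against nearest-neighbour
label masks loses ~5% of boundary mass), and pipeline sphericities of
true spheres read ~0.86–0.90 (z-blockiness of the nearest-label
upsampling). Both effects are multiplicative and class-independent, so
compartment contrasts and classification are unaffected.

## Known limitations

* γ is assumed, so absolute dry masses are scale-uncertain.
* The adaptive-threshold formula reconstructs an undocumented reference
  routine; only its qualitative contract (higher sensitivity ⇒ more
  foreground) is certain.
* bw3dB values depend on the documented frequency-mapping convention;
  comparisons are only meaningful within one convention.
* The Hilbert-transform integration variant of the original instrument
  lives in prior literature; spectral inverse differentiation is the
  standard realization and is what the round-trip tests certify.
* Real nucleus-prediction volumes have structured, spatially correlated
  errors that the additive-noise channel does not reproduce.
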
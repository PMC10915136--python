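# embryoqpi

Label-free assessment of pre-implantation embryo health from
quantitative-phase z-stacks. The package is aimed at computational
imaging and embryology groups working with gradient light interference
microscopy (GLIM) or similar quantitative phase instruments, where
embryo viability must be graded without fluorescent staining.

Given a phase volume φ(**r**) (radians) and a co-registered
nucleus-channel volume (a stain or the output of a nucleus-prediction
network), the pipeline:

1. **Reconstructs phase** from four phase-shifted intensity frames
   (I_n = A + B cos(φ_g + nπ/2), n = 0..3): four-quadrant arctangent for
   the gradient, spectral integration along the shear axis.
2. **Segments nuclei in 3D** in two steps: per-z-section 2D segmentation
   (19 px median filter, hard threshold 0.2 + adaptive local-mean
   threshold at sensitivity 0.55 / window 145 px, opening, 400 px² area
   filter, distance-transform watershed, 60 px-diameter ∧ 0.8-solidity
   artifact filter), then z-trajectory linking of centroids (50 px
   radius, 5 µm gap bridging), splitting of stacked nuclei at area
   minima, 3D filters (volume ∈ [5000, 250000] vox, depth ≥ 3, extent
   ≥ 0.14) and isotropic resampling (labels nearest, phase linear).
3. **Extracts features** per nucleus: dry mass via

       M = λ/(2πγ) ∫ φ(r) d³r   [pg],

   dry-mass density ρ = M/V, volume, isosurface area, sphericity
   π^{1/3}(6V)^{2/3}/S, and a trophectoderm / inner-cell-mass (TE/ICM)
   compartment from the normalized centroid radius (TE outside 0.7).
4. **Computes the scattering-spectrum bandwidth** bw3dB: nuclei are
   replaced by unit spheres at their centroids (the structure-function
   model F(q) = F₀(q)·S(q)), a 256-point 3D FFT power spectrum is
   radially shell-averaged, and bw3dB is the spatial frequency at which
   power first drops to half its peak — compact, sparse arrangements
   (growth-arrested embryos) have wider spectra than expanded
   blastocysts.
5. **Grades health**: a 5→10→2→2 ReLU/softmax network over (bw3dB,
   nucleus count, ρ, surface area, sphericity), trained with L-BFGS on
   cross-entropy + L2 (λ = 1e−6) with validation-patience early
   stopping, classifies each nucleus as healthy/intermediate (HI) or
   sick (S); max-voting aggregates nuclei to an embryo grade with a
   confidence probability. A sparse z-subset protocol (≥ 7 slices,
   ≤ 10 µm spacing) grades from reduced scans.

A synthetic-embryo generator with exact ground truth (blastocysts with
TE/ICM density contrast, growth-arrested embryos with fragmented
nuclei), image-similarity metrics (PSNR, MS-SSIM, Pearson loss, the
weighted combination 2·L1 + 1·(1−MS-SSIM) + 0.5·(1−r)²) and a
normality-gated statistics pipeline (Lilliefors → Kruskal–Wallis/Dunn-
Holm or Levene/ANOVA/t-Holm) round out the toolkit. See
`docs/methods.md` for models, assumptions and limitations.

## Worked example

```python
import embryoqpi as eq

config = eq.default_config("blastocyst_healthy", seed=7, lateral_px_per_um=4.0)
phase, nucleus_channel, truth = eq.generate_embryo(config)

pipeline = eq.PipelineConfig(lateral_px_per_um=4.0)
result = eq.process_embryo(phase, nucleus_channel, pipeline)

rec = result.records
print(f"recovered nuclei: {result.nuc_count} (truth: {len(truth)})")
print(f"bw3dB: {result.bw3db:.4f} rad/um")
print(f"mean nuclear dry mass: {rec.dry_mass_pg.mean():.1f} pg")
te, icm = rec[rec.compartment == "TE"], rec[rec.compartment == "ICM"]
print(f"TE mean density {te.dmd_pg_um3.mean():.4f} vs ICM {icm.dmd_pg_um3.mean():.4f}")
print(f"TE vs ICM Kruskal-Wallis p = {eq.te_icm_test(rec).omnibus_p:.2e}")
```

prints

```
recovered nuclei: 40 (truth: 40)
bw3dB: 0.0946 rad/um
mean nuclear dry mass: 11.3 pg
TE mean density 0.1159 vs ICM 0.0941
TE vs ICM Kruskal-Wallis p = 4.64e-05
```

All 40 nuclei of this simulated blastocyst are recovered; the
trophectoderm shell reads ~23% denser than the inner cell mass (the
configured contrast is 25%), already significant at the nucleus counts
of a single embryo. Dry masses of ~11 pg per nucleus follow from the
configured densities and nuclear volumes of ~110 µm³.

The same stages are available from the shell:

```
embryoqpi simulate --embryo-class blastocyst_healthy --seed 7 --out sim/
embryoqpi segment sim/nucleus.tif sim/phase.tif
embryoqpi train-fbm features.csv --out model.json
embryoqpi grade features.csv model.json
```

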
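# y90pet

Segmentation-aware voxel dosimetry for ⁹⁰Y microsphere radioembolization,
built around post-therapy ⁹⁰Y PET.

After radioembolization of liver tumors, the microspheres stay trapped in
the tumor microvasculature, so the ⁹⁰Y PET activity-concentration image
determines the absorbed-dose (AD) distribution up to physical decay. How
the tumor is contoured — on anatomy (morphologic segmentation, MS) or on
the emission image itself (PET-based gradient segmentation, PS) — changes
the reported dose-volume-histogram (DVH) metrics. This package provides the
full simulation-and-analysis loop to quantify that effect:

- **Synthetic ⁹⁰Y-PET cases** (`y90pet.synthetic`): liver phantoms with
  8/16/29/60 cm³ lesions at tumor-to-background ratios (TBR) ≈ 5–6, a 5-mm
  FWHM Gaussian resolution blur on a 4.07 × 4.07 × 3 mm grid, and correlated
  signal-dependent noise; plus patient-like cohorts (lesion volumes
  2–818 cm³, partial perfusion, necrotic rims, residual mis-registration of
  the morphologic mask).
- **Gradient-based segmentation** (`y90pet.segmentation`): a semi-automatic
  ray/ellipsoid-initialized edge detector. Dense rays from the lesion seed
  stop at the most negative outward directional derivative; the radii are
  median-regularized over angular neighbors and the star-convex surface is
  voxelized. A percent-of-max threshold method is included as the classical
  comparator.
- **Dosimetry** (`y90pet.dosimetry`): local energy deposition for trapped
  microspheres, `D [Gy] = C/ρ · Δ/λ` with Δ the mean β energy per decay
  (0.9267 MeV) and λ = ln 2 / 64.1 h; an optional radial dose-kernel
  convolution bounds cross-voxel β transport.
- **Metrics** (`y90pet.metrics`): DVH quantiles D70/D90, the
  linear-quadratic biologically effective dose
  `BEDᵢ = Dᵢ + Dᵢ²/(α/β) · λ/(λ+μ)` (α/β = 10 Gy, μ = 0.462/h), EUD/EUBED
  with α = 0.004/Gy, Dice similarity coefficient (DSC) and mean distance to
  agreement (MDA).
- **Statistics** (`y90pet.stats`): Pearson r, Lin's concordance correlation
  coefficient, and patient-level cluster-bootstrap confidence intervals for
  lesion-level paired differences.
- **Pipeline** (`y90pet.pipeline`): case → dose → two PS realizations
  (the second from a 2-mm jittered initialization, an intra-observer
  variability proxy) → per-lesion metrics and cohort statistics, with the
  exclusion rules (< 2 cm³, < 5 Gy mean AD) applied on MS.

## Worked example

```python
import y90pet as yp

suite = yp.make_phantom_suite(seed=1)          # three bench phantoms
case = suite[2]                                # 8/16/29 cm³ lesion set
res = yp.run_case(case, yp.PipelineConfig(), seed=13)
for r in res:
    print(f"{r.lesion_id:9s} MS {r.ms_metrics.volume_cm3:5.1f} cm³ "
          f"PS {r.ps1_metrics.volume_cm3:5.1f} cm³  "
          f"DSC {r.concordance.dsc:.3f}  MDA {r.concordance.mda_mm:.2f} mm  "
          f"Dmean {r.ms_metrics.mean_gy:5.1f}->{r.ps1_metrics.mean_gy:5.1f} Gy")
```

prints

```
sphere8   MS   8.1 cm³ PS   7.5 cm³  DSC 0.962  MDA 0.33 mm  Dmean 446.5->455.8 Gy
sphere16  MS  16.0 cm³ PS  15.5 cm³  DSC 0.983  MDA 0.13 mm  Dmean 578.8->583.7 Gy
ovoid29   MS  28.5 cm³ PS  27.8 cm³  DSC 0.987  MDA 0.18 mm  Dmean 493.3->496.6 Gy
```

i.e. on phantoms the gradient contour recovers each lesion volume within a
few percent, overlaps the morphologic truth at DSC > 0.96, and shifts the
mean absorbed dose by only a few Gy. On patient-like cohorts
(`yp.make_patient_cohort`) the agreement degrades in the characteristic
pattern: concordance is best for the mean dose and worsens toward D70 and
D90, because the PET contour conforms to the activity while the anatomy
contour does not.

A thin CLI mirrors the library: `y90pet simulate`, `y90pet segment
gradient|threshold`, `y90pet dose`, `y90pet metrics`, `y90pet compare`,
`y90pet run`, `y90pet run-phantom-acceptance` (see `--help`).

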
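# lc3d — 3D lamina cribrosa morphometry from OCT optic-disc cube scans

The lamina cribrosa (LC) is the porous collagenous plate at the optic nerve
head through which retinal ganglion cell axons exit the eye; its deformation
and thinning are central to glaucomatous damage, and normal-tension glaucoma
in particular. Swept-source OCT can image the LC in depth, but measuring its
thickness requires (i) reslicing the cube scan into radial B-scans around
Bruch's membrane opening (BMO), (ii) reconstructing the anterior and
posterior LC borders from sparse manual marks, and (iii) restricting the
measurement to the region where vessel shadows do not obscure the borders.

`lc3d` implements that measurement pipeline for researchers working with
optic-disc cube scans (3 × 3 mm, 2.6 mm depth, 256 B-scans by default):

- **Reslicing** — pseudo-radial B-scans at angles θ = 0, Δθ, …, π − Δθ
  (Δθ = 15° gives 12 images) through the BMO center, and en-face slices
  motion-averaged over a 5-plane z window.
- **Surface reconstruction** — per radial half-axis *i* (θᵢ = i·Δθ,
  i = 0…M−1), the operator's (r, z) border marks (≥ 4 points including both
  terminals) are interpolated by a cubic spline in r; each curve is resampled
  at rᵢⱼ = j·terminal(i)/N (j = 0…N), and for each j the ring of
  zᵢⱼ values is closed with (r_Mj, z_Mj) = (r_0j, z_0j) and interpolated by a
  periodic cubic spline in θ. Defaults M = 24, N = 140.
- **Reliable region and avgLCT** — the per-axis reliable limits are joined
  into a closed periodic-spline boundary, extruded along z and intersected
  with the model; thickness is posterior-minus-anterior depth per polar node,
  and the average LC thickness (avgLCT) is the area-weighted mean
  (polar element r·Δr·Δθ) over the masked nodes. The same closed-curve
  machinery yields the reliable area, BMO area and their ratio.
- **Statistics** — intrasession coefficient of variation, Kruskal–Wallis with
  Steel–Dwass all-pairs follow-up, chi-square (sex), Spearman and
  age-corrected partial Spearman correlation, ROC/AUC with the Youden-index
  cutoff.
- **Phantom** — a synthetic optic-disc generator (LC slab with pores, vessel
  shadows, speckle) with analytic ground truth, truth-derived annotation
  sets, and a dense-grid brute-force thickness oracle for validation.

## Worked example

Render a 64³ phantom (flat 250 µm LC slab, 860 µm BMO radius) with
truth-derived annotations, then measure it:

```sh
$ lc3d phantom --preset fast --seed 1 --out-volume v.tif --out-annotations a.json
phantom written to v.tif (checksum a917abf8f8e4)

$ lc3d thickness --annotations a.json --out out/
{
 "avg_lct_um": 250.00000000000003,
 "unweighted_avg_lct_um": 250.0,
 "reliable_area_mm2": 1.043015159087018,
 "bmo_area_mm2": 2.323491109572328,
 "area_ratio_pct": 44.89,
 "M": 24,
 "N": 140,
 "delta_theta_deg": 14.999999999999998,
 "n_reliable_nodes": 2256,
 ...
}
```

`avg_lct_um` recovers the phantom's true 250 µm thickness exactly (the slab
is flat, so spline interpolation is exact). The reliable region (1.04 mm²)
covers 44.9% of the BMO aperture (2.32 mm²) — the phantom's default reliable
fraction emulates the roughly 45% coverage typical when vessel shadows are
excluded. `out/map.csv` holds the per-node thickness map; `--png` adds a
polar thickness-map rendering.

Other entry points: `lc3d reslice` (the 12 pseudo-radial images plus a
manifest), `lc3d enface`, `lc3d model` (the interpolated grids as JSON),
`lc3d repro` (CV across repeated markings), `lc3d cohort` (group statistics
from a per-eye CSV with columns `id, group, avgLCT_um, cpRNFLT_um, MD_dB,
age_y, sex, IOP_mmHg, refraction_D`). The same operations are available as a
library (`lc3d.run_eye`, `lc3d.run_cohort`, …).

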
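# vesselniche

Quantitative 3D analysis of the calvarial microvascular niche from
light-sheet microscopy, with companion bone μCT morphometry.

Calvarial (skull-cap) bone is vascularized by phenotypically distinct
vessels that can be resolved in cleared whole-mount samples stained for two
endothelial markers: CD31 (PECAM-1, pan-endothelial) and endomucin (Emcn,
capillaries/sinusoids). Three phenotypes are distinguished by relative
intensity — CD31ʰⁱEmcn⁻ arteries and arterioles, CD31ʰⁱEmcnʰⁱ capillaries
(the "type-H"-like subtype associated with osteoprogenitors), and
CD31ˡᵒEmcnʰⁱ capillaries and sinusoids. Skeletal progenitors (Osterix⁺ or
Gli1⁺ nuclei) cluster around specific phenotypes, and the strength of that
association — e.g. the fraction of cells within 5 μm of their nearest
CD31ʰⁱEmcnʰⁱ vessel — is the readout this package quantifies.

`vesselniche` re-implements that analysis as an open, scriptable pipeline:

* **Segmentation** — local background subtraction at a 10 μm radius,
  per-channel thresholding (Otsu default, scalar override), 26-connected
  vessel surfaces with a 10⁴ μm³ volume filter, 2× down-sampling, seeded
  "split objects" re-segmentation (10 μm seeding point diameter), and
  anisotropic Laplacian-of-Gaussian spot detection of nuclei at
  pre-measured sizes (Gli1: 5 μm lateral / 15 μm axial; Osterix: 6/18 μm).
* **Phenotyping** — CD31-sourced objects split by the presence of masked
  Emcn signal; Emcn-sourced objects co-localized with CD31 dropped (so each
  dual-positive vessel is counted once); fractional phenotype volumes.
* **Spatial statistics** — exact anisotropic Euclidean distance transforms
  (per-axis spacing, e.g. 1.3 × 1.3 × 2.5 μm voxels), sub-voxel
  cell-to-vessel surface distances ("touching" ⇒ 0 μm), proximity fractions
  at a cutoff, distance histograms, box/cylinder volumes of interest.
* **μCT morphometry** — fixed-threshold bone segmentation, shrink-wrap
  tissue volume, BV, BV/TV, iso-surface SA and SA/V, and the
  defect/contralateral bone-volume ratio in 1 mm cylindrical VOIs
  (9 μm isotropic voxels).
* **Optics QC** — Gaussian-beam light-sheet width: full 1/e² width
  2λ/(π·NA) at the waist and its divergence with lateral offset.
* **Synthetic phantoms** — tubular vessel networks of the three phenotypes
  arranged in periosteum/marrow/dura-analog layers, with progenitor nuclei
  planted at a configurable distance law to a chosen phenotype, rendered to
  multi-channel volumes with exact ground truth. Every pipeline stage is
  validated against these phantoms; no acquired data are required.

## Worked example

Generate a phantom with 28 tubes and 2,000 Osterix⁺ nuclei planted with an
exponential 5 μm affinity to dual-positive capillaries, then run the full
chain (render → segment → classify → distances) and compare with ground
truth:

```python
import vesselniche as vn
from vesselniche.spatial import fit_exponential_scale, proximity_fraction
from vesselniche.validation import (
    analyze_scene, classification_accuracy,
    ground_truth_volume_fractions, recovered_volume_fractions,
)

scene = vn.make_vessel_scene(
    extent_um=(400, 400, 200),
    n_vessels_per_layer={"periosteum": 6, "marrow": 8, "dura": 6, "transcortical": 8},
    rng_seed=11,
)
aff = vn.AffinityLaw(target_phenotype="CD31hi_EmcnHi", law="exponential", scale_um=5.0)
scene = vn.place_cells(scene, 2000, "Osterix", aff, rng_seed=11)
an = analyze_scene(scene)

print(f"classification accuracy: {classification_accuracy(an.segments, an.gt_ds, scene):.3f}")
rec, gt = recovered_volume_fractions(an.segments), ground_truth_volume_fractions(scene)
for p in rec:
    print(f"{p}: recovered fraction {rec[p]:.3f} (ground truth {gt[p]:.3f})")
print(f"fraction within 5 um: {proximity_fraction(an.records, 5.0, 'CD31hi_EmcnHi'):.3f}")
print(f"ML affinity scale: {fit_exponential_scale(an.records, 'CD31hi_EmcnHi'):.2f} um")
```

prints

```
classification accuracy: 1.000
CD31hi_EmcnNeg: recovered fraction 0.475 (ground truth 0.488)
CD31hi_EmcnHi: recovered fraction 0.214 (ground truth 0.199)
CD31lo_EmcnHi: recovered fraction 0.311 (ground truth 0.312)
fraction within 5 um: 0.636
ML affinity scale: 5.01 um
```

Every classified object received its planted phenotype, the fractional
phenotype volumes are recovered to ~1 point, the measured 5 μm proximity
fraction matches the exponential closed form 1 − e⁻¹ ≈ 0.632, and the
maximum-likelihood scale recovers the planted 5 μm.

## Command line

```sh
vesselniche run --config run.yaml        # full pipeline from one YAML config
vesselniche validate --config run.yaml   # schema + unit checks, typo suggestions
vesselniche segment vessels IMG.ome.tif --threshold otsu --out vessels.csv
vesselniche segment spots IMG.ome.tif --marker Osterix --out spots.csv
vesselniche ct morpho CT.tif --threshold 70 --voi-preset ct_parietal --out morpho.csv
vesselniche optics sheet-width --wavelength 561 --na 0.154
```

Exit codes: 0 success, 2 configuration error, 3 stage failure. Every run
writes a `manifest.json` (config snapshot, input hashes, stage timings,
object counts, seeds), and deterministic stages reproduce bit-identically
under a fixed seed.

Ground-truth tables written alongside synthetic runs: `cells.csv`
(`id,x,y,z,marker,true_distance_um`) and `vessels.csv`
(`id,phenotype,radius_um,analytic_volume_um3`), plus a lossless
`scene.json` descriptor. All public coordinates are physical micrometres in
(x, y, z) order; arrays are (z, y, x) internally.

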
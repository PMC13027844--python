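# hsifuse

Automated processing and pixel-level fusion of multimodal hyperspectral
microscopy data.

Biological tissue sections are often imaged with several complementary
spectral systems — here a near-infrared (NIR) whiskbroom scanner (260
contiguous bands, 960–1478 nm), a laser-based mid-infrared (MIR) area
scanner (3 discrete lines at 2790, 2962 and 3700 nm) and an RGB microscope.
Each modality sees different tissue chemistry: NIR reflectance separates
lipid-rich (myelinated) from water-rich tissue via CH-overtone and water
absorption bands, MIR adds strong CH-stretch/water contrast, and RGB
contributes structural detail.  No single sensor resolves every region;
a fused datacube can.  `hsifuse` implements the full chain needed to get
there reproducibly:

* **Datacube model and container I/O** — `(y, x, λ)` cubes with wavelength
  axes, modality tags, background masks and provenance, stored one-per-file
  in a fixed HDF5 layout; RGB TIFF/PNG import, wavelength CSVs.
* **Modality-specific preprocessing** — reference correction
  `R(λ) = I(λ)/I₀(λ)`; spectral despiking by a modified Z-score
  `Z = 0.6745·(d − median d)/MAD(d)` on first differences (threshold 0.125,
  window 13) with sliding-window replacement; Gaussian-blur vignette
  correction `I′ = I·mean(F)/(F + ε)` with `F = G_σ * I`; Otsu background
  masking that preserves the full cube; min–max normalization per spectrum
  or per band; and low-collinearity band selection with the successive
  projection algorithm (SPA), reducing NIR to k = 20 bands.
* **Geometric harmonization** — bilinear resizing to the MIR reference
  grid; intra-cube layer registration for area-scanned data (ORB keypoints,
  Hamming matching with cross-check and 0.75 ratio test, euclidean RANSAC);
  and cross-modal alignment maximizing the enhanced correlation coefficient
  ρ(p) = ⟨ī_r, ī_w(p)⟩ / (‖ī_r‖·‖ī_w(p)‖) over warp parameters p on a
  coarse-to-fine pyramid (invariant to affine intensity changes, hence
  usable across sensors).
* **Pixel-level fusion** — spectral concatenation of the registered cubes,
  post-merge per-band min–max normalization, and a continuous
  modality-aware spectral index that keeps every band's (modality, original
  wavelength) resolvable.
* **Segmentation and validation** — mini-batch k-means (k = 9), mean
  silhouette coefficient, spectral correlation coefficient (SCC, per-pixel
  Pearson r between original and fused spectra), joint-histogram mutual
  information (nats), and adjusted Rand index against known labels.
* **Declarative workflows** — a YAML workflow (`datasets` + ordered
  `steps`) validated all-or-nothing before execution, with content-hash
  provenance and deterministic reruns, plus a thin `hsifuse` CLI.
* **Synthetic phantom** — a fully ground-truthed three-modality phantom
  (9 tissue classes: grey blobs, white-matter tracts, CSF cavities) with
  realistic degradations (misalignment, vignetting, spikes, noise, lamp
  spectrum), so every stage is testable without any external data.

## Worked example

```python
from hsifuse import (generate_phantom, phantom_reference,
                     run_default_pipeline, truth_metrics)

nir, mir, rgb, truth = generate_phantom(seed=42, scale=0.2)
result = run_default_pipeline(nir, mir, rgb, phantom_reference(truth), seed=42)

m = result["metrics"]
for name, r in m["scc_per_modality"].items():
    print(f"SCC({name}, fused) = {r:.4f}")
print(f"mean silhouette (fused, k=9) = {m['silhouette_mean']:.4f}")
score = truth_metrics(truth, result["clusters"], result["transforms"])
print(f"ARI vs ground truth = {score['ari']:.4f}")
print(f"classes detected = {score['n_detected']}/9")
```

prints

```
SCC(NIR, fused) = 0.9997
SCC(MIR, fused) = 0.9996
SCC(RGB, fused) = 1.0000
mean silhouette (fused, k=9) = 0.6547
ARI vs ground truth = 0.9962
classes detected = 9/9
```

The SCC values say the fused cube preserves each modality's spectral
shapes almost perfectly; the ARI and the 9/9 detection say the clustering
of the fused cube recovers the true tissue partition, including classes
that are degenerate in every single modality (the CSF pair is invisible to
NIR, one grey-matter pair to MIR, and RGB carries only compartment-level
color).  Running the same clustering on each registered single modality
detects strictly fewer classes.

The same pipeline can be driven from the shell:

```bash
hsifuse phantom --seed 42 --scale 0.2 --out phantom/
hsifuse run --workflow workflow.yaml --out results/
hsifuse metrics --fused results/fused.h5 --orig results/mir.h5 --json m.json
```

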
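"""Default per-modality processing chains and the end-to-end fusion run.

These functions wire the toolkit's operations into the canonical
processing matrix: NIR gets reference correction, despiking, background
masking, per-spectrum min-max normalization and SPA reduction to 20 bands;
MIR gets vignette correction, background masking, per-band normalization
and intra-cube layer registration; RGB gets vignette correction,
background masking and per-band normalization.  NIR and RGB are then
resized to the MIR grid and ECC-aligned onto it, all modalities are fused
by spectral concatenation, and the fused cube is segmented with mini-batch
k-means (k = 9).
"""

from __future__ import annotations

from typing import Any

import numpy as np

from .analysis import (
    ClusterResult,
    minibatch_kmeans,
    mutual_information,
    silhouette_mean,
    spectral_correlation,
)
from .datacube import DataCube, Modality, to_panchromatic
from .fusion import fuse_cubes
from .preprocess import (
    MIR_VIGNETTE_SIGMA,
    NIR_SPA_BANDS,
    RGB_VIGNETTE_SIGMA,
    ReferenceSpectrum,
    SpikeParams,
    VignetteParams,
    correct_vignette,
    minmax_normalize,
    reference_correct,
    remove_background,
    remove_spikes,
    spa_select_bands,
)
from .registration import Transform2D, align_ecc, register_layers_keypoint, resize_cube


def preprocess_nir(cube: DataCube, ref: ReferenceSpectrum,
                   spike_params: SpikeParams | None = None,
                   spa_bands: int = NIR_SPA_BANDS) -> DataCube:
    cube = reference_correct(cube, ref)
    cube = remove_spikes(cube, spike_params or SpikeParams())
    cube = remove_background(cube)
    cube = minmax_normalize(cube, per="spectrum")
    cube, _ = spa_select_bands(cube, spa_bands)
    return cube


def preprocess_mir(cube: DataCube,
                   vignette: VignetteParams | None = None,
                   layer_registration: bool = True,
                   seed: int = 0) -> DataCube:
    cube = correct_vignette(cube, vignette or VignetteParams(sigma=MIR_VIGNETTE_SIGMA))
    cube = remove_background(cube)
    cube = minmax_normalize(cube, per="band")
    if layer_registration:
        cube, _ = register_layers_keypoint(cube, reference_band=0, seed=seed)
    return cube


def preprocess_rgb(cube: DataCube,
                   vignette: VignetteParams | None = None) -> DataCube:
    cube = correct_vignette(cube, vignette or VignetteParams(sigma=RGB_VIGNETTE_SIGMA))
    cube = remove_background(cube)
    # per-spectrum scaling aligns the radiometric scale with the (also
    # per-spectrum normalized) NIR cube and keeps every pixel's channel
    # contrast well above the noise floor
    cube = minmax_normalize(cube, per="spectrum")
    return cube


def register_to_reference(cube: DataCube, reference: DataCube,
                          model: str = "euclidean") -> tuple[DataCube, Transform2D]:
    """Resize to the reference grid, then ECC-align onto it."""
    cube = resize_cube(cube, reference.data.shape[:2])
    return align_ecc(cube, reference, model=model)


def run_default_pipeline(
    nir: DataCube,
    mir: DataCube,
    rgb: DataCube,
    nir_reference: ReferenceSpectrum,
    seed: int = 0,
    k: int = 9,
    cluster_singles: bool = False,
) -> dict[str, Any]:
    """Preprocess, register, fuse and segment the three modality cubes.

    Returns the registered per-modality cubes, the fused cube, the fused
    clustering, the registration transforms, and a metrics dictionary
    (per-modality SCC against the fused cube, silhouette of the fused
    clustering, MI of each modality's panchromatic image against the
    fused one).  With ``cluster_singles`` the registered single-modality
    cubes are segmented too (same k and seed) for comparison.
    """
    nir_p = preprocess_nir(nir, nir_reference)
    mir_p = preprocess_mir(mir, seed=seed)
    rgb_p = preprocess_rgb(rgb)

    nir_r, t_nir = register_to_reference(nir_p, mir_p)
    rgb_r, t_rgb = register_to_reference(rgb_p, mir_p)

    fused = fuse_cubes([nir_r, mir_p, rgb_r])
    clusters = minibatch_kmeans(fused, k=k, seed=seed)

    registered = {"NIR": nir_r, "MIR": mir_p, "RGB": rgb_r}
    scc = {name: spectral_correlation(cube, fused, name)
           for name, cube in registered.items()}
    fg = fused.foreground()
    sil = silhouette_mean(fused.data[fg].astype(np.float64),
                          clusters.labels[fg], seed=seed)
    pan_fused = to_panchromatic(fused)
    mi = {f"({name}, FUSED)": mutual_information(to_panchromatic(cube), pan_fused)
          for name, cube in registered.items()}

    out: dict[str, Any] = {
        "registered": registered,
        "fused": fused,
        "clusters": clusters,
        "transforms": {"NIR": t_nir, "RGB": t_rgb},
        "metrics": {"scc_per_modality": scc, "silhouette_mean": sil,
                    "mi_pairs": mi},
    }
    if cluster_singles:
        out["single_clusters"] = {
            name: minibatch_kmeans(cube, k=k, seed=seed)
            for name, cube in registered.items()
        }
    return out
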
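"""Pixel-level multimodal fusion.

Registered cubes are concatenated along the spectral axis in a canonical
NIR, MIR, RGB order; a post-merge per-band min-max normalization harmonizes
the scale differences of heterogeneous sensors; and the wavelength axis is
reassigned to a continuous, modality-aware spectral index (consecutive
integers, with every band's source modality and original wavelength in nm
preserved, since the physical NIR/MIR/RGB ranges overlap numerically).
"""

from __future__ import annotations

import warnings

import numpy as np

from .datacube import DataCube, Modality, WavelengthAxis
from .errors import DimensionError, ParameterError


def reassign_wavelengths(axis_list: list[WavelengthAxis]) -> WavelengthAxis:
    """Build the fused modality-aware spectral index.

    The fused axis values are consecutive integer indices ``0..B-1`` in
    concatenation order; each index keeps its (modality, original
    wavelength nm) pair, so the mapping is lossless.
    """
    if not axis_list:
        raise ParameterError("at least one wavelength axis required")
    tags: list[str] = []
    originals: list[np.ndarray] = []
    for axis in axis_list:
        tags.extend(axis.band_modality)
        originals.append(axis.band_original_wavelength_nm)
    total = len(tags)
    return WavelengthAxis(
        np.arange(total, dtype=np.float64),
        tuple(tags),
        np.concatenate(originals),
    )


def fuse_cubes(cubes: list[DataCube], normalize: str = "band") -> DataCube:
    """Concatenate registered cubes along the spectral axis.

    All cubes must share identical spatial dims and sit on the common
    reference grid.  Post-merge min-max normalization (per band by default,
    per spectrum if requested) harmonizes sensor scales; the output is a
    FUSED cube whose background mask is the logical OR of the inputs'.
    """
    if len(cubes) < 2:
        raise ParameterError("fusion needs at least 2 cubes")
    shape = cubes[0].data.shape[:2]
    for i, cube in enumerate(cubes):
        if cube.data.shape[:2] != shape:
            raise DimensionError(
                f"cube {i} ({cube.modality.value}) spatial shape "
                f"{cube.data.shape[:2]} does not match reference {shape}")
    tags = [c.modality.value for c in cubes]
    if len(set(tags)) != len(tags):
        warnings.warn(f"duplicate modality tags in fusion inputs: {tags}")

    data = np.concatenate([c.data for c in cubes], axis=2).astype(np.float64)
    if normalize == "band":
        lo = data.min(axis=(0, 1), keepdims=True)
        hi = data.max(axis=(0, 1), keepdims=True)
    elif normalize == "spectrum":
        lo = data.min(axis=2, keepdims=True)
        hi = data.max(axis=2, keepdims=True)
    else:
        raise ParameterError(f"normalize must be 'band' or 'spectrum', got {normalize!r}")
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        data = np.where(span == 0, 0.0, (data - lo) / span)

    mask = None
    for cube in cubes:
        if cube.mask is not None:
            mask = cube.mask.copy() if mask is None else (mask | cube.mask)

    axis = reassign_wavelengths([c.wavelengths for c in cubes])
    fused = DataCube(
        data=data,
        wavelengths=axis,
        modality=Modality.FUSED,
        spatial_resolution_um=cubes[0].spatial_resolution_um,
        mask=mask,
        meta={"history": [], "fused_from": tags,
              "band_counts": [c.n_bands for c in cubes]},
    )
    fused.log_step("fuse_cubes", order=tags, normalize=normalize)
    return fused
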
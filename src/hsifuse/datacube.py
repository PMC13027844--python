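"""Core data model for hyperspectral datacubes and their container I/O.

A :class:`DataCube` is a 3-D intensity array indexed ``(row y, col x, band b)``
together with a wavelength axis, a modality tag, the spatial resolution, an
optional background mask, and a provenance record.  Axis order is pinned to
``(y, x, band)`` with the origin at the top-left and 0-based indices;
intensities are stored as 32-bit floats.

Cubes are persisted one-per-file in a fixed HDF5 layout::

    /data                          float32 (y, x, band)
    /wavelengths                   float64 (band,)
    /mask                          uint8  (y, x)      [optional]
    attrs: modality, spatial_resolution_um,
           band_modality (per-band strings),
           band_original_wavelength_nm (float64 per band),
           provenance (JSON string)

RGB images are imported from TIFF/PNG; wavelength axes from single-column
CSV files with header ``wavelength_nm``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Any

import numpy as np
import pandas as pd

from .errors import DimensionError, FormatError, ValidationError


class Modality(str, Enum):
    """Acquisition modality of a cube.

    NIR: whiskbroom near-infrared scanner (many contiguous bands).
    MIR: area-scanning mid-infrared scanner (few discrete laser lines).
    RGB: trichromatic microscope image.
    FUSED: spectral concatenation of registered modalities.
    """

    NIR = "NIR"
    MIR = "MIR"
    RGB = "RGB"
    FUSED = "FUSED"


@dataclass(frozen=True)
class WavelengthAxis:
    """Spectral axis of a cube.

    ``values`` are strictly increasing wavelengths in nm or, for FUSED cubes,
    strictly increasing integer spectral indices.  Every band additionally
    carries its source modality and its original wavelength in nm, so the
    physical axis remains resolvable after fusion reassigns indices.
    """

    values: np.ndarray
    band_modality: tuple[str, ...]
    band_original_wavelength_nm: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        orig = np.asarray(self.band_original_wavelength_nm, dtype=np.float64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "band_original_wavelength_nm", orig)
        object.__setattr__(self, "band_modality", tuple(self.band_modality))
        if values.ndim != 1:
            raise DimensionError("wavelength values must be 1-D")
        if len(values) != len(self.band_modality) or len(values) != len(orig):
            raise DimensionError(
                "wavelengths, band modalities and original wavelengths must "
                "have equal length"
            )
        if len(values) > 1 and not np.all(np.diff(values) > 0):
            raise ValidationError("wavelength values must be strictly increasing")
        if not np.all(np.isfinite(values)) or not np.all(np.isfinite(orig)):
            raise ValidationError("wavelength values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def from_values(cls, values: np.ndarray, modality: "Modality | str") -> "WavelengthAxis":
        """Build a single-modality axis where every band's original
        wavelength equals its axis value."""
        values = np.asarray(values, dtype=np.float64)
        tag = modality.value if isinstance(modality, Modality) else str(modality)
        return cls(values, (tag,) * len(values), values.copy())

    def subset(self, indices: np.ndarray) -> "WavelengthAxis":
        indices = np.asarray(indices, dtype=int)
        return WavelengthAxis(
            self.values[indices],
            tuple(self.band_modality[i] for i in indices),
            self.band_original_wavelength_nm[indices],
        )

    def band_block(self, modality: "Modality | str") -> slice:
        """Contiguous slice of bands carrying ``modality``'s tag.

        Raises :class:`LookupError` when the modality is absent and
        :class:`ValidationError` when its bands are not contiguous.
        """
        tag = modality.value if isinstance(modality, Modality) else str(modality)
        idx = [i for i, m in enumerate(self.band_modality) if m == tag]
        if not idx:
            raise LookupError(f"modality {tag!r} not present in wavelength axis")
        if idx != list(range(idx[0], idx[-1] + 1)):
            raise ValidationError(f"bands of modality {tag!r} are not contiguous")
        return slice(idx[0], idx[-1] + 1)


@dataclass
class DataCube:
    """3-D spectral image with wavelength axis, modality and provenance."""

    data: np.ndarray
    wavelengths: WavelengthAxis
    modality: Modality
    spatial_resolution_um: float
    mask: np.ndarray | None = None  # True = background
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.modality = Modality(self.modality)
        self.validate()

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise DimensionError(
                f"cube data must have exactly 3 axes (y, x, band); got {self.data.ndim}"
            )
        if self.data.shape[2] != len(self.wavelengths):
            raise DimensionError(
                f"band count {self.data.shape[2]} does not match wavelength "
                f"count {len(self.wavelengths)}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("cube intensities must be finite (no NaN/Inf)")
        if not self.spatial_resolution_um > 0:
            raise ValidationError("spatial_resolution_um must be > 0")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:2]:
                raise DimensionError(
                    f"mask shape {self.mask.shape} does not match spatial "
                    f"shape {self.data.shape[:2]}"
                )

    # -- convenience ------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def foreground(self) -> np.ndarray:
        """Boolean (y, x) map of foreground pixels (everything when no mask)."""
        if self.mask is None:
            return np.ones(self.data.shape[:2], dtype=bool)
        return ~self.mask

    def foreground_matrix(self) -> np.ndarray:
        """Foreground pixel-by-band matrix (float64)."""
        return self.data[self.foreground()].astype(np.float64)

    def with_data(self, data: np.ndarray, step: str | None = None,
                  keep_mask: bool = True, **meta: Any) -> "DataCube":
        """Copy of the cube with replaced data and a provenance entry.

        ``keep_mask=False`` drops the mask (required when the spatial shape
        changes; the caller attaches a resampled mask afterwards).
        """
        data = np.asarray(data, dtype=np.float32)
        if data.shape[:2] != self.data.shape[:2]:
            keep_mask = False
        cube = replace(
            self,
            data=data,
            mask=self.mask.copy() if (keep_mask and self.mask is not None) else None,
            meta=dict(self.meta),
        )
        if step is not None:
            cube.log_step(step, **meta)
        return cube

    def log_step(self, step: str, **params: Any) -> None:
        self.meta.setdefault("history", []).append({"step": step, **params})

    def crop(self, rows: slice, cols: slice) -> "DataCube":
        return replace(
            self,
            data=self.data[rows, cols],
            mask=None if self.mask is None else self.mask[rows, cols],
            meta=dict(self.meta),
        )


def make_datacube(
    data: np.ndarray,
    wavelengths: WavelengthAxis | np.ndarray,
    modality: Modality | str,
    spatial_resolution_um: float,
) -> DataCube:
    """Construct a validated cube with an empty mask and fresh provenance.

    ``wavelengths`` may be a plain array of nm values, in which case a
    single-modality axis is built from it.
    """
    modality = Modality(modality)
    if not isinstance(wavelengths, WavelengthAxis):
        wavelengths = WavelengthAxis.from_values(wavelengths, modality)
    return DataCube(
        data=data,
        wavelengths=wavelengths,
        modality=modality,
        spatial_resolution_um=float(spatial_resolution_um),
        mask=None,
        meta={"history": []},
    )


def to_panchromatic(cube: DataCube) -> np.ndarray:
    """Per-pixel mean over bands; the single-channel projection used as the
    registration and mutual-information operand."""
    pan = cube.data.mean(axis=2, dtype=np.float64)
    if not np.all(np.isfinite(pan)):
        raise ValidationError("panchromatic projection is not finite")
    return pan


# -- container I/O --------------------------------------------------------

_REQUIRED_DATASETS = ("data", "wavelengths")
_REQUIRED_ATTRS = (
    "modality",
    "spatial_resolution_um",
    "band_modality",
    "band_original_wavelength_nm",
)


def write_cube(cube: DataCube, path: str) -> None:
    """Write a cube to its standardized HDF5 container."""
    import h5py

    cube.validate()
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=cube.data.astype(np.float32))
        f.create_dataset("wavelengths", data=cube.wavelengths.values.astype(np.float64))
        if cube.mask is not None:
            f.create_dataset("mask", data=cube.mask.astype(np.uint8))
        f.attrs["modality"] = cube.modality.value
        f.attrs["spatial_resolution_um"] = float(cube.spatial_resolution_um)
        f.attrs["band_modality"] = [m.encode() for m in cube.wavelengths.band_modality]
        f.attrs["band_original_wavelength_nm"] = (
            cube.wavelengths.band_original_wavelength_nm.astype(np.float64)
        )
        f.attrs["provenance"] = json.dumps(cube.meta, default=str)


def read_cube(path: str) -> DataCube:
    """Read a cube from its HDF5 container, naming any missing key."""
    import h5py

    with h5py.File(path, "r") as f:
        for name in _REQUIRED_DATASETS:
            if name not in f:
                raise FormatError(f"cube container missing required dataset '/{name}'")
        for name in _REQUIRED_ATTRS:
            if name not in f.attrs:
                raise FormatError(f"cube container missing required attribute '{name}'")
        band_modality = tuple(
            m.decode() if isinstance(m, bytes) else str(m)
            for m in f.attrs["band_modality"]
        )
        axis = WavelengthAxis(
            np.asarray(f["wavelengths"], dtype=np.float64),
            band_modality,
            np.asarray(f.attrs["band_original_wavelength_nm"], dtype=np.float64),
        )
        mask = np.asarray(f["mask"], dtype=bool) if "mask" in f else None
        meta = json.loads(f.attrs["provenance"])
        return DataCube(
            data=np.asarray(f["data"], dtype=np.float32),
            wavelengths=axis,
            modality=Modality(str(f.attrs["modality"])),
            spatial_resolution_um=float(f.attrs["spatial_resolution_um"]),
            mask=mask,
            meta=meta,
        )


def read_rgb_image(path: str, spatial_resolution_um: float) -> DataCube:
    """Import a TIFF/PNG RGB image as a 3-channel cube.

    Channels are tagged R/G/B with nominal wavelengths 620/550/465 nm;
    integer images are rescaled to [0, 1].
    """
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim == 2:
        img = img[:, :, None]
    if img.ndim != 3 or img.shape[2] < 3:
        raise FormatError(f"expected an RGB image at {path}, got shape {img.shape}")
    img = img[:, :, :3].astype(np.float32)
    if img.max() > 1.0:
        img = img / np.float32(255.0 if img.max() <= 255 else 65535.0)
    # nominal channel centers; stored reversed (B, G, R) would violate the
    # strictly increasing axis, so bands are ordered B, G, R by wavelength
    axis = WavelengthAxis(
        np.array([465.0, 550.0, 620.0]),
        (Modality.RGB.value,) * 3,
        np.array([465.0, 550.0, 620.0]),
    )
    data = img[:, :, ::-1]  # R,G,B file order -> B,G,R ascending wavelength
    cube = make_datacube(data, axis, Modality.RGB, spatial_resolution_um)
    cube.log_step("read_rgb_image", path=str(path))
    return cube


def read_wavelengths_csv(path: str) -> np.ndarray:
    """Read a single-column wavelength CSV with header ``wavelength_nm``."""
    df = pd.read_csv(path)
    if "wavelength_nm" not in df.columns:
        raise FormatError(f"wavelength CSV {path} lacks a 'wavelength_nm' column")
    return df["wavelength_nm"].to_numpy(dtype=np.float64)
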
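"""Modality-specific radiometric preprocessing.

Implements the per-modality cleanup chain applied before geometric
registration and fusion: spectral reference correction (raw intensity
``I(lambda)`` to relative reflectance ``R(lambda) = I/I0``), spectral spike
removal by a modified Z-score on first differences, Gaussian-blur vignette
correction, Otsu background masking, min-max normalization, and
low-collinearity band selection with the successive projection algorithm
(SPA).

Modality defaults follow the study conditions: spike threshold 0.125 with
window 13 for NIR; vignette ``sigma=10, epsilon=5`` for MIR and
``sigma=100, epsilon=5`` for RGB; NIR reduced to k=20 bands by SPA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .datacube import DataCube, to_panchromatic
from .errors import DimensionError, ParameterError, SelectionError, ValidationError

#: Modified Z-score despiking defaults (NIR).
DEFAULT_SPIKE_THRESHOLD = 0.125
DEFAULT_SPIKE_WINDOW = 13
#: Vignette correction defaults per modality.
MIR_VIGNETTE_SIGMA = 10.0
RGB_VIGNETTE_SIGMA = 100.0
DEFAULT_VIGNETTE_EPSILON = 5.0
#: SPA band count for NIR.
NIR_SPA_BANDS = 20

_MAD_CONSTANT = 0.6745  # scales MAD to the stddev of a normal distribution


@dataclass(frozen=True)
class ReferenceSpectrum:
    """Wavelength-matched reference spectrum I0(lambda), strictly positive."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))
        if self.values.ndim != 1:
            raise DimensionError("reference spectrum must be 1-D")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValidationError("reference spectrum values must be finite and > 0")


@dataclass(frozen=True)
class SpikeParams:
    """Parameters of the modified Z-score despiking procedure."""

    threshold: float = DEFAULT_SPIKE_THRESHOLD
    window: int = DEFAULT_SPIKE_WINDOW

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ParameterError("spike threshold must be > 0")
        if self.window < 3 or self.window % 2 == 0:
            raise ParameterError("spike window must be odd and >= 3")


@dataclass(frozen=True)
class VignetteParams:
    """Parameters of the Gaussian-blur vignette correction."""

    sigma: float
    epsilon: float = DEFAULT_VIGNETTE_EPSILON

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ParameterError("vignette sigma must be > 0")
        if self.epsilon < 0:
            raise ParameterError("vignette epsilon must be >= 0")


def load_reference_csv(path: str) -> ReferenceSpectrum:
    """Load a single-column reference spectrum CSV (header row ignored)."""
    import pandas as pd

    df = pd.read_csv(path)
    return ReferenceSpectrum(df.iloc[:, 0].to_numpy(dtype=np.float64))


def reference_correct(cube: DataCube, ref: ReferenceSpectrum) -> DataCube:
    """Convert raw intensities to relative reflectance R = I / I0 bandwise."""
    if len(ref.values) != cube.n_bands:
        raise DimensionError(
            f"reference spectrum length {len(ref.values)} does not match "
            f"cube band count {cube.n_bands}"
        )
    data = cube.data / ref.values.astype(np.float32)[None, None, :]
    return cube.with_data(data, step="reference_correct")


def _modified_zscore(diffs: np.ndarray) -> np.ndarray:
    """Modified Z-score of each row of ``diffs``.

    Where a row's MAD is zero, entries away from the median get infinite
    scores (isolated spikes on otherwise flat spectra are still detected)
    and entries at the median get zero.
    """
    med = np.median(diffs, axis=-1, keepdims=True)
    dev = diffs - med
    mad = np.median(np.abs(dev), axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = _MAD_CONSTANT * dev / mad
    degenerate = np.where(dev > 0, np.inf, np.where(dev < 0, -np.inf, 0.0))
    return np.where(np.broadcast_to(mad == 0, z.shape), degenerate, z)


def remove_spikes(cube: DataCube, params: SpikeParams | None = None) -> DataCube:
    """Replace spectral spikes with the local mean of the sliding window.

    Per pixel spectrum: modified Z-scores of the first-difference series flag
    a band when either adjacent difference exceeds the threshold in absolute
    value; each flagged band is replaced by the mean of the non-flagged
    intensities inside the centered window (shrunk at the spectrum edges; if
    the window holds no non-flagged value, the window median is used).
    Non-flagged bands pass through bit-unchanged.
    """
    params = params or SpikeParams()
    if cube.n_bands <= params.window:
        raise ParameterError(
            f"band count {cube.n_bands} must exceed the window {params.window}"
        )
    ny, nx, nb = cube.shape
    spectra = cube.data.reshape(-1, nb).astype(np.float64)
    z = _modified_zscore(np.diff(spectra, axis=1))
    hot = np.abs(z) > params.threshold  # (P, nb-1)
    flagged = np.zeros((spectra.shape[0], nb), dtype=bool)
    flagged[:, 1:] |= hot
    flagged[:, :-1] |= hot

    keep = ~flagged
    kernel = np.ones(params.window)
    # windowed mean of non-flagged values, window shrunk at edges
    num = ndimage.convolve1d(spectra * keep, kernel, axis=1, mode="constant")
    cnt = ndimage.convolve1d(keep.astype(np.float64), kernel, axis=1, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        win_mean = num / cnt
    empty = cnt == 0
    if np.any(empty & flagged):
        win_median = ndimage.median_filter(
            spectra, size=(1, params.window), mode="nearest"
        )
        win_mean = np.where(empty, win_median, win_mean)
    out = np.where(flagged, win_mean, spectra).reshape(ny, nx, nb)
    result = cube.with_data(out, step="remove_spikes",
                            threshold=params.threshold, window=params.window)
    return result


def correct_vignette(cube: DataCube, params: VignetteParams) -> DataCube:
    """Divide out a per-band illumination field estimated by Gaussian blur.

    For each band ``b``: ``F_b = GaussianBlur(I_b, sigma)`` and
    ``I'_b = I_b * mean(F_b) / (F_b + epsilon)``.  The mean(F) factor keeps
    the global intensity scale; epsilon stabilizes dark regions.
    """
    if cube.shape[0] < 3 or cube.shape[1] < 3:
        raise DimensionError("vignette correction needs spatial dims >= 3x3")
    data = cube.data.astype(np.float64)
    out = np.empty_like(data)
    for b in range(cube.n_bands):
        field = ndimage.gaussian_filter(data[:, :, b], params.sigma, mode="reflect")
        denom = field + params.epsilon
        if np.any(denom <= 0):
            raise ValidationError("vignette field plus epsilon must be positive")
        out[:, :, b] = data[:, :, b] * field.mean() / denom
    return cube.with_data(out, step="correct_vignette",
                          sigma=params.sigma, epsilon=params.epsilon)


def remove_background(cube: DataCube) -> DataCube:
    """Mask background by an Otsu threshold on the panchromatic projection.

    Pixels below the threshold are marked background.  Spectra are left
    untouched (the full datacube is preserved); the mask is carried to all
    downstream steps, which restrict metrics and band selection to the
    foreground.  A degenerate histogram (all pixels on one side) records a
    warning and leaves the mask empty.
    """
    pan = to_panchromatic(cube)
    out = cube.with_data(cube.data, step="remove_background")
    if np.ptp(pan) == 0:
        warnings.warn("background removal: uniform image, mask left empty")
        out.mask = np.zeros(pan.shape, dtype=bool)
        out.meta["background_warning"] = "uniform image"
        return out
    thresh = threshold_otsu(pan)
    mask = pan < thresh
    if mask.all() or not mask.any():
        warnings.warn("background removal: all pixels on one side of the "
                      "Otsu threshold, mask left empty")
        out.mask = np.zeros(pan.shape, dtype=bool)
        out.meta["background_warning"] = "degenerate threshold"
        return out
    out.mask = mask
    out.meta["background_threshold"] = float(thresh)
    return out


def minmax_normalize(cube: DataCube, per: str = "spectrum") -> DataCube:
    """Min-max rescale to [0, 1] per pixel spectrum or per band image.

    Constant vectors map to all-zeros; the operation is idempotent.
    """
    if per not in ("spectrum", "band"):
        raise ParameterError(f"per must be 'spectrum' or 'band', got {per!r}")
    data = cube.data.astype(np.float64)
    axis = 2 if per == "spectrum" else (0, 1)
    lo = data.min(axis=axis, keepdims=True)
    hi = data.max(axis=axis, keepdims=True)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (data - lo) / span
    out = np.where(span == 0, 0.0, out)
    return cube.with_data(out, step="minmax_normalize", per=per)


def spa_select_bands(cube: DataCube, k: int) -> tuple[DataCube, np.ndarray]:
    """Select ``k`` low-collinearity bands by successive projection.

    Greedy successive projection on the foreground pixel-by-band matrix X:
    start with the band column of maximal Euclidean norm; at each step
    project all unselected columns onto the orthogonal complement of the
    span of the selected columns and pick the column of maximal residual
    norm (ties broken by the lowest band index).  Returns the cube
    restricted to the selected bands (reported ascending) and the indices.
    """
    if k > cube.n_bands:
        raise ParameterError(f"k={k} exceeds band count {cube.n_bands}")
    if k < 1:
        raise ParameterError("k must be >= 1")
    X = cube.foreground_matrix()
    if X.shape[0] < 1:
        raise ValidationError("no foreground pixels available for band selection")

    norms2 = np.einsum("ij,ij->j", X, X)  # squared residual norms
    selected: list[int] = []
    residual2 = norms2.copy()
    basis: list[np.ndarray] = []
    tol = max(1e-12, 1e-10 * norms2.max())
    for _ in range(k):
        if residual2.max() <= tol:
            raise SelectionError(
                f"rank deficiency: only {len(selected)} of {k} bands selectable"
            )
        j = int(np.argmax(residual2))  # argmax takes the lowest index on ties
        selected.append(j)
        v = X[:, j].copy()
        for q in basis:
            v -= (q @ v) * q
        nv = np.linalg.norm(v)
        if nv <= 0:
            raise SelectionError(
                f"rank deficiency: only {len(selected) - 1} of {k} bands selectable"
            )
        q = v / nv
        basis.append(q)
        proj = X.T @ q
        residual2 = np.maximum(residual2 - proj**2, 0.0)
        residual2[selected] = 0.0

    indices = np.sort(np.asarray(selected, dtype=int))
    out = DataCube(
        data=cube.data[:, :, indices],
        wavelengths=cube.wavelengths.subset(indices),
        modality=cube.modality,
        spatial_resolution_um=cube.spatial_resolution_um,
        mask=None if cube.mask is None else cube.mask.copy(),
        meta=dict(cube.meta),
    )
    out.log_step("spa_select_bands", k=k, indices=[int(i) for i in indices])
    return out, indices
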
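"""Geometric harmonization of multimodal cubes.

Three stages bring every modality onto the reference (MIR) pixel grid:

1. :func:`resize_cube` — bilinear resampling to the reference spatial shape.
2. :func:`register_layers_keypoint` — intra-cube band alignment for
   area-scanned data (ORB keypoints, Hamming matching with cross-check and
   ratio test, euclidean RANSAC).
3. :func:`align_ecc` — cross-modal alignment maximizing the enhanced
   correlation coefficient (ECC) between zero-mean panchromatic
   projections, iterated forward-additively on a coarse-to-fine pyramid.

All transforms are :class:`Transform2D`: a 2x3 matrix mapping reference
pixel coordinates ``(x, y)`` (col, row) to moving-image coordinates.  The
ECC objective rho is invariant to affine intensity changes of either image,
which is what makes it usable across sensors with unrelated radiometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import transform as sktf
from skimage.feature import ORB, match_descriptors
from skimage.measure import ransac

from .datacube import DataCube, to_panchromatic
from .errors import (
    AlignmentError,
    DimensionError,
    ParameterError,
    RegistrationError,
    ValidationError,
)

DEFAULT_MAX_ITER = 200
DEFAULT_EPS = 1e-6
DEFAULT_PYRAMID_LEVELS = 3
RANSAC_RESIDUAL_PX = 2.0
MATCH_MAX_RATIO = 0.75
MIN_INLIER_MATCHES = 8

_MODELS = ("translation", "euclidean", "affine")


@dataclass
class Transform2D:
    """2-D warp mapping reference pixel coords (x, y) to moving-image coords."""

    model: str
    matrix: np.ndarray  # 2x3, row-major: [[a11, a12, tx], [a21, a22, ty]]
    score: float = float("nan")

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ParameterError(f"unknown warp model {self.model!r}")
        self.matrix = np.asarray(self.matrix, dtype=np.float64).reshape(2, 3)
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("transform matrix must be finite")

    @classmethod
    def identity(cls, model: str = "euclidean") -> "Transform2D":
        return cls(model, np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @classmethod
    def from_euclidean(cls, angle_rad: float, tx: float, ty: float,
                       score: float = float("nan")) -> "Transform2D":
        c, s = np.cos(angle_rad), np.sin(angle_rad)
        return cls("euclidean", np.array([[c, -s, tx], [s, c, ty]]), score)

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 2]

    @property
    def rotation_deg(self) -> float:
        """Rotation angle for (near-)euclidean transforms, degrees."""
        return float(np.degrees(np.arctan2(self.matrix[1, 0], self.matrix[0, 0])))

    def as_homogeneous(self) -> np.ndarray:
        return np.vstack([self.matrix, [0.0, 0.0, 1.0]])

    def inverse(self) -> "Transform2D":
        inv = np.linalg.inv(self.as_homogeneous())
        return Transform2D(self.model, inv[:2], self.score)

    def compose(self, other: "Transform2D") -> "Transform2D":
        """self o other: apply ``other`` first, then ``self``."""
        m = self.as_homogeneous() @ other.as_homogeneous()
        model = self.model if self.model == other.model else "affine"
        return Transform2D(model, m[:2])

    def apply_points(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=np.float64))
        return xy @ self.linear.T + self.translation

    def to_json(self) -> str:
        return json.dumps({
            "model": self.model,
            "matrix": self.matrix.ravel().tolist(),
            "score": None if np.isnan(self.score) else float(self.score),
        })

    @classmethod
    def from_json(cls, text: str) -> "Transform2D":
        d = json.loads(text)
        score = d.get("score")
        return cls(d["model"], np.asarray(d["matrix"]).reshape(2, 3),
                   float("nan") if score is None else float(score))


# -- resampling -----------------------------------------------------------

def resize_cube(cube: DataCube, target_shape: tuple[int, int]) -> DataCube:
    """Bilinearly interpolate every band to ``target_shape`` (rows, cols).

    The wavelength axis is untouched, masks are resized nearest-neighbor,
    and the nominal spatial resolution is rescaled by the mean axis ratio.
    """
    rows, cols = int(target_shape[0]), int(target_shape[1])
    if rows < 1 or cols < 1:
        raise ParameterError(f"target shape must be positive, got {target_shape}")
    if (rows, cols) == cube.data.shape[:2]:
        out = cube.with_data(cube.data.copy(), step="resize_cube",
                             target=[rows, cols])
        return out
    data = sktf.resize(cube.data, (rows, cols, cube.n_bands), order=1,
                       mode="edge", anti_aliasing=False, preserve_range=True)
    out = cube.with_data(data, step="resize_cube", target=[rows, cols])
    if cube.mask is not None:
        out.mask = sktf.resize(cube.mask.astype(np.uint8), (rows, cols), order=0,
                               mode="edge", anti_aliasing=False,
                               preserve_range=True).astype(bool)
    ratio = 0.5 * (cube.data.shape[0] / rows + cube.data.shape[1] / cols)
    out.spatial_resolution_um = cube.spatial_resolution_um * ratio
    return out


def apply_transform(cube: DataCube, t: Transform2D,
                    target_shape: tuple[int, int] | None = None) -> DataCube:
    """Resample every band through ``t`` onto the reference grid.

    ``t`` maps reference coords to moving-image coords, which is exactly the
    inverse map a backward-warping resampler needs.  Out-of-field pixels are
    set to 0 and marked background in the mask.
    """
    if abs(np.linalg.det(t.linear)) < 1e-12:
        raise ParameterError("transform matrix is singular")
    rows, cols = target_shape if target_shape is not None else cube.data.shape[:2]
    tf = sktf.AffineTransform(matrix=t.as_homogeneous())
    data = np.empty((rows, cols, cube.n_bands), dtype=np.float64)
    for b in range(cube.n_bands):
        data[:, :, b] = sktf.warp(cube.data[:, :, b].astype(np.float64), tf,
                                  output_shape=(rows, cols), order=1,
                                  mode="constant", cval=0.0, preserve_range=True)
    infield = sktf.warp(np.ones(cube.data.shape[:2]), tf,
                        output_shape=(rows, cols), order=0,
                        mode="constant", cval=0.0, preserve_range=True) > 0.5
    out = cube.with_data(data, step="apply_transform", transform=t.to_json())
    if cube.mask is not None:
        moved = sktf.warp(cube.mask.astype(np.float64), tf,
                          output_shape=(rows, cols), order=0,
                          mode="constant", cval=1.0, preserve_range=True) > 0.5
        out.mask = moved | ~infield
    else:
        out.mask = ~infield
    return out


# -- intra-cube layer registration ---------------------------------------

def _orb_keypoints(image: np.ndarray, n_keypoints: int) -> tuple[np.ndarray, np.ndarray]:
    # light presmoothing suppresses per-band noise so FAST corners land on
    # shared structure; the low threshold keeps enough corners for
    # cross-band matching where class contrast differs between bands
    smoothed = ndimage.gaussian_filter(image.astype(np.float64), 1.0)
    orb = ORB(n_keypoints=n_keypoints, fast_threshold=0.01)
    orb.detect_and_extract(smoothed)
    return orb.keypoints, orb.descriptors


def register_layers_keypoint(
    cube: DataCube,
    reference_band: int = 0,
    n_keypoints: int = 1500,
    fallback_identity: bool = False,
    seed: int = 0,
) -> tuple[DataCube, list[Transform2D]]:
    """Align every band of an area-scanned cube onto a reference band.

    Rotation-invariant binary-descriptor (ORB) keypoints are matched by
    Hamming distance with cross-check and a 0.75 ratio test; a euclidean
    transform is estimated by RANSAC (inlier threshold 2 px) and each band
    is warped onto the reference band's grid.  Bands with fewer than 8
    inlier matches raise :class:`RegistrationError` naming the band, unless
    ``fallback_identity`` keeps them unwarped.
    """
    if cube.n_bands < 2:
        raise ParameterError("layer registration needs at least 2 bands")
    if not 0 <= reference_band < cube.n_bands:
        raise ParameterError(f"reference band {reference_band} out of range")
    ref_img = cube.data[:, :, reference_band].astype(np.float64)
    try:
        ref_kp, ref_desc = _orb_keypoints(ref_img, n_keypoints)
    except RuntimeError as exc:
        raise RegistrationError(f"no keypoints on reference band: {exc}") from exc

    transforms: list[Transform2D] = []
    data = np.empty_like(cube.data, dtype=np.float64)
    for b in range(cube.n_bands):
        if b == reference_band:
            transforms.append(Transform2D.identity("euclidean"))
            data[:, :, b] = cube.data[:, :, b]
            continue
        t = _estimate_band_transform(ref_kp, ref_desc, cube.data[:, :, b],
                                     n_keypoints, b, fallback_identity, seed)
        transforms.append(t)
        tf = sktf.AffineTransform(matrix=t.as_homogeneous())
        data[:, :, b] = sktf.warp(cube.data[:, :, b].astype(np.float64), tf,
                                  order=1, mode="constant", cval=0.0,
                                  preserve_range=True)
    out = cube.with_data(data, step="register_layers_keypoint",
                         reference_band=reference_band,
                         transforms=[t.to_json() for t in transforms])
    return out, transforms


def _estimate_band_transform(ref_kp, ref_desc, band_img, n_keypoints,
                             band_index, fallback_identity, seed) -> Transform2D:
    try:
        kp, desc = _orb_keypoints(band_img.astype(np.float64), n_keypoints)
        matches = match_descriptors(ref_desc, desc, cross_check=True,
                                    max_ratio=MATCH_MAX_RATIO)
        if len(matches) < MIN_INLIER_MATCHES:
            raise RegistrationError(
                f"band {band_index}: only {len(matches)} keypoint matches")
        src = ref_kp[matches[:, 0]][:, ::-1]  # (row, col) -> (x, y)
        dst = kp[matches[:, 1]][:, ::-1]
        model, inliers = ransac((src, dst), sktf.EuclideanTransform,
                                min_samples=3,
                                residual_threshold=RANSAC_RESIDUAL_PX,
                                max_trials=1000, rng=seed)
        n_inliers = 0 if inliers is None else int(inliers.sum())
        if model is None or n_inliers < MIN_INLIER_MATCHES:
            raise RegistrationError(
                f"band {band_index}: only {n_inliers} RANSAC inlier matches")
        return Transform2D("euclidean", model.params[:2],
                           score=n_inliers / len(matches))
    except (RuntimeError, RegistrationError) as exc:
        if fallback_identity:
            return Transform2D.identity("euclidean")
        if isinstance(exc, RegistrationError):
            raise
        raise RegistrationError(f"band {band_index}: {exc}") from exc


# -- ECC cross-modal alignment -------------------------------------------

def _warp_params_to_matrix(model: str, p: np.ndarray) -> np.ndarray:
    if model == "translation":
        return np.array([[1.0, 0.0, p[0]], [0.0, 1.0, p[1]]])
    if model == "euclidean":
        c, s = np.cos(p[0]), np.sin(p[0])
        return np.array([[c, -s, p[1]], [s, c, p[2]]])
    return np.array([[1.0 + p[0], p[1], p[2]], [p[3], 1.0 + p[4], p[5]]])


def _identity_params(model: str) -> np.ndarray:
    return np.zeros({"translation": 2, "euclidean": 3, "affine": 6}[model])


def _ecc_level(ref: np.ndarray, mov: np.ndarray, model: str, p: np.ndarray,
               max_iter: int, eps: float) -> tuple[np.ndarray, float]:
    """Forward-additive ECC iterations at a single pyramid level."""
    h, w = ref.shape
    yg, xg = np.mgrid[0:h, 0:w].astype(np.float64)
    xf, yf = xg.ravel(), yg.ravel()
    gy, gx = np.gradient(mov)

    best_rho = -1.0
    best_p = p.copy()
    decreasing = 0
    stalled = 0
    for _ in range(max_iter):
        m = _warp_params_to_matrix(model, p)
        xm = m[0, 0] * xf + m[0, 1] * yf + m[0, 2]
        ym = m[1, 0] * xf + m[1, 1] * yf + m[1, 2]
        valid = (xm >= 0) & (xm <= w - 1) & (ym >= 0) & (ym <= h - 1)
        if valid.sum() < 16:
            raise AlignmentError("warp left too few pixels in field of view")
        coords = np.vstack([ym[valid], xm[valid]])
        iw = ndimage.map_coordinates(mov, coords, order=1, mode="nearest")
        gxw = ndimage.map_coordinates(gx, coords, order=1, mode="nearest")
        gyw = ndimage.map_coordinates(gy, coords, order=1, mode="nearest")
        ir = ref.ravel()[valid]

        ir = ir - ir.mean()
        iw = iw - iw.mean()
        nr, nw = np.linalg.norm(ir), np.linalg.norm(iw)
        if nr == 0 or nw == 0:
            raise ValidationError("constant image region in ECC alignment")
        rho = float(ir @ iw / (nr * nw))
        if rho > best_rho + 1e-9:
            best_rho, best_p = rho, p.copy()
            decreasing = 0
            stalled = 0
        else:
            stalled += 1
            # genuine divergence: sustained, meaningful drop below the best
            decreasing = decreasing + 1 if rho < best_rho - 1e-2 else 0
            if decreasing >= 10:
                raise AlignmentError(
                    f"ECC diverging; best correlation rho={best_rho:.4f}")
            if stalled >= 12:  # objective plateau: keep the best iterate
                break

        xv, yv = xf[valid], yf[valid]
        if model == "translation":
            cols = [gxw, gyw]
        elif model == "euclidean":
            c, s = np.cos(p[0]), np.sin(p[0])
            cols = [gxw * (-s * xv - c * yv) + gyw * (c * xv - s * yv), gxw, gyw]
        else:
            cols = [gxw * xv, gxw * yv, gxw, gyw * xv, gyw * yv, gyw]
        G = np.stack(cols, axis=1)
        G = G - G.mean(axis=0)

        GtG = G.T @ G
        try:
            GtG_inv = np.linalg.inv(GtG)
        except np.linalg.LinAlgError as exc:
            raise AlignmentError(f"singular ECC normal equations: {exc}") from exc
        Gw = G.T @ iw
        Gr = G.T @ ir
        num = nw**2 - Gw @ (GtG_inv @ Gw)
        den = ir @ iw - Gr @ (GtG_inv @ Gw)
        if den <= 0:
            raise AlignmentError(
                f"ECC cannot increase correlation (rho={best_rho:.4f}); "
                "images may be uncorrelated or the warp is outside the basin")
        lam = num / den
        err = lam * ir - iw
        dp = GtG_inv @ (G.T @ err)
        p = p + dp
        if np.linalg.norm(dp) < eps:
            if rho >= best_rho:
                best_rho, best_p = rho, p.copy()
            break
    return best_p, best_rho


def _pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    out = [img.astype(np.float64)]
    for _ in range(levels - 1):
        if min(out[-1].shape) < 32:
            break
        out.append(sktf.pyramid_reduce(out[-1], downscale=2,
                                       preserve_range=True))
    return out


def align_ecc(
    moving: DataCube,
    reference: DataCube,
    model: str = "euclidean",
    max_iter: int = DEFAULT_MAX_ITER,
    eps: float = DEFAULT_EPS,
    levels: int = DEFAULT_PYRAMID_LEVELS,
    init: Transform2D | None = None,
) -> tuple[DataCube, Transform2D]:
    """Align ``moving`` onto ``reference`` by maximizing the ECC objective.

    Both cubes must share spatial dims (resize first).  The objective
    ``rho(p)`` is the normalized correlation of the zero-mean panchromatic
    projections; parameters are refined coarse-to-fine over a pyramid and
    the single resulting transform warps every band of the moving cube.
    """
    if model not in _MODELS:
        raise ParameterError(f"unknown warp model {model!r}")
    if moving.data.shape[:2] != reference.data.shape[:2]:
        raise DimensionError(
            f"moving shape {moving.data.shape[:2]} != reference "
            f"{reference.data.shape[:2]}; resize first")
    pan_m = to_panchromatic(moving)
    pan_r = to_panchromatic(reference)
    if np.ptp(pan_m) == 0 or np.ptp(pan_r) == 0:
        raise ValidationError("constant panchromatic projection; cannot align")

    pyr_r = _pyramid(pan_r, levels)
    pyr_m = _pyramid(pan_m, levels)
    n_levels = min(len(pyr_r), len(pyr_m))

    p = _identity_params(model)
    if init is not None:
        scale = 2.0 ** (n_levels - 1)
        if model == "translation":
            p = np.array(init.translation) / scale
        elif model == "euclidean":
            p = np.array([np.radians(init.rotation_deg),
                          init.translation[0] / scale,
                          init.translation[1] / scale])
        else:
            m = init.matrix
            p = np.array([m[0, 0] - 1, m[0, 1], m[0, 2] / scale,
                          m[1, 0], m[1, 1] - 1, m[1, 2] / scale])
    rho = -1.0
    for level in range(n_levels - 1, -1, -1):
        p, rho = _ecc_level(pyr_r[level], pyr_m[level], model, p, max_iter, eps)
        if level > 0:  # promote translation to the next finer level
            if model == "translation":
                p = p * 2.0
            elif model == "euclidean":
                p = np.array([p[0], p[1] * 2.0, p[2] * 2.0])
            else:
                p = p * np.array([1, 1, 2.0, 1, 1, 2.0])
    t = Transform2D(model, _warp_params_to_matrix(model, p), score=rho)
    warped = apply_transform(moving, t, reference.data.shape[:2])
    warped.log_step("align_ecc", model=model, rho=rho)
    return warped, t
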
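"""Synthetic multimodal phantom with known ground truth.

:func:`generate_phantom` builds three co-located modality cubes (NIR, MIR,
RGB) of one synthetic tissue section, degraded the way the real
acquisitions are: per-modality downsampling to the native pixel grids,
rigid misalignment of NIR and RGB against the reference (MIR) grid,
inter-band shifts of the area-scanned MIR cube, multiplicative vignetting,
impulse spikes on the NIR spectra, additive Gaussian noise, and a
wavelength-dependent lamp spectrum distorting the raw NIR intensities (so
reference correction is exercised).  Everything injected is recorded in a
:class:`PhantomTruth` so each pipeline stage can be scored against a known
answer.

Geometry convention: a modality image samples the reference scene through
``A = M_mis o S`` (S = grid scaling, M_mis = rigid misalignment in
reference coordinates).  After resizing a modality to the reference grid,
the warp that re-aligns it is ``M_mis^{-1}``; truth stores ``M_mis``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
from scipy import ndimage
from skimage import transform as sktf

from . import phantom_constants as C
from .analysis import ClusterResult
from .datacube import DataCube, Modality, WavelengthAxis, make_datacube, write_cube
from .errors import ParameterError
from .preprocess import ReferenceSpectrum
from .registration import Transform2D


@dataclass
class PhantomTruth:
    """Everything needed to score a pipeline run on the phantom."""

    label_map: np.ndarray                      # (H, W) 0 = background, 1..9
    transforms: dict[str, Transform2D]         # NIR, RGB misalignments (M_mis)
    mir_layer_transforms: list[Transform2D]    # per-band MIR shifts
    signatures: dict[str, np.ndarray]          # modality -> (9, B) clean signatures
    reference_spectrum: np.ndarray             # NIR lamp spectrum I0
    spike_indices: np.ndarray                  # (N, 3) NIR (y, x, band)
    spike_clean_values: np.ndarray             # (N,) pre-spike raw values
    artifact_params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    scale: float = 1.0

    @property
    def n_classes(self) -> int:
        return int(self.label_map.max())

    def save(self, out_dir: str) -> None:
        """Write truth.json plus a paletted label-map PNG."""
        import imageio.v3 as iio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        iio.imwrite(out / "label_map.png", self.label_map.astype(np.uint8))
        payload = {
            "seed": self.seed,
            "scale": self.scale,
            "transforms": {k: json.loads(t.to_json())
                           for k, t in self.transforms.items()},
            "mir_layer_transforms": [json.loads(t.to_json())
                                     for t in self.mir_layer_transforms],
            "signatures": {k: v.tolist() for k, v in self.signatures.items()},
            "reference_spectrum": self.reference_spectrum.tolist(),
            "spike_indices": self.spike_indices.tolist(),
            "spike_clean_values": self.spike_clean_values.tolist(),
            "artifact_params": self.artifact_params,
        }
        (out / "truth.json").write_text(json.dumps(payload))


def _label_map(shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    labels = np.zeros(shape, dtype=np.uint8)
    for idx, (_, _, (fr, fc), (ar, ac), angle) in enumerate(C.CLASS_SHAPES, start=1):
        dy = yy - fr * h
        dx = xx - fc * w
        th = np.radians(angle)
        u = np.cos(th) * dx + np.sin(th) * dy
        v = -np.sin(th) * dx + np.cos(th) * dy
        inside = (u / (ac * w)) ** 2 + (v / (ar * h)) ** 2 <= 1.0
        labels[inside] = idx
    return labels


def _scaling_transform(native_shape, ref_shape) -> np.ndarray:
    """Homogeneous matrix mapping native (x, y) -> reference (x, y).

    Pixel-center (area) convention, matching bilinear resize: native pixel
    i covers reference coords ``(i + 0.5) * s - 0.5``, so that resizing a
    native image back to the reference grid lands exactly on the scene.
    """
    sy = ref_shape[0] / native_shape[0]
    sx = ref_shape[1] / native_shape[1]
    return np.array([
        [sx, 0.0, 0.5 * sx - 0.5],
        [0.0, sy, 0.5 * sy - 0.5],
        [0.0, 0.0, 1.0],
    ])


def _euclidean_about_center(angle_deg: float, tx: float, ty: float,
                            shape) -> Transform2D:
    """Rigid transform rotating about the image center, in (x, y) coords."""
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    th = np.radians(angle_deg)
    c, s = np.cos(th), np.sin(th)
    # x' = R (x - c) + c + t
    m = np.array([
        [c, -s, cx - c * cx + s * cy + tx],
        [s, c, cy - s * cx - c * cy + ty],
    ])
    return Transform2D("euclidean", m)


def _sample_scene(fields: np.ndarray, warp_matrix: np.ndarray,
                  out_shape: tuple[int, int], presmooth: float) -> np.ndarray:
    """Warp a stack of reference-grid fields (H, W, K) through ``warp_matrix``
    (native (x,y) -> reference (x,y)) onto a native grid, with optional
    anti-alias presmoothing for downsampling."""
    tf = sktf.AffineTransform(matrix=warp_matrix)
    out = np.empty((out_shape[0], out_shape[1], fields.shape[2]))
    for k in range(fields.shape[2]):
        f = fields[:, :, k]
        if presmooth > 0.5:
            f = ndimage.gaussian_filter(f, presmooth, mode="nearest")
        out[:, :, k] = sktf.warp(f, tf, output_shape=out_shape, order=1,
                                 mode="constant", cval=0.0, preserve_range=True)
    return out


def _vignette(shape: tuple[int, int], amplitude: float) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    r2 = ((yy - (h - 1) / 2) / (h / 2)) ** 2 + ((xx - (w - 1) / 2) / (w / 2)) ** 2
    return 1.0 - amplitude * r2 / 2.0


def generate_phantom(
    seed: int,
    scale: float = 0.2,
) -> tuple[DataCube, DataCube, DataCube, PhantomTruth]:
    """Generate the three raw modality cubes and their ground truth.

    ``scale`` shrinks the full acquisition geometry (reference grid
    1600 x 2000) uniformly; the default 0.2 gives a 320 x 400 reference
    grid.  Deterministic for a fixed seed.
    """
    if not 0 < scale <= 1:
        raise ParameterError("scale must be in (0, 1]")
    H = round(C.REFERENCE_SHAPE_FULL[0] * scale)
    W = round(C.REFERENCE_SHAPE_FULL[1] * scale)
    if H < C.MIN_GRID or W < C.MIN_GRID:
        raise ParameterError(
            f"scale {scale} yields reference grid {H}x{W} < "
            f"{C.MIN_GRID}x{C.MIN_GRID}")
    rng = np.random.default_rng(seed)

    labels = _label_map((H, W))
    indicators = np.stack(
        [(labels == c).astype(np.float64) for c in range(1, C.N_CLASSES + 1)],
        axis=2)
    tex_sigma = max(1.5, C.TEXTURE_CORR_FRACTION * min(H, W))
    texture = 1.0 + C.TEXTURE_AMPLITUDE * np.clip(
        ndimage.gaussian_filter(rng.standard_normal((H, W)), tex_sigma)
        * tex_sigma * 2.0, -2.0, 2.0)
    fields = np.concatenate([indicators, texture[:, :, None]], axis=2)

    # -- true misalignments ----------------------------------------------
    def draw_rigid(shape):
        tx, ty = rng.uniform(-C.MISALIGN_MAX_SHIFT_PX, C.MISALIGN_MAX_SHIFT_PX, 2)
        ang = rng.uniform(-C.MISALIGN_MAX_ROT_DEG, C.MISALIGN_MAX_ROT_DEG)
        return _euclidean_about_center(ang, tx, ty, shape)

    t_nir = draw_rigid((H, W))
    t_rgb = draw_rigid((H, W))
    mir_layers = [Transform2D.identity("translation")]
    for _ in range(2):
        tx, ty = rng.uniform(-C.MIR_LAYER_MAX_SHIFT_PX,
                             C.MIR_LAYER_MAX_SHIFT_PX, 2)
        mir_layers.append(Transform2D(
            "translation", np.array([[1.0, 0.0, tx], [0.0, 1.0, ty]])))

    sig_nir = C.nir_class_signatures()
    sig_mir = C.MIR_CLASS_SIGNATURES
    sig_rgb = C.rgb_class_signatures()
    i0 = C.nir_reference_spectrum()

    # -- NIR: warp + downsample, lamp spectrum, spikes, noise -------------
    nir_shape = (max(8, round(H / C.NIR_DOWNSCALE)),
                 max(8, round(W / C.NIR_DOWNSCALE)))
    warp_nir = t_nir.as_homogeneous() @ _scaling_transform(nir_shape, (H, W))
    smp = _sample_scene(fields, warp_nir, nir_shape,
                        presmooth=0.5 * H / nir_shape[0])
    refl = np.einsum("yxc,cb->yxb", smp[:, :, :-1], sig_nir)
    refl *= smp[:, :, -1][:, :, None]  # shared micro-structure
    refl += rng.normal(0.0, C.NOISE_SIGMA, refl.shape)
    nir_raw = np.clip(refl, 0.0, None) * i0[None, None, :]

    n_spikes = int(round(C.SPIKE_RATE * nir_raw.size))
    flat_idx = rng.choice(nir_raw.size, size=n_spikes, replace=False)
    spike_idx = np.stack(np.unravel_index(flat_idx, nir_raw.shape), axis=1)
    clean_vals = nir_raw.reshape(-1)[flat_idx].copy()
    signal_floor = float(np.median(nir_raw[nir_raw > 0.05]))
    amp = rng.uniform(*C.SPIKE_AMPLITUDE, size=n_spikes)
    nir_raw.reshape(-1)[flat_idx] = clean_vals + amp * np.maximum(
        clean_vals, signal_floor)

    nir = make_datacube(nir_raw, C.NIR_WAVELENGTHS_NM, Modality.NIR,
                        C.MIR_RESOLUTION_UM * C.NIR_DOWNSCALE / scale)
    nir.log_step("generate_phantom", seed=seed, scale=scale)

    # -- MIR: per-band layer shifts, vignette, noise ----------------------
    mir_data = np.empty((H, W, 3))
    vign_mir = _vignette((H, W), C.VIGNETTE_AMPLITUDE)
    for b in range(3):
        scene_b = indicators @ sig_mir[:, b] * texture
        warped = sktf.warp(scene_b,
                           sktf.AffineTransform(
                               matrix=mir_layers[b].as_homogeneous()),
                           order=1, mode="constant", cval=0.0,
                           preserve_range=True)
        mir_data[:, :, b] = warped * vign_mir
    mir_data += rng.normal(0.0, C.NOISE_SIGMA, mir_data.shape)
    mir = make_datacube(np.clip(mir_data, 0.0, None), C.MIR_WAVELENGTHS_NM,
                        Modality.MIR, C.MIR_RESOLUTION_UM / scale)
    mir.log_step("generate_phantom", seed=seed, scale=scale)

    # -- RGB: warp + downsample, vignette, noise --------------------------
    rgb_shape = (max(8, round(H / C.RGB_DOWNSCALE)),
                 max(8, round(W / C.RGB_DOWNSCALE)))
    warp_rgb = t_rgb.as_homogeneous() @ _scaling_transform(rgb_shape, (H, W))
    smp = _sample_scene(fields, warp_rgb, rgb_shape,
                        presmooth=0.5 * H / rgb_shape[0])
    rgb_data = np.einsum("yxc,cb->yxb", smp[:, :, :-1], sig_rgb)
    rgb_data *= smp[:, :, -1][:, :, None]
    rgb_data *= _vignette(rgb_shape, C.VIGNETTE_AMPLITUDE)[:, :, None]
    rgb_data += rng.normal(0.0, C.NOISE_SIGMA, rgb_data.shape)
    rgb = make_datacube(np.clip(rgb_data, 0.0, None), C.RGB_WAVELENGTHS_NM,
                        Modality.RGB, C.MIR_RESOLUTION_UM * C.RGB_DOWNSCALE / scale)
    rgb.log_step("generate_phantom", seed=seed, scale=scale)

    truth = PhantomTruth(
        label_map=labels,
        transforms={"NIR": t_nir, "RGB": t_rgb},
        mir_layer_transforms=mir_layers,
        signatures={"NIR": sig_nir, "MIR": sig_mir, "RGB": sig_rgb},
        reference_spectrum=i0,
        spike_indices=spike_idx,
        spike_clean_values=clean_vals,
        artifact_params={
            "noise_sigma": C.NOISE_SIGMA,
            "spike_rate": C.SPIKE_RATE,
            "spike_amplitude": list(C.SPIKE_AMPLITUDE),
            "vignette_amplitude": C.VIGNETTE_AMPLITUDE,
            "texture_amplitude": C.TEXTURE_AMPLITUDE,
        },
        seed=seed,
        scale=scale,
    )
    return nir, mir, rgb, truth


def phantom_reference(truth: PhantomTruth) -> ReferenceSpectrum:
    """The NIR lamp spectrum as a ReferenceSpectrum for reference_correct."""
    return ReferenceSpectrum(truth.reference_spectrum)


def write_phantom(out_dir: str, seed: int, scale: float = 0.2) -> dict[str, str]:
    """Generate and persist the phantom (three cubes + truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nir, mir, rgb, truth = generate_phantom(seed, scale)
    paths = {}
    for name, cube in (("nir", nir), ("mir", mir), ("rgb", rgb)):
        path = out / f"{name}.h5"
        write_cube(cube, str(path))
        paths[name] = str(path)
    truth.save(str(out))
    np.savetxt(out / "reference_nir.csv", truth.reference_spectrum,
               header="reference", comments="")
    paths["truth"] = str(out / "truth.json")
    return paths


def truth_metrics(
    truth: PhantomTruth,
    result: ClusterResult | None = None,
    transforms: dict[str, Transform2D] | None = None,
    jaccard_threshold: float = 0.5,
) -> dict[str, Any]:
    """Score a pipeline run against the phantom ground truth.

    Reports the adjusted Rand index of the cluster labels against the true
    label map, per-modality transform recovery errors (translation px,
    rotation deg, against the inverse of the true misalignment), and a
    per-class detection flag: a class counts as detected when some cluster
    overlaps it with Jaccard >= ``jaccard_threshold``.
    """
    from .analysis import adjusted_rand_index

    report: dict[str, Any] = {}
    if result is not None:
        true_labels = truth.label_map.astype(np.int32) - 1  # background -> -1
        if result.labels.shape != true_labels.shape:
            raise ParameterError(
                f"label map shape {result.labels.shape} does not match truth "
                f"{true_labels.shape}")
        report["ari"] = adjusted_rand_index(result.labels.ravel(),
                                            true_labels.ravel())
        detected = {}
        for cls in range(1, truth.n_classes + 1):
            in_class = truth.label_map == cls
            best = 0.0
            for k in range(result.k):
                in_cluster = result.labels == k
                inter = float(np.logical_and(in_class, in_cluster).sum())
                union = float(np.logical_or(in_class, in_cluster).sum())
                if union > 0:
                    best = max(best, inter / union)
            detected[cls] = {"jaccard": best,
                             "detected": bool(best >= jaccard_threshold)}
        report["classes"] = detected
        report["n_detected"] = sum(d["detected"] for d in detected.values())
    if transforms is not None:
        recovery = {}
        for name, est in transforms.items():
            true_t = truth.transforms[name]
            resid = Transform2D("affine",
                                (true_t.as_homogeneous()
                                 @ est.as_homogeneous())[:2])
            shape = truth.label_map.shape
            center = np.array([(shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0])
            recovery[name] = {
                "translation_px": float(np.linalg.norm(
                    resid.apply_points(center)[0] - center)),
                "rotation_deg": abs(resid.rotation_deg),
            }
        report["transform_recovery"] = recovery
    return report
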
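"""Versioned constants of the synthetic multimodal brain-section phantom.

The phantom emulates a three-modality acquisition of one coronal tissue
section: a 260-band NIR whiskbroom cube (960-1478 nm, 2 nm steps), a 3-band
MIR area-scan cube (2790, 2962, 3700 nm laser lines) on the reference grid,
and a 3-channel RGB snapshot.  Nine tissue classes sit on a dark
background: three grey-matter blobs, four elongated white-matter tracts and
two CSF cavities.

Spectral logic (fixed here so tests are stable): grey matter and CSF are
water-dominated (strong 1450 nm NIR absorption, high 2790/3700 nm MIR
response), white matter is lipid-dominated (1210/1390 nm CH overtones,
strong 2962 nm CH stretch).  Class-modality visibility is engineered to
mirror what single sensors can and cannot resolve:

* RGB carries only structural (compartment-level) contrast - all classes of
  a compartment share one color, so RGB alone can separate at most 3 groups.
* NIR lacks the CSF contrast - classes 8 and 9 have identical NIR
  signatures.
* MIR lacks one grey-matter contrast - classes 1 and 2 have identical MIR
  signatures.
* Only the fused cube separates all 9 classes.
"""

from __future__ import annotations

import numpy as np

# -- acquisition geometry (reference grid = MIR grid) ---------------------
REFERENCE_SHAPE_FULL = (1600, 2000)   # rows, cols at scale 1.0
NIR_DOWNSCALE = 7.6                   # 76 um NIR vs 10 um MIR pixels
RGB_DOWNSCALE = 1.6                   # 16 um RGB vs 10 um MIR pixels
MIR_RESOLUTION_UM = 10.0
MIN_GRID = 64

NIR_WAVELENGTHS_NM = 960.0 + 2.0 * np.arange(260)   # 960..1478 nm
MIR_WAVELENGTHS_NM = np.array([2790.0, 2962.0, 3700.0])
RGB_WAVELENGTHS_NM = np.array([465.0, 550.0, 620.0])  # B, G, R ascending

# -- degradation model ----------------------------------------------------
NOISE_SIGMA = 0.01          # additive Gaussian noise on reflectance scale
SPIKE_RATE = 0.002          # fraction of NIR (pixel, band) samples spiked
SPIKE_AMPLITUDE = (20.0, 40.0)  # spike height, multiples of local signal
VIGNETTE_AMPLITUDE = 0.10   # radial quadratic falloff at the corners
TEXTURE_AMPLITUDE = 0.05    # multiplicative micro-structure, shared scene
TEXTURE_CORR_FRACTION = 0.0125  # correlation length / min(grid dims)
MISALIGN_MAX_SHIFT_PX = 8.0     # NIR/RGB rigid offset on the reference grid
MISALIGN_MAX_ROT_DEG = 3.0
MIR_LAYER_MAX_SHIFT_PX = 3.0    # inter-band shifts of the area-scanned MIR

# -- NIR reference (lamp) spectrum I0, arbitrary counts -------------------
def nir_reference_spectrum() -> np.ndarray:
    lam = NIR_WAVELENGTHS_NM
    u = (lam - lam[0]) / (lam[-1] - lam[0])
    return 1.2 + 0.8 * np.exp(-(((lam - 1180.0) / 160.0) ** 2)) + 0.05 * u


# -- tissue class geometry ------------------------------------------------
# (name, compartment, center (row_frac, col_frac),
#  semi-axes (row_frac, col_frac), rotation_deg)
CLASS_SHAPES = (
    ("grey-1", "grey", (0.22, 0.20), (0.100, 0.095), 0.0),
    ("grey-2", "grey", (0.22, 0.55), (0.100, 0.095), 0.0),
    ("grey-3", "grey", (0.22, 0.85), (0.100, 0.075), 0.0),
    ("white-4", "white", (0.48, 0.25), (0.050, 0.170), 0.0),
    ("white-5", "white", (0.48, 0.70), (0.050, 0.170), 15.0),
    ("white-6", "white", (0.70, 0.25), (0.045, 0.160), -12.0),
    ("white-7", "white", (0.70, 0.70), (0.045, 0.160), 8.0),
    ("csf-8", "csf", (0.88, 0.32), (0.060, 0.100), 0.0),
    ("csf-9", "csf", (0.88, 0.70), (0.055, 0.085), 0.0),
)
N_CLASSES = len(CLASS_SHAPES)

# -- NIR reflectance model ------------------------------------------------
# R(lam) = base + slope*u - a_water*G(1450, 28) - a_lipid*G(1210, 22)
#                        - a_lipid2*G(1390, 30),  u in [0, 1]
# Classes 8 and 9 are identical by construction (no CSF contrast in NIR).
# Rows: (base, slope, a_water, a_lipid, a_lipid2)
NIR_CLASS_PARAMS = np.array([
    [0.60, -0.05, 0.34, 0.06, 0.12],   # grey-1
    [0.60, -0.05, 0.26, 0.14, 0.12],   # grey-2
    [0.62, +0.02, 0.40, 0.04, 0.20],   # grey-3
    [0.72, -0.02, 0.10, 0.34, 0.06],   # white-4
    [0.70, -0.02, 0.16, 0.26, 0.06],   # white-5
    [0.74, -0.02, 0.10, 0.34, 0.18],   # white-6
    [0.70, +0.03, 0.22, 0.30, 0.02],   # white-7
    [0.50, -0.04, 0.48, 0.00, 0.06],   # csf-8
    [0.50, -0.04, 0.48, 0.00, 0.06],   # csf-9 (== csf-8 in NIR)
])
NIR_FEATURES = ((1450.0, 28.0), (1210.0, 22.0), (1390.0, 30.0))

# -- MIR reflectance per band (2790, 2962, 3700 nm) -----------------------
# Band 2962 (CH stretch) dominates white matter; 2790/3700 (water) dominate
# CSF.  Classes 1 and 2 are identical (one grey contrast missing in MIR).
MIR_CLASS_SIGNATURES = np.array([
    [0.55, 0.45, 0.50],   # grey-1
    [0.55, 0.45, 0.50],   # grey-2 (== grey-1 in MIR)
    [0.62, 0.38, 0.40],   # grey-3
    [0.30, 0.85, 0.22],   # white-4
    [0.40, 0.76, 0.32],   # white-5
    [0.24, 0.80, 0.40],   # white-6
    [0.34, 0.66, 0.16],   # white-7
    [0.85, 0.12, 0.72],   # csf-8
    [0.42, 0.50, 0.58],   # csf-9
])

# -- RGB colors (B, G, R ascending wavelength) ----------------------------
# Structural contrast only: one color per compartment.
RGB_COMPARTMENT_COLORS = {
    "grey": np.array([0.46, 0.50, 0.60]),
    "white": np.array([0.72, 0.78, 0.84]),
    "csf": np.array([0.62, 0.50, 0.40]),
}


def nir_class_signatures() -> np.ndarray:
    """(9, 260) clean NIR reflectance signatures."""
    lam = NIR_WAVELENGTHS_NM
    u = (lam - lam[0]) / (lam[-1] - lam[0])
    feats = np.stack([np.exp(-0.5 * ((lam - c) / w) ** 2) for c, w in NIR_FEATURES])
    sigs = (
        NIR_CLASS_PARAMS[:, :1]
        + NIR_CLASS_PARAMS[:, 1:2] * u[None, :]
        - NIR_CLASS_PARAMS[:, 2:5] @ feats
    )
    return np.clip(sigs, 0.02, 0.98)


def rgb_class_signatures() -> np.ndarray:
    """(9, 3) RGB colors per class (compartment color)."""
    return np.stack([RGB_COMPARTMENT_COLORS[comp] for _, comp, *_ in CLASS_SHAPES])
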
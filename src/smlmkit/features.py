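"""Per-localization feature vectors for fit-quality classification.

Each localization is described by the raw pixels around it: a 21x21 patch
from its own frame plus the same patch from the previous and next frames
(overlapping-emitter misfits and background flickers look different from a
clean single blink when the neighbouring frames are taken into account).
The patch is shifted (bilinear) so the localization sits at the centre of
the middle pixel, rotated (bilinear) so the intensity gradient across the
centre pixel points up, and multiplied by a Gaussian window that
de-emphasises the patch rim.  The three 441-pixel blocks are concatenated
with whatever numeric outputs the localization algorithm supplied, each
element is replaced by the natural log of its magnitude, and PCA — fitted on
this acquisition only — compresses the result to 20 dimensions.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .simulate import FrameStack

__all__ = [
    "PatchTriple",
    "PCABasis",
    "FeatureMatrix",
    "extract_patch_triple",
    "assemble_raw_feature",
    "log_magnitude",
    "fit_pca",
    "reduce",
    "build_features",
]

WINDOW = 21
DEFAULT_NUMERIC_COLUMNS = [
    "sigma_nm",
    "intensity_photon",
    "bkgstd_photon",
    "uncertainty_nm",
]


@dataclass
class PatchTriple:
    """Aligned, windowed 21x21 patches for (previous, current, next) frames."""

    current: np.ndarray
    previous: np.ndarray
    next: np.ndarray
    rotation_deg: float
    has_previous: bool
    has_next: bool
    border_flag: bool

    def __post_init__(self) -> None:
        for p in (self.current, self.previous, self.next):
            if p.shape != (WINDOW, WINDOW):
                raise ValueError("patches must be 21x21")
            if not np.all(np.isfinite(p)):
                raise ValueError("patches must be finite")


@dataclass
class PCABasis:
    """Mean vector, orthonormal component directions and eigenvalues."""

    mean: np.ndarray  # (d,)
    components: np.ndarray  # (k, d)
    eigenvalues: np.ndarray  # (k,)

    @property
    def fingerprint(self) -> str:
        h = hashlib.sha1()
        h.update(np.ascontiguousarray(self.mean).tobytes())
        h.update(np.ascontiguousarray(self.components).tobytes())
        return h.hexdigest()[:16]


@dataclass
class FeatureMatrix:
    """Raw, log-transformed and PCA-reduced features plus the fitted basis."""

    raw: np.ndarray  # (n, d)
    transformed: np.ndarray  # (n, d)
    reduced: np.ndarray  # (n, k)
    basis: PCABasis

    @property
    def n(self) -> int:
        return self.raw.shape[0]


def _resample(
    img: np.ndarray,
    centre_rc: tuple[float, float],
    angle_rad: float,
    half: int = WINDOW // 2,
) -> np.ndarray:
    """Bilinear sample of a (2*half+1)^2 patch centred and rotated about a point.

    The output grid is rotated by ``angle_rad`` about the patch centre, which
    maps image content by the opposite rotation (content gradient at +angle
    ends up vertical for angle = 90deg - gradient angle).
    """
    n = 2 * half + 1
    jj, ii = np.meshgrid(np.arange(n) - half, np.arange(n) - half)
    ca, sa = math.cos(angle_rad), math.sin(angle_rad)
    rows = centre_rc[0] + ii * ca - jj * sa
    cols = centre_rc[1] + ii * sa + jj * ca
    return ndimage.map_coordinates(img, [rows, cols], order=1, mode="reflect")


def gaussian_window(sigma_px: float, n: int = WINDOW) -> np.ndarray:
    half = n // 2
    ax = np.arange(n) - half
    g = np.exp(-(ax**2) / (2 * sigma_px**2))
    return np.outer(g, g)


def extract_patch_triple(
    stack: FrameStack,
    record: pd.Series | dict,
    gauss_window_sigma_px: float = 5.0,
    apply_window: bool = True,
) -> PatchTriple:
    """Extract the aligned, windowed patch triple for one localization.

    The rotation angle comes from a Sobel gradient of the sigma=1 px
    smoothed current patch, evaluated at the centre pixel; the same shift
    and rotation are applied to the previous and next frames.  A missing
    neighbour frame (first/last frame of the stack) is replaced by a copy of
    the current patch and flagged.  Localizations near the border are served
    by reflect-padding (flagged).

    With ``apply_window=False`` the aligned patches are returned unscaled;
    :func:`build_features` uses this and applies the window to the
    log-transformed values instead (see :func:`log_magnitude` for why).
    """
    frame = int(record["frame"])
    if frame < 0 or frame >= stack.n_frames:
        raise ValueError("record frame outside stack")
    px = stack.pixel_size_nm
    row = float(record["y_nm"]) / px - 0.5  # centre of pixel (i) sits at (i+0.5)*px
    col = float(record["x_nm"]) / px - 0.5
    h, w = stack.shape
    half = WINDOW // 2
    border_flag = not (
        half <= row <= h - 1 - half and half <= col <= w - 1 - half
    )

    cur_img = np.asarray(stack.data[frame], dtype=float)
    # shift-only patch to measure the gradient on
    shifted = _resample(cur_img, (row, col), 0.0)
    sm = ndimage.gaussian_filter(shifted, 1.0)
    gy = ndimage.sobel(sm, axis=0)[half, half]
    gx = ndimage.sobel(sm, axis=1)[half, half]
    mag = math.hypot(gx, gy)
    if mag < 1e-12:
        angle = 0.0
    else:
        angle = math.pi / 2.0 - math.atan2(gy, gx)

    win = gaussian_window(gauss_window_sigma_px) if apply_window else 1.0

    def grab(f: int) -> np.ndarray:
        img = np.asarray(stack.data[f], dtype=float)
        return _resample(img, (row, col), angle) * win

    current = grab(frame)
    has_prev = frame - 1 >= 0
    has_next = frame + 1 < stack.n_frames
    previous = grab(frame - 1) if has_prev else current.copy()
    nxt = grab(frame + 1) if has_next else current.copy()
    return PatchTriple(
        current=current,
        previous=previous,
        next=nxt,
        rotation_deg=math.degrees(angle),
        has_previous=has_prev,
        has_next=has_next,
        border_flag=border_flag,
    )


def assemble_raw_feature(
    triple: PatchTriple,
    record: pd.Series | dict,
    numeric_columns: list[str] | None = None,
) -> np.ndarray:
    """Concatenate [current 441 | previous 441 | next 441 | numerics].

    The numeric tail holds the localization algorithm's per-fit outputs
    (width, brightness, background, uncertainty by default) plus the two
    neighbour-presence flags, keeping the dimensionality constant across the
    stack.  The ordering is fixed: pixel blocks row-major, then numerics in
    the order given.
    """
    cols = DEFAULT_NUMERIC_COLUMNS if numeric_columns is None else numeric_columns
    numerics = [float(record[c]) for c in cols]
    numerics += [float(triple.has_previous), float(triple.has_next)]
    return np.concatenate(
        [
            triple.current.ravel(),
            triple.previous.ravel(),
            triple.next.ravel(),
            np.asarray(numerics),
        ]
    )


def log_magnitude(raw: np.ndarray, eps: float | None = None) -> np.ndarray:
    """Elementwise ``ln(|v| + eps)``.

    Pixel intensities span orders of magnitude over an acquisition; the log
    keeps a handful of very bright patches from dominating the covariance
    that PCA diagonalises.  ``eps`` defaults to 1e-6 of the median nonzero
    magnitude so zeros stay finite without distorting the scale.
    """
    mag = np.abs(np.asarray(raw, dtype=float))
    if eps is None:
        nz = mag[mag > 0]
        eps = 1e-6 * float(np.median(nz)) if len(nz) else 1e-12
    return np.log(mag + eps)


def fit_pca(transformed: np.ndarray, k: int = 20) -> PCABasis:
    """PCA basis from the covariance of THIS acquisition's features.

    A fresh basis is fitted per dataset rather than reusing a global one, so
    the 20 retained directions capture the variability actually present in
    the acquisition at hand.
    """
    x = np.asarray(transformed, dtype=float)
    if x.shape[0] < k + 1:
        raise ValueError(
            f"need at least {k + 1} feature vectors to fit a {k}-component PCA; "
            f"got {x.shape[0]} — use a smaller k"
        )
    mean = x.mean(axis=0)
    xc = x - mean
    # SVD of the centred data; components are right singular vectors
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    eig = s**2 / (x.shape[0] - 1)
    return PCABasis(mean=mean, components=vt[:k].copy(), eigenvalues=eig[:k].copy())


def reduce(basis: PCABasis, vectors: np.ndarray) -> np.ndarray:
    """Mean-centred projection onto the PCA components."""
    x = np.atleast_2d(np.asarray(vectors, dtype=float))
    out = (x - basis.mean) @ basis.components.T
    return out[0] if np.asarray(vectors).ndim == 1 else out


def build_features(
    stack: FrameStack,
    table: pd.DataFrame,
    k: int = 20,
    gauss_window_sigma_px: float = 5.0,
    numeric_columns: list[str] | None = None,
) -> FeatureMatrix:
    """Full pipeline: patches -> raw vectors -> log -> window -> PCA.

    The Gaussian window is applied to the log-transformed pixel values, not
    the raw counts: a multiplicative window on raw pixels turns into a
    per-pixel additive constant after the log and therefore cancels out of
    the covariance matrix entirely — it would have no effect on the PCA it
    is meant to shape.  Windowing in log space genuinely down-weights the
    variance of rim pixels, as intended.
    """
    raws = []
    for _, rec in table.iterrows():
        triple = extract_patch_triple(stack, rec, apply_window=False)
        raws.append(assemble_raw_feature(triple, rec, numeric_columns))
    raw = np.asarray(raws)
    transformed = log_magnitude(raw)
    n_pix = 3 * WINDOW * WINDOW
    win = gaussian_window(gauss_window_sigma_px).ravel()
    transformed[:, :n_pix] *= np.concatenate([win, win, win])
    basis = fit_pca(transformed, k=k)
    reduced = reduce(basis, transformed)
    return FeatureMatrix(raw=raw, transformed=transformed, reduced=reduced, basis=basis)
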
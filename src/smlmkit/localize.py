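"""Reference single-emitter detection and fitting.

This is a deliberately simple, fully documented localizer — band-pass
detection followed by elliptical-Gaussian least squares in an 11x11 window,
with width/asymmetry rejection.  It is not a re-implementation of any
published tool; it exists so the rest of the package (planning theory,
feature extraction, quality classification) can be exercised end-to-end on
simulated data with a known, controllable algorithm.  The quantitative
regime boundaries it produces in the two-emitter separation sweep are
therefore properties of *this* fitter; published values for other fitters
differ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.special import erf
from skimage.feature import peak_local_max

from .simulate import CameraModel, EmitterTraces, FrameStack, OpticsConfig, render_frames

__all__ = [
    "LocalizerConfig",
    "SeparationSweepResult",
    "detect_candidates",
    "fit_emitter",
    "reject_fits",
    "localize_stack",
    "separation_sweep",
    "estimate_exclusion_radius",
]

TABLE_COLUMNS = [
    "id",
    "frame",
    "x_nm",
    "y_nm",
    "sigma_nm",
    "sigma_x_nm",
    "sigma_y_nm",
    "intensity_photon",
    "offset_photon",
    "bkgstd_photon",
    "uncertainty_nm",
]


@dataclass
class LocalizerConfig:
    """Tunables of the reference localizer.

    ``k_sigma`` scales the robust noise estimate of the band-pass image into
    a detection threshold; ``sigma_bounds`` are relative to the optical PSF
    sigma; ``asymmetry_bound`` caps ``|sx - sy| / mean(sx, sy)``.
    """

    min_distance_px: int = 3
    window_px: int = 11
    k_sigma: float = 6.0
    threshold_abs_min: float = 1e-6
    sigma_bounds: tuple[float, float] = (0.7, 1.5)
    asymmetry_bound: float = 0.6
    max_nfev: int = 200
    algorithm_tag: str = "smlmkit-ref"


@dataclass
class SeparationSweepResult:
    """Outcome of the two-emitter separation sweep."""

    separations_nm: np.ndarray
    n_localizations: np.ndarray
    midpoint_bias_nm: np.ndarray
    regimes: list[str]  # "merged" | "biased" | "accurate"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "separation_nm": self.separations_nm,
                "n_localizations": self.n_localizations,
                "midpoint_bias_nm": self.midpoint_bias_nm,
                "regime": self.regimes,
            }
        )


def detect_candidates(
    frame_image: np.ndarray,
    config: LocalizerConfig | None = None,
) -> np.ndarray:
    """Local maxima of a difference-of-Gaussians band-pass above threshold.

    Threshold = ``k_sigma`` x robust (MAD-based) standard deviation of the
    filtered image, floored at ``threshold_abs_min`` so a perfectly flat
    frame yields no candidates.  Returns an (n, 2) array of (row, col) pixel
    indices; no two candidates lie within ``min_distance_px``.  Ties between
    equal-height neighbouring maxima break toward the lowest (row, col).
    """
    config = config or LocalizerConfig()
    img = np.asarray(frame_image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2D image")
    bp = ndimage.gaussian_filter(img, 1.0) - ndimage.gaussian_filter(img, 2.5)
    # noise floor from the lower half of the band-pass distribution: a global
    # MAD would inflate with scene density and throttle detection exactly in
    # the crowded frames the quality classifier needs to see
    lo = np.percentile(bp, [16, 50])
    noise_sd = max(lo[1] - lo[0], 0.0)  # half the 16-84 spread of a Gaussian
    thresh = max(config.k_sigma * noise_sd, config.threshold_abs_min)
    peaks = peak_local_max(
        bp,
        min_distance=config.min_distance_px,
        threshold_abs=thresh,
        exclude_border=False,
    )
    if len(peaks) == 0:
        return np.empty((0, 2), dtype=int)
    order = np.lexsort((peaks[:, 1], peaks[:, 0]))
    return peaks[order]


def _erf_profile(edges_nm: np.ndarray, mu_nm: float, sigma_nm: float) -> np.ndarray:
    s = sigma_nm * math.sqrt(2.0)
    e = erf((edges_nm - mu_nm) / s)
    return 0.5 * np.diff(e)


def fit_emitter(
    frame_image: np.ndarray,
    candidate_px: tuple[int, int],
    optics: OpticsConfig,
    camera: CameraModel,
    config: LocalizerConfig | None = None,
    frame_index: int = 0,
) -> dict | None:
    """Least-squares elliptical pixel-integrated Gaussian fit in a window.

    Model per pixel: ``offset + N * fx(x0, sx) * fy(y0, sy)`` in counts,
    where ``fx, fy`` are erf-integrated 1D Gaussian profiles.  Intensity is
    converted to photons using the camera gain/QE chain.  The localization
    uncertainty is the standard shot-noise + pixelation + background
    precision estimate:

        var = (s^2 + px^2/12) / N + 8 pi s^4 b^2 / (px^2 N^2)

    Returns ``None`` for a non-convergent or out-of-bounds fit.

    Raises
    ------
    ValueError
        If the fitting window does not fit inside the image.
    """
    config = config or LocalizerConfig()
    img = np.asarray(frame_image, dtype=float)
    h, w = img.shape
    half = config.window_px // 2
    r, c = candidate_px
    if r - half < 0 or c - half < 0 or r + half >= h or c + half >= w:
        raise ValueError("candidate too close to the image border for the fit window")
    win = img[r - half : r + half + 1, c - half : c + half + 1]
    px = optics.pixel_size_nm
    x_edges = (np.arange(c - half, c + half + 2)) * px
    y_edges = (np.arange(r - half, r + half + 2)) * px
    offset0 = float(win.min())
    n0 = max(float(win.sum() - offset0 * win.size), 1.0)
    x0 = (c + 0.5) * px
    y0 = (r + 0.5) * px
    s0 = optics.sigma_nm

    def residuals(p: np.ndarray) -> np.ndarray:
        x, y, sx, sy, n, off = p
        model = off + n * np.outer(
            _erf_profile(y_edges, y, sy), _erf_profile(x_edges, x, sx)
        )
        return (model - win).ravel()

    lb = [x_edges[0], y_edges[0], s0 * 0.2, s0 * 0.2, 0.0, -np.inf]
    ub = [x_edges[-1], y_edges[-1], s0 * 6.0, s0 * 6.0, np.inf, np.inf]
    try:
        res = least_squares(
            residuals,
            [x0, y0, s0, s0, n0, offset0],
            bounds=(lb, ub),
            xtol=1e-6,
            ftol=1e-6,
            max_nfev=config.max_nfev,
        )
    except Exception:
        return None
    if not res.success or not np.all(np.isfinite(res.x)):
        return None
    x, y, sx, sy, n_counts, off = res.x
    if n_counts <= 0:
        return None
    counts_per_photon = (
        camera.quantum_efficiency * camera.em_gain * camera.counts_per_photoelectron
    )
    n_photons = n_counts / counts_per_photon
    resid = res.fun.reshape(win.shape)
    bkg_counts = float(resid.std())
    bkg_photons = bkg_counts / counts_per_photon
    sigma = 0.5 * (sx + sy)
    var = (sigma**2 + px**2 / 12.0) / max(n_photons, 1e-9) + (
        8.0 * math.pi * sigma**4 * bkg_photons**2
    ) / (px**2 * max(n_photons, 1e-9) ** 2)
    if camera.em_gain > 1:
        var *= 2.0  # EM-register excess noise doubles the shot-noise variance
    return {
        "frame": frame_index,
        "x_nm": float(x),
        "y_nm": float(y),
        "sigma_nm": float(sigma),
        "sigma_x_nm": float(sx),
        "sigma_y_nm": float(sy),
        "intensity_photon": float(n_photons),
        "offset_photon": float((off - camera.baseline_offset) / counts_per_photon),
        "bkgstd_photon": float(bkg_photons),
        "uncertainty_nm": float(math.sqrt(var)),
    }


def reject_fits(
    records: pd.DataFrame,
    optics: OpticsConfig,
    config: LocalizerConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split fitted records into (kept, rejected) by width and asymmetry.

    Keep iff ``sigma_nm`` lies within ``sigma_bounds`` x optical sigma and
    the x/y width asymmetry is below ``asymmetry_bound``.  Merged fits to a
    sufficiently separated emitter pair inflate the fitted width and are
    rejected here; closer pairs slip through and are the classifier's job.
    """
    config = config or LocalizerConfig()
    if len(records) == 0:
        return records.copy(), records.copy()
    lo, hi = config.sigma_bounds
    s = records["sigma_nm"]
    asym = (records["sigma_x_nm"] - records["sigma_y_nm"]).abs() / s
    ok = (s >= lo * optics.sigma_nm) & (s <= hi * optics.sigma_nm) & (
        asym <= config.asymmetry_bound
    )
    return records[ok].reset_index(drop=True), records[~ok].reset_index(drop=True)


def localize_stack(
    stack: FrameStack,
    optics: OpticsConfig,
    camera: CameraModel,
    config: LocalizerConfig | None = None,
    keep_rejected: bool = False,
) -> pd.DataFrame:
    """Detect, fit and filter every frame independently.

    Returns a localization table with one fitted fluorophore per row.
    Candidates whose fit window would cross the image border are skipped;
    non-convergent fits are dropped.
    """
    config = config or LocalizerConfig()
    rows: list[dict] = []
    for f in range(stack.n_frames):
        img = stack.data[f]
        for r, c in detect_candidates(img, config):
            try:
                rec = fit_emitter(img, (int(r), int(c)), optics, camera, config, f)
            except ValueError:
                continue  # window off the edge
            if rec is not None:
                rows.append(rec)
    if not rows:
        return pd.DataFrame(columns=TABLE_COLUMNS)
    table = pd.DataFrame(rows)
    kept, rejected = reject_fits(table, optics, config)
    if keep_rejected:
        kept = kept.assign(rejected=False)
        rejected = rejected.assign(rejected=True)
        out = pd.concat([kept, rejected], ignore_index=True)
        out = out.sort_values(["frame", "y_nm", "x_nm"]).reset_index(drop=True)
    else:
        out = kept
    out.insert(0, "id", np.arange(len(out)))
    return out


def _render_pair(
    separation_nm: float,
    optics: OpticsConfig,
    camera: CameraModel,
    rng: np.random.Generator,
    noise: bool,
) -> FrameStack:
    fw, fh = optics.field_nm
    cx, cy = fw / 2, fh / 2
    pos = np.array(
        [[cx - separation_nm / 2, cy], [cx + separation_nm / 2, cy]]
    )
    traces = EmitterTraces(
        positions=pos,
        n_frames=1,
        active_frame=np.array([0, 0]),
        active_emitter=np.array([0, 1]),
        on_fraction=np.array([1.0, 1.0]),
    )
    if noise:
        return render_frames(traces, optics, camera, rng)
    quiet = CameraModel(
        em_gain=camera.em_gain,
        readout_noise_rms=0.0,
        baseline_offset=camera.baseline_offset,
        quantum_efficiency=camera.quantum_efficiency,
        counts_per_photoelectron=camera.counts_per_photoelectron,
    )
    return render_frames(traces, optics, quiet, rng, shot_noise=False)


def separation_sweep(
    separations_nm: np.ndarray | list[float],
    optics: OpticsConfig | None = None,
    camera: CameraModel | None = None,
    n_repeats: int = 1,
    rng_seed: int = 0,
    noise: bool = False,
    accurate_bias_tol_nm: float = 2.0,
    config: LocalizerConfig | None = None,
) -> SeparationSweepResult:
    """Two equal emitters moved progressively closer; localize each image.

    For every separation the pair is rendered (noise-free by default so the
    regime boundaries are deterministic properties of the fitter), localized,
    and classified:

    - ``accurate``: two localizations, both within ``accurate_bias_tol_nm``
      of truth;
    - ``biased``: two localizations with larger midpoint-ward bias;
    - ``merged``: at most one localization returned.

    The midpoint bias reported is ``(d_true - d_fit) / 2`` when two fits are
    returned, and the distance shortfall of the single fit otherwise.
    """
    optics = optics or OpticsConfig()
    camera = camera or CameraModel()
    config = config or LocalizerConfig()
    seps = np.asarray(separations_nm, dtype=float)
    if np.any(np.diff(seps) <= 0):
        raise ValueError("separations must be sorted strictly ascending")
    rng = np.random.default_rng(rng_seed)
    counts = np.zeros(len(seps), dtype=int)
    biases = np.zeros(len(seps))
    regimes: list[str] = []
    for i, d in enumerate(seps):
        n_found = []
        bias_vals = []
        for _ in range(n_repeats if noise else 1):
            stack = _render_pair(d, optics, camera, rng, noise)
            table = localize_stack(stack, optics, camera, config, keep_rejected=False)
            n = len(table)
            n_found.append(n)
            fw, fh = optics.field_nm
            cx = fw / 2
            if n >= 2:
                xs = np.sort(table["x_nm"].to_numpy())[:2] if n == 2 else np.sort(
                    table["x_nm"].to_numpy()
                )[[0, -1]]
                d_fit = xs[-1] - xs[0]
                bias_vals.append((d - d_fit) / 2.0)
            elif n == 1:
                bias_vals.append(d / 2.0 - abs(float(table["x_nm"].iloc[0]) - cx))
            else:
                bias_vals.append(d / 2.0)
        counts[i] = int(round(np.mean(n_found)))
        biases[i] = float(np.mean(bias_vals))
        if counts[i] >= 2 and abs(biases[i]) <= accurate_bias_tol_nm:
            regimes.append("accurate")
        elif counts[i] >= 2:
            regimes.append("biased")
        else:
            regimes.append("merged")
    return SeparationSweepResult(seps, counts, biases, regimes)


def estimate_exclusion_radius(
    sweep: SeparationSweepResult,
) -> tuple[float, float, float]:
    """Regime boundaries of the sweep and a conservative exclusion radius.

    Returns ``(merge_threshold, accurate_threshold, recommended_r)`` where
    ``merge_threshold`` is the largest separation still fitted as a single
    emitter, ``accurate_threshold`` the smallest separation from which all
    larger ones are accurate, and the recommendation is the conservative
    accurate threshold.

    Raises
    ------
    ValueError
        If the sweep does not bracket both regime changes.
    """
    regimes = sweep.regimes
    seps = sweep.separations_nm
    merged_idx = [i for i, r in enumerate(regimes) if r == "merged"]
    acc_idx = [i for i, r in enumerate(regimes) if r == "accurate"]
    if not merged_idx or not acc_idx:
        raise ValueError(
            "sweep must bracket both the merged and the accurate regime; "
            "extend the separation range"
        )
    merge_threshold = float(seps[max(merged_idx)])
    # smallest separation after which every larger one is accurate
    tail_start = len(regimes)
    for i in range(len(regimes) - 1, -1, -1):
        if regimes[i] != "accurate":
            break
        tail_start = i
    if tail_start == len(regimes):
        raise ValueError("largest separation is not in the accurate regime")
    accurate_threshold = float(seps[tail_start])
    if merge_threshold >= accurate_threshold:
        raise ValueError("regimes are not ordered merged < accurate")
    return merge_threshold, accurate_threshold, accurate_threshold
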
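"""Ground-truth structures, Markov-chain photoswitching and camera rendering.

The simulator produces the raw material for every downstream test: emitters
scattered on a 0D/1D/2D structure (or a four-vesicle benchmark), switched on
and off by a per-frame Markov chain, and rendered into noisy EMCCD frames
with a pixel-integrated Gaussian PSF.

The photophysics model is a large-pool regime: a big reservoir of tagged
fluorophores of which a small random subset activates each frame, with
irreversible bleaching negligible on the acquisition timescale (the common
live-cell situation).  The activation probability per emitter per frame
``p_act`` times the tagging density sets the activation density ``a`` that
the planning theory in :mod:`smlmkit.geometry` reasons about.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.special import erf

from .geometry import Disc, Rectangle, SampleGeometry

__all__ = [
    "OpticsConfig",
    "CameraModel",
    "PhotophysicsModel",
    "EmitterTraces",
    "FrameStack",
    "make_structure",
    "seed_emitters",
    "simulate_blinking",
    "render_frames",
    "simulate_acquisition",
]

# Markov states
INACTIVE, ACTIVE, DARK, BLEACHED = 0, 1, 2, 3

EMITTER_CAP = 2_000_000


@dataclass(frozen=True)
class OpticsConfig:
    """Optical train: wavelength, NA, pixel size and photon budget.

    ``psf_sigma_nm`` defaults to the standard Airy-core Gaussian
    approximation ``0.21 * lambda / NA`` (~73 nm at 488 nm / NA 1.4).
    ``photons_full_frame`` is the number of detected photoelectron-equivalent
    photons an emitter active for a whole frame delivers (before quantum
    efficiency and gain).
    """

    wavelength_nm: float = 488.0
    numerical_aperture: float = 1.4
    pixel_size_nm: float = 110.0
    photons_full_frame: float = 450.0
    field_px: tuple[int, int] = (40, 40)
    psf_sigma_nm: float | None = None

    @property
    def lambda_over_na(self) -> float:
        return self.wavelength_nm / self.numerical_aperture

    @property
    def sigma_nm(self) -> float:
        if self.psf_sigma_nm is not None:
            return self.psf_sigma_nm
        return 0.21 * self.lambda_over_na

    @property
    def field_nm(self) -> tuple[float, float]:
        return (
            self.field_px[0] * self.pixel_size_nm,
            self.field_px[1] * self.pixel_size_nm,
        )

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0 or self.numerical_aperture <= 0:
            raise ValueError("wavelength and NA must be positive")
        if self.photons_full_frame <= 0:
            raise ValueError("photon budget must be positive")


@dataclass(frozen=True)
class CameraModel:
    """EMCCD camera: QE, stochastic EM gain, Gaussian read noise, offset.

    The EM register is modelled as Gamma(k=n_photoelectrons, theta=gain)
    conditional on the Poisson photoelectron count — the standard EMCCD
    output distribution.  ``counts_per_photoelectron`` converts post-gain
    electrons to camera counts (ADU).
    """

    em_gain: float = 100.0
    readout_noise_rms: float = 1.0
    baseline_offset: float = 100.0
    quantum_efficiency: float = 0.9
    counts_per_photoelectron: float = 1.0

    def __post_init__(self) -> None:
        if self.em_gain < 1:
            raise ValueError("em_gain must be >= 1")
        if not (0 < self.quantum_efficiency <= 1):
            raise ValueError("quantum_efficiency must be in (0, 1]")
        if min(self.readout_noise_rms, self.baseline_offset) < 0:
            raise ValueError("noise and offset must be non-negative")


@dataclass
class PhotophysicsModel:
    """Four-state per-frame Markov chain: inactive, active, dark, bleached.

    Defaults put the simulator in the large-pool live-cell regime: an
    inactive emitter activates with probability ``p_act`` per frame, an
    active one switches off with probability 0.5 per frame (mean on-time two
    frames), the dark state is unused and bleaching is negligible.  All
    probabilities are exposed so fixed-cell photophysics can be dialled in.
    """

    p_act: float = 1e-4
    p_off: float = 0.5
    p_dark: float = 0.0
    p_bleach: float = 0.0
    p_dark_recover: float = 0.0

    def transition_matrix(self) -> np.ndarray:
        if not (0 <= self.p_act <= 1):
            raise ValueError("p_act must be in [0, 1]")
        t = np.zeros((4, 4))
        t[INACTIVE, ACTIVE] = self.p_act
        t[INACTIVE, INACTIVE] = 1 - self.p_act
        t[ACTIVE, INACTIVE] = self.p_off
        t[ACTIVE, DARK] = self.p_dark
        t[ACTIVE, BLEACHED] = self.p_bleach
        t[ACTIVE, ACTIVE] = 1 - self.p_off - self.p_dark - self.p_bleach
        t[DARK, ACTIVE] = self.p_dark_recover
        t[DARK, DARK] = 1 - self.p_dark_recover
        t[BLEACHED, BLEACHED] = 1.0
        if np.any(t < -1e-12):
            raise ValueError("transition probabilities produce a negative entry")
        return t


@dataclass
class EmitterTraces:
    """Ground-truth emitter positions plus sparse per-frame activity.

    Only active (frame, emitter) pairs are stored; ``on_fraction`` is the
    fraction of the frame the emitter spent emitting (1 for a full frame,
    uniform in (0, 1) for the frame in which it switched on).
    """

    positions: np.ndarray  # (M, 2) nm
    n_frames: int
    active_frame: np.ndarray  # (K,) frame index of each activity record
    active_emitter: np.ndarray  # (K,) emitter index
    on_fraction: np.ndarray  # (K,)

    @property
    def n_emitters(self) -> int:
        return len(self.positions)

    def active_counts_per_frame(self) -> np.ndarray:
        return np.bincount(self.active_frame, minlength=self.n_frames)

    def measured_activation_density(self, tagged_area_nm2: float) -> float:
        """Mean active emitters per frame divided by the tagged area."""
        return float(self.active_counts_per_frame().mean() / tagged_area_nm2)

    def sidecar(self, photons_full_frame: float) -> pd.DataFrame:
        """Ground-truth table: frame, emitter_id, x_nm, y_nm, on_fraction, photons."""
        return pd.DataFrame(
            {
                "frame": self.active_frame.astype(int),
                "emitter_id": self.active_emitter.astype(int),
                "x_nm": self.positions[self.active_emitter, 0],
                "y_nm": self.positions[self.active_emitter, 1],
                "on_fraction": self.on_fraction,
                "photons": self.on_fraction * photons_full_frame,
            }
        )


@dataclass
class FrameStack:
    """Camera image sequence in counts, with the metadata needed downstream."""

    data: np.ndarray  # (n_frames, h, w)
    pixel_size_nm: float
    meta: dict = dc_field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


def make_structure(
    kind: str,
    *,
    center: tuple[float, float] = (0.0, 0.0),
    width_nm: float = 8.0,
    length_nm: float = 3520.0,
    side_nm: float = 3520.0,
    vesicle_radius_nm: float = 30.0,
) -> SampleGeometry:
    """Build a canonical test structure.

    Kinds
    -----
    ``point``
        0D: a ``width_nm`` x ``width_nm`` square (default 8 x 8 nm).
    ``strand``
        1D: a ``width_nm`` x ``length_nm`` line (default 8 x 3520 nm).
    ``plane``
        2D: a ``side_nm`` x ``side_nm`` patch (default 3520 x 3520 nm).
    ``vesicles``
        Four discs of radius ``vesicle_radius_nm`` (default 30 nm) at
        relative offsets (0, 0), (200, 200), (200, 400), (400, 600) nm —
        a standard resolvability benchmark.

    The structure is centred on ``center`` (nm).
    """
    cx, cy = center
    if kind == "point":
        rect = Rectangle(cx - width_nm / 2, cy - width_nm / 2, width_nm, width_nm)
        return SampleGeometry(
            [rect], dimensionality_hint=0, width_nm=(width_nm, width_nm), label="0D point"
        )
    if kind == "strand":
        rect = Rectangle(cx - width_nm / 2, cy - length_nm / 2, width_nm, length_nm)
        return SampleGeometry(
            [rect], dimensionality_hint=1, width_nm=width_nm, label="1D strand"
        )
    if kind == "plane":
        rect = Rectangle(cx - side_nm / 2, cy - side_nm / 2, side_nm, side_nm)
        return SampleGeometry([rect], dimensionality_hint=2, label="2D plane")
    if kind == "vesicles":
        offsets = [(0.0, 0.0), (200.0, 200.0), (200.0, 400.0), (400.0, 600.0)]
        ox = cx - 200.0  # centre the offset bounding box (0..400, 0..600)
        oy = cy - 300.0
        discs = [Disc(ox + dx, oy + dy, vesicle_radius_nm) for dx, dy in offsets]
        return SampleGeometry(
            discs,
            dimensionality_hint=0,
            width_nm=(2 * vesicle_radius_nm, 2 * vesicle_radius_nm),
            label="four vesicles",
        )
    raise ValueError(f"unknown structure kind: {kind!r}")


def seed_emitters(
    geometry: SampleGeometry,
    tagging_density_per_nm2: float,
    rng: np.random.Generator | int,
    cap: int = EMITTER_CAP,
) -> np.ndarray:
    """Scatter emitters uniformly on the labelled region.

    The emitter count is Poisson with mean ``density * area``; positions are
    uniform within the union of primitives (primitives chosen by area
    weight).  Returns an (M, 2) array of nm coordinates.
    """
    if tagging_density_per_nm2 < 0:
        raise ValueError("tagging density must be non-negative")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    mean = tagging_density_per_nm2 * geometry.area
    if mean > cap:
        raise ValueError(
            f"expected emitter count {mean:.3g} exceeds cap {cap}; "
            "lower the tagging density or shrink the structure"
        )
    m = int(rng.poisson(mean))
    if m == 0:
        return np.empty((0, 2))
    areas = np.array([p.area for p in geometry.primitives])
    choice = rng.choice(len(areas), size=m, p=areas / areas.sum())
    xs = np.empty(m)
    ys = np.empty(m)
    for i, prim in enumerate(geometry.primitives):
        mask = choice == i
        k = int(mask.sum())
        if k == 0:
            continue
        if isinstance(prim, Rectangle):
            xs[mask] = prim.x + rng.random(k) * prim.width
            ys[mask] = prim.y + rng.random(k) * prim.height
        else:
            rr = prim.radius * np.sqrt(rng.random(k))
            th = rng.random(k) * 2 * math.pi
            xs[mask] = prim.cx + rr * np.cos(th)
            ys[mask] = prim.cy + rr * np.sin(th)
    return np.column_stack([xs, ys])


def simulate_blinking(
    positions: np.ndarray,
    photophysics: PhotophysicsModel,
    n_frames: int,
    rng: np.random.Generator | int,
) -> EmitterTraces:
    """Evolve every emitter's state through the per-frame Markov chain.

    All emitters start inactive.  The returned traces store only the active
    (frame, emitter) pairs; an emitter switching on mid-frame gets a uniform
    random on-fraction for that first frame and a full frame thereafter.
    Bleached emitters never re-activate (absorbing state).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    t = photophysics.transition_matrix()
    if not np.allclose(t.sum(axis=1), 1.0):
        raise ValueError("transition matrix rows must sum to 1")
    cum = np.cumsum(t, axis=1)
    m = len(positions)
    states = np.full(m, INACTIVE, dtype=np.uint8)
    frames_out: list[np.ndarray] = []
    emitters_out: list[np.ndarray] = []
    fracs_out: list[np.ndarray] = []
    for f in range(n_frames):
        u = rng.random(m)
        # vectorized categorical draw per current state
        new_states = np.empty(m, dtype=np.uint8)
        for s in (INACTIVE, ACTIVE, DARK, BLEACHED):
            mask = states == s
            if not mask.any():
                continue
            new_states[mask] = np.searchsorted(cum[s], u[mask], side="right").astype(
                np.uint8
            )
        newly_on = (new_states == ACTIVE) & (states != ACTIVE)
        still_on = (new_states == ACTIVE) & (states == ACTIVE)
        idx_new = np.nonzero(newly_on)[0]
        idx_cont = np.nonzero(still_on)[0]
        idx = np.concatenate([idx_new, idx_cont])
        if len(idx):
            frac = np.concatenate(
                [rng.random(len(idx_new)), np.ones(len(idx_cont))]
            )
            frames_out.append(np.full(len(idx), f, dtype=np.int64))
            emitters_out.append(idx)
            fracs_out.append(frac)
        states = new_states
    if frames_out:
        af = np.concatenate(frames_out)
        ae = np.concatenate(emitters_out)
        fr = np.concatenate(fracs_out)
    else:
        af = np.empty(0, dtype=np.int64)
        ae = np.empty(0, dtype=np.int64)
        fr = np.empty(0)
    return EmitterTraces(
        positions=np.asarray(positions, dtype=float),
        n_frames=n_frames,
        active_frame=af,
        active_emitter=ae,
        on_fraction=fr,
    )


def _pixel_integrated_psf(
    h: int,
    w: int,
    x_nm: float,
    y_nm: float,
    sigma_nm: float,
    pixel_nm: float,
    halfwidth_px: int,
) -> tuple[slice, slice, np.ndarray]:
    """Fraction of total flux falling in each pixel of a local window.

    Uses the error-function integral of the Gaussian over each pixel, so the
    sum over an unbounded grid is exactly 1.  Pixel (i, j) covers
    [j*px, (j+1)*px] x [i*px, (i+1)*px] in nm; x maps to columns, y to rows.
    """
    cx = int(x_nm // pixel_nm)
    cy = int(y_nm // pixel_nm)
    x0 = max(cx - halfwidth_px, 0)
    x1 = min(cx + halfwidth_px + 1, w)
    y0 = max(cy - halfwidth_px, 0)
    y1 = min(cy + halfwidth_px + 1, h)
    if x0 >= x1 or y0 >= y1:
        return slice(0, 0), slice(0, 0), np.zeros((0, 0))
    s = sigma_nm * math.sqrt(2.0)
    ex = erf((np.arange(x0, x1 + 1) * pixel_nm - x_nm) / s)
    ey = erf((np.arange(y0, y1 + 1) * pixel_nm - y_nm) / s)
    fx = 0.5 * np.diff(ex)
    fy = 0.5 * np.diff(ey)
    return slice(y0, y1), slice(x0, x1), np.outer(fy, fx)


def expected_photon_image(
    traces: EmitterTraces,
    optics: OpticsConfig,
    frame: int,
) -> np.ndarray:
    """Noise-free expected photon image for one frame."""
    w, h = optics.field_px
    img = np.zeros((h, w))
    sel = traces.active_frame == frame
    halfwidth = max(3, int(math.ceil(5 * optics.sigma_nm / optics.pixel_size_nm)))
    for emitter, frac in zip(traces.active_emitter[sel], traces.on_fraction[sel]):
        x, y = traces.positions[emitter]
        ys, xs, psf = _pixel_integrated_psf(
            h, w, x, y, optics.sigma_nm, optics.pixel_size_nm, halfwidth
        )
        img[ys, xs] += frac * optics.photons_full_frame * psf
    return img


def render_frames(
    traces: EmitterTraces,
    optics: OpticsConfig,
    camera: CameraModel,
    rng: np.random.Generator | int,
    shot_noise: bool = True,
    clip_outside: bool = True,
    bg_photons_per_px: float = 0.0,
) -> FrameStack:
    """Render the full noisy camera sequence.

    Per frame: expected photons (PSFs plus a uniform diffuse background of
    ``bg_photons_per_px``) -> photoelectrons (QE, Poisson shot noise) ->
    EM register (Gamma with mean gain) -> counts -> Gaussian read noise ->
    baseline offset -> non-negative uint16 counts.

    With ``shot_noise=False`` and ``readout_noise_rms=0`` the output is the
    deterministic expectation (float, not rounded), which the flux tests use.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    w, h = optics.field_px
    fw, fh = optics.field_nm
    if not clip_outside:
        pos = traces.positions
        act = np.unique(traces.active_emitter) if len(traces.active_emitter) else []
        for e in act:
            x, y = pos[e]
            if not (0 <= x <= fw and 0 <= y <= fh):
                raise ValueError(f"emitter {e} at ({x:.0f}, {y:.0f}) nm outside field")
    deterministic = not shot_noise and camera.readout_noise_rms == 0
    frames = np.empty((traces.n_frames, h, w), dtype=float)
    for f in range(traces.n_frames):
        exp_photons = expected_photon_image(traces, optics, f) + bg_photons_per_px
        exp_pe = exp_photons * camera.quantum_efficiency
        if shot_noise:
            pe = rng.poisson(exp_pe).astype(float)
        else:
            pe = exp_pe
        if camera.em_gain > 1 and shot_noise:
            out = np.zeros_like(pe)
            nz = pe > 0
            out[nz] = rng.gamma(pe[nz], camera.em_gain)
        else:
            out = pe * camera.em_gain
        counts = out * camera.counts_per_photoelectron
        if camera.readout_noise_rms > 0:
            counts = counts + rng.normal(0, camera.readout_noise_rms, counts.shape)
        frames[f] = counts + camera.baseline_offset
    meta = {
        "optics": optics,
        "camera": camera,
        "deterministic": deterministic,
    }
    if deterministic:
        return FrameStack(frames, optics.pixel_size_nm, meta)
    return FrameStack(
        np.clip(np.rint(frames), 0, 65535).astype(np.uint16),
        optics.pixel_size_nm,
        meta,
    )


def simulate_acquisition(
    geometry: SampleGeometry,
    optics: OpticsConfig,
    camera: CameraModel,
    photophysics: PhotophysicsModel,
    n_frames: int,
    tagging_density_per_nm2: float = 0.5,
    seed: int | np.random.Generator = 0,
    bg_photons_per_px: float = 2.0,
) -> tuple[FrameStack, EmitterTraces]:
    """Seed, blink and render in one call; the standard entry point.

    The default diffuse background of 2 photons per pixel per frame models
    cellular autofluorescence; pass 0 for an idealized dark specimen.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    positions = seed_emitters(geometry, tagging_density_per_nm2, rng)
    traces = simulate_blinking(positions, photophysics, n_frames, rng)
    stack = render_frames(traces, optics, camera, rng, bg_photons_per_px=bg_photons_per_px)
    return stack, traces
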
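"""Formats, configuration, seed plumbing and deterministic fixtures.

Localization tables use the ThunderSTORM-compatible CSV dialect (bracketed
unit suffixes in the header, e.g. ``x [nm]``); image sequences are
multi-page TIFF with the pixel size carried in a JSON description tag.  The
fixture factory produces the small, fully simulated bundles (stack +
ground-truth sidecar + config) every downstream module is tested against,
so no external data is ever needed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import SampleGeometry
from .simulate import (
    CameraModel,
    EmitterTraces,
    FrameStack,
    OpticsConfig,
    PhotophysicsModel,
    make_structure,
    simulate_acquisition,
)

__all__ = [
    "substream",
    "read_localizations",
    "write_localizations",
    "read_stack",
    "write_stack",
    "FixtureBundle",
    "make_fixture",
    "RunConfig",
]

# internal column name <-> ThunderSTORM-style header
_HEADER_MAP = {
    "id": "id",
    "frame": "frame",
    "x_nm": "x [nm]",
    "y_nm": "y [nm]",
    "sigma_nm": "sigma [nm]",
    "intensity_photon": "intensity [photon]",
    "offset_photon": "offset [photon]",
    "bkgstd_photon": "bkgstd [photon]",
    "uncertainty_nm": "uncertainty [nm]",
}
_REVERSE_MAP = {v: k for k, v in _HEADER_MAP.items()}
_REQUIRED = ("frame", "x_nm", "y_nm")


def substream(root_seed: int, name: str) -> np.random.Generator:
    """Named RNG substream derived from one root seed.

    Every stochastic stage (simulate / split / forest / sample ...) draws
    from its own named stream, so stages can be re-run independently without
    perturbing each other.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(root_seed), zlib.crc32(name.encode())])
    )


def write_localizations(table: pd.DataFrame, path: str | Path) -> None:
    """Write a localization table as ThunderSTORM-dialect CSV.

    Known columns get the standard bracketed-unit headers; unknown columns
    are written verbatim so round trips are lossless.
    """
    out = table.rename(columns=_HEADER_MAP)
    out.to_csv(path, index=False)


def read_localizations(path: str | Path) -> pd.DataFrame:
    """Read a ThunderSTORM-compatible CSV into internal column names.

    Bracketed unit suffixes are parsed; ``[um]`` columns are converted to nm.
    Missing frame/x/y columns or non-numeric rows raise with a clear message.
    """
    df = pd.read_csv(path, dtype=str)
    rename: dict[str, str] = {}
    scale: dict[str, float] = {}
    for col in df.columns:
        c = col.strip()
        if c in _REVERSE_MAP:
            rename[col] = _REVERSE_MAP[c]
        elif c.endswith(" [um]"):
            base = c[: -len(" [um]")]
            target = {"x": "x_nm", "y": "y_nm", "sigma": "sigma_nm", "uncertainty": "uncertainty_nm"}.get(
                base, base + "_nm"
            )
            rename[col] = target
            scale[target] = 1000.0
        elif c.endswith(" [nm]"):
            rename[col] = c[: -len(" [nm]")] + "_nm"
        else:
            rename[col] = c
    df = df.rename(columns=rename)
    for req in _REQUIRED:
        if req not in df.columns:
            raise ValueError(f"localization file is missing required column {req!r}")
    numeric_cols = set(_HEADER_MAP) | set(scale) | {
        c for c in df.columns if c.endswith(("_nm", "_photon"))
    }
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df[col][vals.isna() & df[col].notna()]
        if len(bad):
            if col in numeric_cols:
                raise ValueError(
                    f"malformed value {bad.iloc[0]!r} in column {col!r} "
                    f"at data row {int(bad.index[0]) + 1}"
                )
            continue  # free-text column (e.g. quality labels): keep as is
        df[col] = vals
    for col, k in scale.items():
        df[col] = df[col] * k
    df["frame"] = df["frame"].astype(int)
    return df


def write_stack(stack: FrameStack, path: str | Path) -> None:
    """Write a frame stack as multi-page 16-bit TIFF with pixel-size metadata."""
    data = stack.data
    if data.dtype != np.uint16:
        data = np.clip(np.rint(data), 0, 65535).astype(np.uint16)
    desc = json.dumps({"pixel_size_nm": stack.pixel_size_nm})
    tifffile.imwrite(path, data, description=desc)


def read_stack(path: str | Path, pixel_size_nm: float | None = None) -> FrameStack:
    """Read a multi-page TIFF into a :class:`FrameStack`.

    The pixel size is taken from the JSON description tag written by
    :func:`write_stack`; if absent, it must be supplied explicitly.
    """
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description or ""
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError("expected a 2D image or a 3D stack of equal-shape pages")
    px = pixel_size_nm
    if px is None:
        try:
            px = float(json.loads(desc)["pixel_size_nm"])
        except (json.JSONDecodeError, KeyError, TypeError):
            raise ValueError(
                "TIFF carries no pixel-size metadata; pass pixel_size_nm explicitly"
            )
    return FrameStack(data, px, {"source": str(path)})


@dataclass
class FixtureBundle:
    """A deterministic simulated dataset: stack, truth sidecar and config."""

    name: str
    stack: FrameStack
    traces: EmitterTraces
    sidecar: pd.DataFrame
    geometry: SampleGeometry
    optics: OpticsConfig
    camera: CameraModel
    photophysics: PhotophysicsModel
    config: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_stack(self.stack, out / f"{self.name}.tif")
        self.sidecar.to_csv(out / f"{self.name}_truth.csv", index=False)
        with open(out / f"{self.name}_config.yaml", "w") as fh:
            yaml.safe_dump(self.config, fh, sort_keys=True)


# Fixture study conditions.  Structure sizes are the canonical 0D/1D/2D test
# shapes; tagging density is 0.5 nm^-2 except on the 2D plane, where it is
# reduced so the emitter pool stays tractable while remaining far larger
# than the number of activations (the large-pool regime is preserved).
_FIXTURES = {
    "point_0d": dict(kind="point", tagging=0.5, field_px=(16, 16)),
    "strand_1d": dict(kind="strand", tagging=0.5, field_px=(40, 40)),
    "plane_2d": dict(kind="plane", tagging=0.01, field_px=(40, 40)),
    "vesicles": dict(kind="vesicles", tagging=0.5, field_px=(16, 16)),
}
_SCALE_FRAMES = {"ci": 200, "full": 1000}


def make_fixture(
    name: str,
    scale: str = "ci",
    seed: int = 0,
    p_act: float | None = None,
    n_frames: int | None = None,
    bg_photons_per_px: float = 2.0,
) -> FixtureBundle:
    """Build one of the canonical simulated bundles.

    Names: ``point_0d`` (8x8 nm), ``strand_1d`` (8x3520 nm),
    ``plane_2d`` (3520x3520 nm), ``vesicles`` (four 30 nm discs).  Scale
    ``ci`` renders 200 frames, ``full`` 1000.  ``p_act`` defaults to the
    value that puts the measured activation density near the theoretical
    optimum 1/E for the structure (with E evaluated at r = 440 nm).
    """
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    if n_frames is None:
        if scale not in _SCALE_FRAMES:
            raise ValueError(f"unknown scale {scale!r}; choose from {sorted(_SCALE_FRAMES)}")
        n_frames = _SCALE_FRAMES[scale]
    spec = _FIXTURES[name]
    optics = OpticsConfig(field_px=spec["field_px"])
    fw, fh = optics.field_nm
    geometry = make_structure(spec["kind"], center=(fw / 2, fh / 2))
    camera = CameraModel()
    if p_act is None:
        from .geometry import exclusion_area

        e = exclusion_area(geometry.exclusion_model(440.0))
        a_star = 1.0 / e
        # steady-state active fraction ~ p_act * mean on-time (2 frames)
        p_act = min(0.5, a_star / (spec["tagging"] * 2.0))
    photophysics = PhotophysicsModel(p_act=p_act)
    rng = substream(seed, f"fixture/{name}")
    stack, traces = simulate_acquisition(
        geometry,
        optics,
        camera,
        photophysics,
        n_frames,
        tagging_density_per_nm2=spec["tagging"],
        seed=rng,
        bg_photons_per_px=bg_photons_per_px,
    )
    config = {
        "fixture": name,
        "scale": scale,
        "seed": seed,
        "n_frames": n_frames,
        "p_act": float(p_act),
        "tagging_density_per_nm2": spec["tagging"],
        "bg_photons_per_px": bg_photons_per_px,
        "optics": {
            "wavelength_nm": optics.wavelength_nm,
            "numerical_aperture": optics.numerical_aperture,
            "pixel_size_nm": optics.pixel_size_nm,
            "photons_full_frame": optics.photons_full_frame,
            "field_px": list(optics.field_px),
        },
        "camera": {
            "em_gain": camera.em_gain,
            "readout_noise_rms": camera.readout_noise_rms,
            "baseline_offset": camera.baseline_offset,
            "quantum_efficiency": camera.quantum_efficiency,
            "counts_per_photoelectron": camera.counts_per_photoelectron,
        },
    }
    sidecar = traces.sidecar(optics.photons_full_frame)
    return FixtureBundle(
        name=name,
        stack=stack,
        traces=traces,
        sidecar=sidecar,
        geometry=geometry,
        optics=optics,
        camera=camera,
        photophysics=photophysics,
        config=config,
    )


@dataclass
class RunConfig:
    """Resolved run configuration with full provenance.

    Every defaulted value is serialized back out, so a run can be reproduced
    from its config file alone; the root seed feeds the named substreams of
    :func:`substream`.
    """

    seed: int
    sections: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"seed": self.seed, **self.sections}, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict) or "seed" not in data:
            raise ValueError("config must be a mapping with a mandatory 'seed' key")
        seed = data.pop("seed")
        return cls(seed=int(seed), sections=data)
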
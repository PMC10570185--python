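"""Image functions, config serialization, state files and animation export.

* Uploaded rasters become spatial functions I_S(x, y) / I_T(x, y): greyscale
  luminance (Rec. 601 weights 0.299 R + 0.587 G + 0.114 B), normalised to
  [0, 1], sampled bilinearly and clamped at the borders.  Image x spans
  [0, Lx]; the top row of the picture maps to y = Ly (y points up in the
  model, down in the raster).
* Config documents are JSON.  The ``share`` profile reproduces the current
  simulation given the specified initial conditions — it excludes brush
  events (and never contains image pixels, only paths); the ``full`` profile
  keeps everything and round-trips bit-identically.
* States and checkpoints are HDF5 containers tagged with the config hash.
* Animations export as zero-padded PNG sequences (deterministic bytes) or a
  GIF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .model import ConfigError, DomainSpec, SimulationConfig
from .stepping import FieldState

__all__ = [
    "ImageFunction",
    "load_image_function",
    "serialize_config",
    "deserialize_config",
    "save_config",
    "load_config",
    "save_state",
    "load_state",
    "export_animation",
]

REC601 = np.array([0.299, 0.587, 0.114])


@dataclass
class ImageFunction:
    """Luminance raster in [0, 1] exposed as a continuous function of (x, y)."""

    luminance: np.ndarray  # (H, W), row 0 = top of the picture
    Lx: float
    Ly: float

    def sampler(self, x, y):
        lum = self.luminance
        H, W = lum.shape
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        # pixel-centre alignment; top row = y_max
        px = np.clip(x / self.Lx * W - 0.5, 0.0, W - 1.0)
        py = np.clip((1.0 - y / self.Ly) * H - 0.5, 0.0, H - 1.0)
        x0 = np.floor(px).astype(int)
        y0 = np.floor(py).astype(int)
        x1 = np.minimum(x0 + 1, W - 1)
        y1 = np.minimum(y0 + 1, H - 1)
        fx = px - x0
        fy = py - y0
        top = lum[y0, x0] * (1 - fx) + lum[y0, x1] * fx
        bot = lum[y1, x0] * (1 - fx) + lum[y1, x1] * fx
        return np.clip(top * (1 - fy) + bot * fy, 0.0, 1.0)


def load_image_function(path, domain: DomainSpec | None = None) -> ImageFunction:
    """Read a PNG/JPEG into an :class:`ImageFunction` over the domain."""
    try:
        arr = iio.imread(path)
    except Exception as err:
        raise IOError(f"cannot read image {path!r}: {err}") from err
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        lum = arr @ REC601
    else:
        lum = arr
    if lum.max() > 1.0:
        lum = lum / 255.0
    lum = np.clip(lum, 0.0, 1.0)
    Lx = domain.Lx if domain is not None else 1.0
    Ly = (domain.Ly if domain.dimension == 2 else 1.0) if domain is not None else 1.0
    return ImageFunction(luminance=lum, Lx=float(Lx), Ly=float(Ly or 1.0))


# ---------------------------------------------------------------------------
# config serialization

def serialize_config(cfg: SimulationConfig, profile: str = "share") -> str:
    """JSON text for a config.  ``share`` omits brush events (the shareable
    description covers equations/IC/settings, not anything painted);
    ``full`` keeps everything."""
    if profile not in ("share", "full"):
        raise ValueError(f"unknown profile {profile!r}")
    doc = cfg.to_dict()
    if profile == "share":
        doc.pop("brush_events")
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def deserialize_config(text: str) -> SimulationConfig:
    """Parse JSON into a config; unknown fields are rejected by name."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as err:
        raise ConfigError(f"not valid JSON: {err}") from err
    if not isinstance(doc, dict):
        raise ConfigError("top-level JSON value must be an object")
    return SimulationConfig.from_dict(doc)


def save_config(cfg: SimulationConfig, path, profile: str = "full") -> None:
    Path(path).write_text(serialize_config(cfg, profile=profile))


def load_config(path) -> SimulationConfig:
    return deserialize_config(Path(path).read_text())


# ---------------------------------------------------------------------------
# state files

def save_state(state: FieldState, path, cfg_hash: str = "") -> None:
    """Write all species fields plus the clock to an HDF5 container."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["t"] = state.t
        h5.attrs["step_index"] = state.step_index
        h5.attrs["config_hash"] = cfg_hash
        grp = h5.create_group("fields")
        for name, arr in state.fields.items():
            grp.create_dataset(name, data=arr)


def load_state(path) -> tuple[FieldState, str]:
    import h5py

    with h5py.File(path, "r") as h5:
        fields = {name: np.array(ds) for name, ds in h5["fields"].items()}
        state = FieldState(
            fields=fields,
            t=float(h5.attrs["t"]),
            step_index=int(h5.attrs["step_index"]),
        )
        return state, str(h5.attrs.get("config_hash", ""))


# ---------------------------------------------------------------------------
# animation export

def export_animation(frames, path, fps: int = 25) -> list:
    """Write RGB frames.  A directory (or a path without suffix) receives a
    zero-padded PNG sequence ``frame_0000.png``...; a ``.gif`` path receives
    an animated GIF; a ``.png`` path must have exactly one frame.  PNG bytes
    are deterministic.  Returns the list of files written."""
    frames = [np.asarray(f) for f in frames]
    if not frames:
        raise ValueError("no frames to export")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"frames differ in shape: {sorted(shapes)}")
    path = Path(path)
    if path.suffix.lower() == ".gif":
        iio.imwrite(path, frames, duration=1000.0 / fps, loop=0)
        return [path]
    if path.suffix.lower() == ".png":
        if len(frames) != 1:
            raise ValueError("a .png path can hold exactly one frame")
        iio.imwrite(path, frames[0])
        return [path]
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for i, f in enumerate(frames):
        p = path / f"frame_{i:04d}.png"
        iio.imwrite(p, f)
        written.append(p)
    return written
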
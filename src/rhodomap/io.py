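"""Reading and writing movies, maps, masks and manifests.

Movies travel as multi-page TIFF stacks with a YAML sidecar holding the
time grid and acquisition geometry; parameter maps are 32-bit float
TIFFs; vessel masks are 8-bit TIFFs; multi-spectral sets are described by
a YAML manifest listing one image file per band with its wavelengths and
weight.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .model import AFMovie, Geometry, SpectralBand
from .mp import MPImageSet

__all__ = [
    "save_movie", "load_movie", "save_map", "load_map",
    "save_mask", "load_mp_manifest",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def save_movie(movie: AFMovie, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, movie.frames.astype(np.float32))
    meta = {
        "times": [float(t) for t in movie.times],
        "t0": float(movie.t0),
    }
    if movie.geometry is not None:
        meta["geometry"] = {
            "fov_deg": float(movie.geometry.fov_deg),
            "center": [float(c) for c in movie.geometry.center],
            "px_per_deg": float(movie.geometry.px_per_deg),
        }
    _sidecar(path).write_text(yaml.safe_dump(meta))


def load_movie(path) -> AFMovie:
    path = Path(path)
    frames = tifffile.imread(path)
    meta = yaml.safe_load(_sidecar(path).read_text())
    if "times" in meta:
        times = np.asarray(meta["times"], dtype=float)
    else:
        rate = float(meta["frame_rate"])
        times = np.arange(frames.shape[0]) / rate
    geom = None
    if "geometry" in meta:
        g = meta["geometry"]
        geom = Geometry(fov_deg=float(g["fov_deg"]),
                        center=tuple(g["center"]),
                        px_per_deg=float(g["px_per_deg"]))
    return AFMovie(frames=frames, times=times,
                   t0=float(meta.get("t0", 0.0)), geometry=geom)


def save_map(arr: np.ndarray, path) -> None:
    tifffile.imwrite(Path(path), np.asarray(arr, dtype=np.float32))


def load_map(path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(float)


def save_mask(mask: np.ndarray, path) -> None:
    tifffile.imwrite(Path(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def load_mp_manifest(path) -> MPImageSet:
    """Build an MPImageSet from a YAML manifest.

    Manifest format: a list of entries ``{file, excitation_nm,
    emission_nm, weight}``; image paths are resolved relative to the
    manifest.
    """
    path = Path(path)
    entries = yaml.safe_load(path.read_text())
    images, bands, weights = [], [], []
    for e in entries:
        images.append(np.asarray(iio.imread(path.parent / e["file"]), dtype=float))
        bands.append(SpectralBand(float(e["excitation_nm"]),
                                  float(e["emission_nm"])))
        weights.append(float(e["weight"]))
    return MPImageSet(images=images, bands=bands, weights=np.asarray(weights))
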
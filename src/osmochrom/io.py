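"""Plain-text I/O for traces, curves, profiles and images.

Time series travel as two-column TSV with ``# key=value`` comment headers
carrying ground-truth or fit metadata.  Images travel as single-channel TIFF
(via tifffile) or as portable whitespace text grids; masks as 0/1 grids of
identical shape.
"""

from __future__ import annotations

import numpy as np
import tifffile

from .assays import IncorporationCurve
from .chromatin import GelLaneProfile, NuclearImage
from .flip import FLIPTrace

__all__ = [
    "write_series_tsv",
    "read_series_tsv",
    "write_trace",
    "read_trace",
    "write_curve",
    "read_curve",
    "write_profile",
    "read_profile",
    "write_image",
    "read_image",
]


def write_series_tsv(path, x, y, metadata: dict | None = None,
                     columns: tuple[str, str] = ("time", "intensity")) -> None:
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}={v}\n")
        fh.write(f"{columns[0]}\t{columns[1]}\n")
        for xi, yi in zip(x, y):
            fh.write(f"{float(xi):.17g}\t{float(yi):.17g}\n")


def read_series_tsv(path) -> tuple[np.ndarray, np.ndarray, dict[str, str]]:
    meta: dict[str, str] = {}
    xs, ys = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            a, b = line.split("\t")[:2]
            try:
                xs.append(float(a))
                ys.append(float(b))
            except ValueError:
                continue  # header row
    return np.asarray(xs), np.asarray(ys), meta


def write_trace(path, trace: FLIPTrace, metadata: dict | None = None) -> None:
    write_series_tsv(path, trace.times, trace.intensities, metadata)


def read_trace(path) -> tuple[FLIPTrace, dict[str, str]]:
    t, y, meta = read_series_tsv(path)
    return FLIPTrace(t, y), meta


def write_curve(path, curve: IncorporationCurve, metadata: dict | None = None) -> None:
    write_series_tsv(path, curve.times, curve.signal, metadata, columns=("time_min", "signal"))


def read_curve(path) -> tuple[IncorporationCurve, dict[str, str]]:
    t, s, meta = read_series_tsv(path)
    return IncorporationCurve(t, s), meta


def write_profile(path, profile: GelLaneProfile, metadata: dict | None = None) -> None:
    write_series_tsv(
        path, profile.positions, profile.intensities, metadata, columns=("log10_bp", "intensity")
    )


def read_profile(path) -> tuple[GelLaneProfile, dict[str, str]]:
    p, i, meta = read_series_tsv(path)
    return GelLaneProfile(p, i), meta


def write_image(path, image: NuclearImage) -> None:
    """Write pixels as TIFF (``.tif``/``.tiff``) or a text grid; the mask goes
    alongside with a ``.mask`` suffix inserted before the extension."""
    path = str(path)
    stem, dot, ext = path.rpartition(".")
    mask_path = f"{stem}.mask.{ext}" if dot else f"{path}.mask"
    if ext.lower() in ("tif", "tiff"):
        tifffile.imwrite(path, image.pixels.astype(np.float32))
        tifffile.imwrite(mask_path, image.mask.astype(np.uint8))
    else:
        np.savetxt(path, image.pixels)
        np.savetxt(mask_path, image.mask.astype(int), fmt="%d")


def read_image(path) -> NuclearImage:
    path = str(path)
    stem, dot, ext = path.rpartition(".")
    mask_path = f"{stem}.mask.{ext}" if dot else f"{path}.mask"
    if ext.lower() in ("tif", "tiff"):
        px = tifffile.imread(path).astype(float)
        mk = tifffile.imread(mask_path).astype(bool)
    else:
        px = np.loadtxt(path)
        mk = np.loadtxt(mask_path).astype(bool)
    return NuclearImage(px, mk)
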
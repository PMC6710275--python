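"""Image I/O, maximum-intensity projection and exclusion regions.

A field of view is represented by :class:`MultiChannelField`: one 2-D image
per channel (already z-projected), a physical pixel size, a channel→probe
map and an optional exclusion mask drawn by a reviewer over artefactual
regions.  Physical coordinates follow the pixel-centre convention:
``coordinate_um = (index + 0.5) * pixel_size_um`` with x along columns and
y along rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import shapely
import tifffile
from shapely.geometry import Polygon, shape as shapely_shape

#: probe value in a channel map that designates the nuclear counterstain
COUNTERSTAIN = "nuclear"


@dataclass
class MultiChannelField:
    """One 2-D multi-channel field of view with normalized intensities."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    channel_probe_map: dict[str, str]
    exclusion_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {im.shape for im in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels have mismatched shapes: {shapes}")
        for name, im in self.channels.items():
            if im.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2-D")
        if self.exclusion_mask is not None and self.channels:
            if self.exclusion_mask.shape != self.shape:
                raise ValueError("exclusion_mask shape differs from channels")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def counterstain(self) -> np.ndarray:
        """The nuclear counterstain channel (DAPI)."""
        for ch, probe in self.channel_probe_map.items():
            if probe == COUNTERSTAIN:
                return self.channels[ch]
        raise KeyError("no channel mapped to the nuclear counterstain")

    @property
    def probe_channels(self) -> dict[str, np.ndarray]:
        """Map probe name → channel image, excluding the counterstain."""
        return {
            probe: self.channels[ch]
            for ch, probe in self.channel_probe_map.items()
            if probe != COUNTERSTAIN
        }

    def um_to_px(self, coord_um: Sequence[float]) -> tuple[int, int]:
        """Convert an (x, y) µm coordinate to a (row, col) pixel index."""
        x, y = coord_um
        s = self.pixel_size_um
        return int(np.floor(y / s)), int(np.floor(x / s))

    def is_excluded(self, coord_um: Sequence[float]) -> bool:
        """True when the µm coordinate falls inside the exclusion mask."""
        if self.exclusion_mask is None:
            return False
        r, c = self.um_to_px(coord_um)
        nr, nc = self.exclusion_mask.shape
        if not (0 <= r < nr and 0 <= c < nc):
            return False
        return bool(self.exclusion_mask[r, c])


def _normalize(im: np.ndarray) -> np.ndarray:
    """Bring a channel onto a [0, 1] scale.

    Data already within [0, 1] (a calibrated float image) passes through
    unchanged so that fixed intensity thresholds — notably the 0.15 copy
    intensity criterion — keep the same meaning across fields; anything
    else (integer camera counts, arbitrary float ranges) is min-max
    rescaled per channel.
    """
    im = np.asarray(im, dtype=np.float64)
    lo, hi = float(im.min()), float(im.max())
    if 0.0 <= lo and hi <= 1.0:
        return im
    if hi == lo:
        return np.zeros_like(im)
    return (im - lo) / (hi - lo)


def load_and_project(
    path: str | Path,
    channel_map: Mapping[str, str],
    pixel_size_um: float,
    normalize: bool = True,
) -> MultiChannelField:
    """Read a TIFF / OME-TIFF, max-project over z, normalize per channel.

    ``channel_map`` maps channel names (in page order) to probe names; the
    counterstain channel maps to :data:`COUNTERSTAIN`.  Accepted layouts:
    2-D single plane (one channel), 3-D as (C, Y, X) when the leading axis
    matches ``len(channel_map)`` else (Z, Y, X) for a single channel, and
    4-D as (C, Z, Y, X) or (Z, C, Y, X).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    arr = tifffile.imread(path)
    names = list(channel_map)
    n_ch = len(names)
    if n_ch == 0:
        raise ValueError(f"{path}: empty channel map")

    if arr.ndim == 2:
        if n_ch != 1:
            raise ValueError(
                f"{path}: single-plane image but {n_ch} channels mapped"
            )
        planes = [arr]
    elif arr.ndim == 3:
        if arr.shape[0] == n_ch:
            planes = [arr[i] for i in range(n_ch)]
        elif n_ch == 1:
            planes = [arr.max(axis=0)]  # z-stack, single channel
        else:
            raise ValueError(
                f"{path}: 3-D image with leading axis {arr.shape[0]} does not "
                f"match the {n_ch} mapped channels"
            )
    elif arr.ndim == 4:
        if arr.shape[0] == n_ch:
            planes = [arr[i].max(axis=0) for i in range(n_ch)]
        elif arr.shape[1] == n_ch:
            planes = [arr[:, i].max(axis=0) for i in range(n_ch)]
        else:
            raise ValueError(
                f"{path}: cannot locate a channel axis of size {n_ch} "
                f"in shape {arr.shape}"
            )
    else:
        raise ValueError(f"{path}: unsupported image dimensionality {arr.ndim}")

    channels = {}
    for name, plane in zip(names, planes):
        plane = np.asarray(plane, dtype=np.float64)
        channels[name] = _normalize(plane) if normalize else plane
    return MultiChannelField(
        channels=channels,
        pixel_size_um=pixel_size_um,
        channel_probe_map=dict(channel_map),
    )


def save_field(field_: MultiChannelField, path: str | Path) -> None:
    """Write a field as a multi-page float32 TIFF, one page per channel."""
    stack = np.stack(
        [field_.channels[ch] for ch in field_.channel_probe_map], axis=0
    ).astype(np.float32)
    tifffile.imwrite(path, stack)


def _as_polygon(poly) -> Polygon:
    if isinstance(poly, Polygon):
        p = poly
    else:
        p = Polygon(poly)
    if not p.is_valid:
        raise ValueError(f"malformed (self-intersecting?) polygon: {p.wkt[:80]}")
    return p


def rasterize_polygons(
    polygons: Sequence,
    shape: tuple[int, int],
    pixel_size_um: float,
) -> np.ndarray:
    """Rasterize µm-space polygons onto a pixel grid (pixel-centre test)."""
    mask = np.zeros(shape, dtype=bool)
    if not polygons:
        return mask
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    xs = (cols + 0.5) * pixel_size_um
    ys = (rows + 0.5) * pixel_size_um
    for poly in polygons:
        p = _as_polygon(poly)
        inside = shapely.contains_xy(p, xs.ravel(), ys.ravel())
        mask |= inside.reshape(shape)
    return mask


def apply_exclusion(field_: MultiChannelField, polygons: Sequence) -> MultiChannelField:
    """Attach an exclusion mask rasterized from µm-space polygons.

    Downstream stages drop nuclei and spots whose centroid falls inside
    the mask.  An empty polygon list returns the field unchanged.
    """
    if not polygons:
        return field_
    mask = rasterize_polygons(polygons, field_.shape, field_.pixel_size_um)
    if field_.exclusion_mask is not None:
        mask = mask | field_.exclusion_mask
    return replace(field_, exclusion_mask=mask)


def read_exclusion_geojson(path: str | Path) -> list[Polygon]:
    """Read exclusion polygons (µm coordinates) from a GeoJSON file."""
    with open(path) as fh:
        gj = json.load(fh)
    polys: list[Polygon] = []
    if gj.get("type") == "FeatureCollection":
        geoms = [f["geometry"] for f in gj.get("features", [])]
    elif gj.get("type") == "Feature":
        geoms = [gj["geometry"]]
    else:
        geoms = [gj]
    for g in geoms:
        shp = shapely_shape(g)
        if shp.geom_type == "Polygon":
            polys.append(_as_polygon(shp))
        elif shp.geom_type == "MultiPolygon":
            polys.extend(_as_polygon(p) for p in shp.geoms)
        else:
            raise ValueError(f"unsupported exclusion geometry: {shp.geom_type}")
    return polys
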
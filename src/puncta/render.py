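"""Graphical mark-up of per-cell expression classes.

Nuclei are filled with a 5-step black-to-blue ramp by expression class
(0+ = black, increasingly brighter blue for 1+..4+), overlaid on the
dimmed counterstain, mirroring pathology mark-up overlays.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

from .cells import CellRecord
from .io import MultiChannelField

#: RGB fills for classes 0..4 (black → bright blue)
CLASS_COLORS = (
    (0, 0, 0),
    (0, 20, 90),
    (20, 60, 150),
    (70, 120, 210),
    (140, 190, 255),
)


def render_markup(
    field: MultiChannelField,
    cells: Sequence[CellRecord],
    probe: str,
    out_path: str | Path | None = None,
) -> np.ndarray:
    """Render the class mark-up as an RGB uint8 image (optionally to PNG)."""
    known = {p for c in cells for p in c.bins}
    if cells and probe not in known:
        raise KeyError(f"no bin classes for probe {probe!r} on these cells")
    dapi = field.counterstain
    base = np.clip(dapi * 0.6 * 255, 0, 255).astype(np.uint8)
    rgb = np.stack([base, base, base], axis=-1)
    for cell in cells:
        if cell.nucleus is None:
            continue
        cls = cell.bins[probe]
        coords = cell.nucleus.coords
        rgb[coords[:, 0], coords[:, 1]] = CLASS_COLORS[min(cls, len(CLASS_COLORS) - 1)]
    if out_path is not None:
        iio.imwrite(Path(out_path), rgb, extension=".png")
    return rgb
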
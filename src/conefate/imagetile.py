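"""Two-channel image tile container with TIFF + JSON-sidecar IO.

Channel 0 carries S-opsin signal, channel 1 M-opsin signal. The dorsal-
ventral axis runs along image rows (row 0 = dorsal edge) so that
``y_um = row * pixel_size_um``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

CHANNEL_INDEX = {"S": 0, "M": 1}


@dataclass
class ImageTile:
    pixels: np.ndarray  # shape (2, H, W), non-negative
    pixel_size_um: float
    orientation: str = "dv_rows"  # D-V axis along rows, dorsal at row 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3 or self.pixels.shape[0] != 2:
            raise ValueError("pixels must have shape (2, H, W)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        return self.pixels[CHANNEL_INDEX[name]]


def write_tile(tile: ImageTile, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, tile.pixels.astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = {
        "pixel_size_um": tile.pixel_size_um,
        "orientation": tile.orientation,
        **tile.metadata,
    }
    sidecar.write_text(json.dumps(meta, indent=1, default=float))


def read_tile(path: str | Path) -> ImageTile:
    path = Path(path)
    pixels = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    pixel_size = float(meta.pop("pixel_size_um", 1.0))
    orientation = meta.pop("orientation", "dv_rows")
    return ImageTile(np.asarray(pixels), pixel_size, orientation, meta)
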
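"""Shared per-cell table schema and CSV round-trip.

Every stage of the package (synthetic generation, segmentation, simulation,
profiling) produces or consumes a :class:`CellTable`: one row per cone with
its position in the retinal strip, outer-segment area and S-/M-opsin
intensities, plus an analysis-assigned class label and (for synthetic or
simulated cells) the ground-truth fate.

Coordinate convention: ``y_um`` runs along the dorsal-ventral axis with 0 at
the dorsal edge and increasing ventrally; ``x_um`` is the temporal-nasal
coordinate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: allowed analysis class labels
CLASS_LABELS = ("S_ONLY", "M_ONLY", "COEXPRESSING", "NONE")
#: allowed ground-truth fate labels
FATE_LABELS = ("S_ONLY", "CEC", "UNKNOWN")

CSV_COLUMNS = [
    "cell_id",
    "x_um",
    "y_um",
    "area_um2",
    "s_intensity",
    "m_intensity",
    "class_label",
    "fate_truth",
]


@dataclass
class CellRecord:
    """A single cone photoreceptor observation."""

    cell_id: int
    x_um: float
    y_um: float
    area_um2: float
    s_intensity: float
    m_intensity: float
    class_label: str = "NONE"
    fate_truth: str = "UNKNOWN"


@dataclass
class CellTable:
    """Table of cones plus provenance metadata.

    ``data`` is a pandas DataFrame with the columns of :data:`CSV_COLUMNS`.
    ``metadata`` records at least ``source`` (``experimental``, ``synthetic``
    or ``simulated``) and the strip dimensions in micrometres.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CSV_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"CellTable missing required columns: {missing}")
        if self.data["cell_id"].duplicated().any():
            raise ValueError("cell_ids must be unique")
        for col in ("s_intensity", "m_intensity"):
            if (self.data[col] < 0).any():
                raise ValueError(f"{col} must be non-negative")
        length = self.metadata.get("strip_length_um")
        if length is not None and len(self.data) and not self.metadata.get("aligned", False):
            y = self.data["y_um"].to_numpy()
            if y.min() < -1e-9 or y.max() > length + 1e-9:
                raise ValueError("y_um outside [0, strip_length_um]")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def strip_length_um(self) -> float | None:
        return self.metadata.get("strip_length_um")

    def copy(self) -> "CellTable":
        return CellTable(self.data.copy(), dict(self.metadata))

    @classmethod
    def from_records(cls, records: Iterable[CellRecord], metadata: dict | None = None) -> "CellTable":
        rows = [vars(r) for r in records]
        df = pd.DataFrame(rows, columns=CSV_COLUMNS)
        return cls(df, metadata or {})

    @classmethod
    def from_arrays(
        cls,
        x_um,
        y_um,
        s_intensity,
        m_intensity,
        area_um2=None,
        class_label=None,
        fate_truth=None,
        metadata: dict | None = None,
    ) -> "CellTable":
        n = len(np.atleast_1d(x_um))
        df = pd.DataFrame(
            {
                "cell_id": np.arange(n, dtype=np.int64),
                "x_um": np.asarray(x_um, dtype=float),
                "y_um": np.asarray(y_um, dtype=float),
                "area_um2": np.full(n, 20.0) if area_um2 is None else np.asarray(area_um2, dtype=float),
                "s_intensity": np.asarray(s_intensity, dtype=float),
                "m_intensity": np.asarray(m_intensity, dtype=float),
                "class_label": np.full(n, "NONE", dtype=object) if class_label is None else np.asarray(class_label, dtype=object),
                "fate_truth": np.full(n, "UNKNOWN", dtype=object) if fate_truth is None else np.asarray(fate_truth, dtype=object),
            }
        )
        return cls(df, metadata or {})


_DTYPES = {
    "cell_id": np.int64,
    "x_um": float,
    "y_um": float,
    "area_um2": float,
    "s_intensity": float,
    "m_intensity": float,
    "class_label": object,
    "fate_truth": object,
}


def write_cell_table(table: CellTable, path: str | Path) -> None:
    """Write a CellTable as CSV plus a JSON metadata sidecar (``<path>.meta.json``)."""
    path = Path(path)
    table.data.to_csv(path, index=False, columns=CSV_COLUMNS)
    if table.metadata:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(table.metadata, indent=1, default=float))


def read_cell_table(path: str | Path) -> CellTable:
    """Read a CellTable CSV; raises a schema error naming any missing column."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cell table {path} missing required columns: {missing}")
    df = df[CSV_COLUMNS].astype(_DTYPES)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    metadata = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return CellTable(df, metadata)
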
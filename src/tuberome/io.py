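"""Reading and writing the pipeline's on-disk formats.

Volumes and masks travel as multi-page 16-bit TIFF stacks (one page per
slice) with a JSON sidecar holding spacing and provenance; tables travel
as TSV/CSV with a ``#``-prefixed provenance header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from tuberome.volumetry import SegmentationMask, VoxelVolume, _components_table

__all__ = [
    "write_volume",
    "read_volume",
    "write_mask",
    "read_mask",
    "write_table",
    "read_table",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(volume: VoxelVolume, path: str | Path) -> None:
    """Write a volume as a multi-page uint16 TIFF plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(volume.grey, dtype=np.uint16))
    meta = {
        "spacing_mm": volume.spacing,
        "shape": list(volume.shape),
        **{k: v for k, v in volume.meta.items() if _jsonable(v)},
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_volume(path: str | Path) -> VoxelVolume:
    path = Path(path)
    grey = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    spacing = float(meta.pop("spacing_mm"))
    meta.pop("shape", None)
    return VoxelVolume(grey=grey, spacing=spacing, meta=meta)


def write_mask(mask: SegmentationMask, path: str | Path) -> None:
    """Write mask labels as an integer TIFF stack."""
    tifffile.imwrite(Path(path), mask.labels.astype(np.int32))


def read_mask(path: str | Path) -> SegmentationMask:
    labels = tifffile.imread(Path(path)).astype(np.int32)
    return SegmentationMask(labels=labels, components=_components_table(labels))


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def write_table(
    table: pd.DataFrame,
    path: str | Path,
    provenance: dict | None = None,
    index: bool = True,
    sep: str = "\t",
) -> None:
    """Write a table with ``# key: value`` provenance header lines."""
    path = Path(path)
    with path.open("w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}: {value}\n")
        table.to_csv(fh, sep=sep, index=index, float_format="%.10g")


def read_table(path: str | Path, index_col=0, sep: str = "\t") -> pd.DataFrame:
    """Read a table written by :func:`write_table`, skipping provenance lines."""
    return pd.read_csv(Path(path), sep=sep, comment="#", index_col=index_col)
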
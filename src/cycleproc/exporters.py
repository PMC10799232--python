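"""Output writers: measurement CSV, native FCS 3.1, ImageJ ROI zip, outline
overlay and the analysis-ready output directory layout.

The FCS writer emits version 3.1 list-mode files with ``$DATATYPE=F`` (32-bit
little-endian floats) directly, so round-trip fidelity is testable without any
external converter. ROIs are written in the binary ImageJ ``.roi`` format
(magic ``Iout``, polygon type) inside a plain ZIP archive.
"""

from __future__ import annotations

import hashlib
import json
import struct
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from skimage.segmentation import find_boundaries

from .cells import CellRecord, LabelImage, PolygonROI

__all__ = [
    "MeasurementTable",
    "write_measurements_csv",
    "read_measurements_csv",
    "write_fcs",
    "write_roi_zip",
    "write_outline_overlay",
    "export_output_layout",
]


def intensity_column_name(cycle: int, channel: int, reporter: str) -> str:
    return f"cyc{cycle:02d}_ch{channel}_{reporter}"


@dataclass(frozen=True)
class MeasurementTable:
    """Per-cell measurements with a fixed column order.

    Columns: ``cell_id, x, y, size`` then one intensity column per non-blank
    (cycle, channel) named ``cyc{NN}_ch{C}_{reporter}``.
    """

    data: pd.DataFrame

    BASE_COLUMNS = ("cell_id", "x", "y", "size")

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        if cols[: len(self.BASE_COLUMNS)] != list(self.BASE_COLUMNS):
            raise ValueError(f"table must start with columns {self.BASE_COLUMNS}")
        if len(set(cols)) != len(cols):
            raise ValueError("column names must be unique")

    @property
    def n_cells(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @staticmethod
    def from_records(
        records: Sequence[CellRecord],
        pairs: Sequence[tuple[int, int, str]] | None = None,
    ) -> "MeasurementTable":
        """Build the table from cell records.

        ``pairs`` fixes the (cycle, channel, reporter) column order; by default
        it is taken, sorted, from the first record.
        """
        if pairs is None:
            pairs = sorted(records[0].mean_intensity) if records else []
        rows = []
        for rec in records:
            row = {
                "cell_id": rec.label,
                "x": rec.centroid_x,
                "y": rec.centroid_y,
                "size": rec.area,
            }
            for cycle, channel, reporter in pairs:
                row[intensity_column_name(cycle, channel, reporter)] = rec.mean_intensity[
                    (cycle, channel, reporter)
                ]
            rows.append(row)
        columns = list(MeasurementTable.BASE_COLUMNS) + [
            intensity_column_name(*p) for p in pairs
        ]
        return MeasurementTable(pd.DataFrame(rows, columns=columns))


def write_measurements_csv(table: MeasurementTable, path: str | Path) -> Path:
    """RFC-4180 CSV: header row, one row per cell, plain decimal numbers."""
    path = Path(path)
    table.data.to_csv(path, index=False, lineterminator="\r\n")
    return path


def read_measurements_csv(path: str | Path) -> MeasurementTable:
    return MeasurementTable(pd.read_csv(path))


# --------------------------------------------------------------------------
# FCS 3.1
# --------------------------------------------------------------------------

_FCS_DELIM = "/"


def _fcs_text(keywords: dict[str, str]) -> bytes:
    parts = [_FCS_DELIM]
    for key, value in keywords.items():
        value = str(value)
        if _FCS_DELIM in value:
            value = value.replace(_FCS_DELIM, "_")
        if not value:
            value = " "
        parts.append(f"{key}{_FCS_DELIM}{value}{_FCS_DELIM}")
    return "".join(parts).encode("ascii", errors="replace")


def write_fcs(table: MeasurementTable, path: str | Path) -> Path:
    """Write the table as an FCS 3.1 list-mode file of little-endian float32."""
    n_par = len(table.columns)
    if n_par == 0:
        raise ValueError("cannot write an FCS file with zero parameters")
    n_tot = table.n_cells
    values = table.data.to_numpy(dtype="<f4") if n_tot else np.empty((0, n_par), "<f4")
    data_bytes = values.tobytes(order="C")

    def build(begin_data: int, end_data: int) -> bytes:
        keywords: dict[str, str] = {
            "$BEGINANALYSIS": "0",
            "$ENDANALYSIS": "0",
            "$BEGINSTEXT": "0",
            "$ENDSTEXT": "0",
            "$BEGINDATA": f"{begin_data:010d}",
            "$ENDDATA": f"{end_data:010d}",
            "$BYTEORD": "1,2,3,4",
            "$DATATYPE": "F",
            "$MODE": "L",
            "$NEXTDATA": "0",
            "$PAR": str(n_par),
            "$TOT": str(n_tot),
        }
        for i, name in enumerate(table.columns, start=1):
            col_max = float(table.data[name].max()) if n_tot else 0.0
            rng = max(int(np.ceil(col_max)) + 1, 1)
            keywords[f"$P{i}N"] = name
            keywords[f"$P{i}B"] = "32"
            keywords[f"$P{i}E"] = "0,0"
            keywords[f"$P{i}R"] = str(rng)
        return _fcs_text(keywords)

    header_len = 58
    text = build(0, 0)
    text_begin = header_len
    text_end = text_begin + len(text) - 1
    if data_bytes:
        data_begin = text_end + 1
        data_end = data_begin + len(data_bytes) - 1
    else:
        data_begin = data_end = 0
    text = build(data_begin, data_end)  # same length: offsets are fixed-width

    header = (
        b"FCS3.1    "
        + f"{text_begin:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + (f"{data_begin:>8d}".encode() if data_begin <= 99_999_999 else b"       0")
        + (f"{data_end:>8d}".encode() if data_end <= 99_999_999 else b"       0")
        + f"{0:>8d}".encode()
        + f"{0:>8d}".encode()
    )
    assert len(header) == header_len
    path = Path(path)
    path.write_bytes(header + text + data_bytes)
    return path


# --------------------------------------------------------------------------
# ImageJ ROI
# --------------------------------------------------------------------------

_ROI_POLYGON = 0
_ROI_VERSION = 227


def encode_imagej_roi(roi: PolygonROI) -> bytes:
    """Binary ImageJ ``.roi`` record for a polygon (big-endian, 64-byte header)."""
    if roi.vertices.shape[0] < 3:
        raise ValueError(f"ROI {roi.name!r} needs >= 3 vertices")
    xs = np.round(roi.vertices[:, 0]).astype(int)
    ys = np.round(roi.vertices[:, 1]).astype(int)
    left, top = int(xs.min()), int(ys.min())
    right, bottom = int(xs.max()), int(ys.max())
    n = len(xs)
    header = struct.pack(
        ">4sh2B4hH16x",  # magic, version, type+pad, top/left/bottom/right, n
        b"Iout",
        _ROI_VERSION,
        _ROI_POLYGON,
        0,
        top,
        left,
        bottom,
        right,
        n,
    )
    header += b"\x00" * (64 - len(header))
    rel_x = (xs - left).astype(">h").tobytes()
    rel_y = (ys - top).astype(">h").tobytes()
    return header + rel_x + rel_y


def write_roi_zip(rois: Sequence[PolygonROI], path: str | Path) -> Path:
    """ZIP archive of ImageJ ROI entries, one ``<name>.roi`` per polygon."""
    path = Path(path)
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for roi in rois:
            info = zipfile.ZipInfo(f"{roi.name}.roi", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, encode_imagej_roi(roi))
    return path


def write_outline_overlay(
    label_image: LabelImage,
    path: str | Path,
    color: tuple[int, int, int] = (255, 255, 0),
) -> Path:
    """RGB TIFF with 1-px label boundaries in a fixed colour on black."""
    boundaries = find_boundaries(label_image.labels, mode="inner")
    rgb = np.zeros(label_image.labels.shape + (3,), dtype=np.uint8)
    rgb[boundaries] = color
    path = Path(path)
    tifffile.imwrite(path, rgb, photometric="rgb")
    return path


# --------------------------------------------------------------------------
# Output directory layout
# --------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def export_output_layout(
    mosaics: dict,
    table: MeasurementTable,
    rois: Sequence[PolygonROI],
    label_image: LabelImage,
    config: dict,
    out_dir: str | Path,
    overwrite: bool = False,
) -> Path:
    """Write the deterministic analysis-ready tree and its checksum manifest.

    Layout: ``mosaics/`` (uint16 TIFF per cycle/channel), ``segmentation/``
    (labels + overlay), ``measurements/`` (CSV + FCS), ``rois/``, ``logs/``,
    plus ``manifest.json``. Refuses to clobber a previous run unless
    ``overwrite`` is set.
    """
    if not mosaics:
        raise ValueError("no mosaics to export")
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(
            f"{out_dir} already holds a run manifest; pass overwrite=True to replace"
        )
    for sub in ("mosaics", "segmentation", "measurements", "rois", "logs"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)

    written: list[Path] = []
    for (cycle, channel), mosaic in sorted(mosaics.items()):
        p = out_dir / "mosaics" / f"cyc{cycle:02d}_CH{channel}.tif"
        tifffile.imwrite(p, np.clip(np.round(mosaic), 0, 65535).astype(np.uint16))
        written.append(p)

    p = out_dir / "segmentation" / "labels.tif"
    tifffile.imwrite(p, label_image.labels.astype(np.int32))
    written.append(p)
    written.append(
        write_outline_overlay(label_image, out_dir / "segmentation" / "outline_overlay.tif")
    )
    written.append(write_measurements_csv(table, out_dir / "measurements" / "cells.csv"))
    written.append(write_fcs(table, out_dir / "measurements" / "cells.fcs"))
    written.append(write_roi_zip(rois, out_dir / "rois" / "rois.zip"))

    cfg_path = out_dir / "logs" / "run_config.json"
    cfg_path.write_text(json.dumps(config, indent=2, sort_keys=True, default=str))

    # manifest covers data artifacts only; logs/ records the invocation
    manifest = {
        "files": {
            str(p.relative_to(out_dir)): _sha256(p) for p in sorted(written)
        },
        "n_cells": table.n_cells,
        "n_rois": len(rois),
        "n_mosaics": len(mosaics),
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out_dir
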
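"""Plain-text readers/writers for the pipeline's external formats.

Chromatogram CSV: two columns ``time_min,intensity`` with header.
Panel manifest: YAML or JSON list of per-batch entries.
Peak table: CSV (rows = batches) plus a JSON sidecar with reference times
and marker annotations.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .fingerprint import PeakTable
from .peaks import Peak
from .synthetic import Chromatogram

__all__ = [
    "read_chromatogram_csv", "write_chromatogram_csv",
    "read_manifest", "write_manifest",
    "write_peak_list_csv",
    "read_peak_table", "write_peak_table",
]

_FLOAT_FMT = "%.17g"  # exact float64 round trip


def write_chromatogram_csv(chrom: Chromatogram, path) -> None:
    df = pd.DataFrame({"time_min": chrom.time, "intensity": chrom.intensity})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_chromatogram_csv(path, meta: dict | None = None) -> Chromatogram:
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"time_min", "intensity"} <= set(df.columns):
        raise ValidationError(
            f"{path}: expected columns time_min,intensity, got {list(df.columns)}")
    return Chromatogram(time=df["time_min"].to_numpy(dtype=float),
                        intensity=df["intensity"].to_numpy(dtype=float),
                        meta=dict(meta or {}))


def write_manifest(entries: list[dict], path) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(entries, sort_keys=False))
    else:
        path.write_text(json.dumps(entries, indent=2))


def read_manifest(path) -> list[dict]:
    path = Path(path)
    text = path.read_text()
    entries = (yaml.safe_load(text) if path.suffix in (".yaml", ".yml")
               else json.loads(text))
    if not isinstance(entries, list):
        raise ValidationError(f"{path}: manifest must be a list of entries")
    for e in entries:
        if "batch" not in e:
            raise ValidationError(f"{path}: manifest entry missing 'batch'")
    return entries


def write_peak_list_csv(peaks: list[Peak], path) -> None:
    rows = [(f"peak_{i + 1:02d}", p.apex_time, p.left_bound, p.right_bound,
             p.height, p.area, p.snr) for i, p in enumerate(peaks)]
    pd.DataFrame(rows, columns=[
        "peak_id", "apex_time_min", "left_min", "right_min", "height",
        "area", "snr"]).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_peak_table(table: PeakTable, csv_path, meta_path,
                     apex_csv_path=None) -> None:
    table.areas.to_csv(csv_path, index_label="batch", float_format=_FLOAT_FMT)
    if apex_csv_path is not None:
        table.apex_times.to_csv(apex_csv_path, index_label="batch",
                                float_format=_FLOAT_FMT)
    meta = {
        "reference_batch": table.reference_batch,
        "window": table.window,
        "reference_times": {k: float(v)
                            for k, v in table.reference_times.items()},
        "markers": dict(table.markers),
        "dropped_batches": list(table.dropped_batches),
    }
    Path(meta_path).write_text(json.dumps(meta, indent=2))


def read_peak_table(csv_path, meta_path, apex_csv_path=None) -> PeakTable:
    areas = pd.read_csv(csv_path, index_col="batch",
                        float_precision="round_trip")
    meta = json.loads(Path(meta_path).read_text())
    if apex_csv_path is not None and Path(apex_csv_path).exists():
        apexes = pd.read_csv(apex_csv_path, index_col="batch",
                             float_precision="round_trip")
    else:
        apexes = pd.DataFrame(
            np.tile(list(meta["reference_times"].values()), (len(areas), 1)),
            index=areas.index, columns=areas.columns)
    return PeakTable(
        areas=areas,
        apex_times=apexes,
        reference_times=pd.Series(meta["reference_times"]),
        reference_batch=meta["reference_batch"],
        window=meta["window"],
        markers=meta.get("markers", {}),
        dropped_batches=tuple(meta.get("dropped_batches", ())),
    )
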
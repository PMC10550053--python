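"""File I/O: the CSV schemas, mask PNGs, YAML configs and JSON results.

All tables are comma-separated UTF-8 with a mandatory header row and ISO
8601 timestamps, so runs round-trip byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .core import CanopyCoverSeries, FDISeries, TemperatureSeries
from .estimation import FitResult, ScoringTable
from .imaging import PlotMask

__all__ = [
    "SchemaError",
    "read_temperature_csv",
    "write_temperature_csv",
    "read_cc_csv",
    "write_cc_csv",
    "read_scoring_csv",
    "write_scoring_csv",
    "write_fdi_csv",
    "read_mask_png",
    "write_mask_png",
    "load_yaml",
    "write_fit_result",
]


class SchemaError(ValueError):
    """An input table does not match the expected column schema."""


def _require(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def read_temperature_csv(path) -> TemperatureSeries:
    """Read an hourly temperature table with columns timestamp, temp_c."""
    df = pd.read_csv(path)
    _require(df, ("timestamp", "temp_c"), path)
    return TemperatureSeries(pd.to_datetime(df["timestamp"]), df["temp_c"].to_numpy())


def write_temperature_csv(series: TemperatureSeries, path) -> None:
    df = series.to_frame()
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False)


def read_cc_csv(path) -> list[CanopyCoverSeries]:
    """Read per-row CC measurements (unit_id, genotype, date, cc)."""
    df = pd.read_csv(path)
    _require(df, ("unit_id", "genotype", "date", "cc"), path)
    df["date"] = pd.to_datetime(df["date"])
    out = []
    for (unit, geno), grp in df.groupby(["unit_id", "genotype"], sort=True):
        grp = grp.sort_values("date")
        out.append(
            CanopyCoverSeries(str(unit), str(geno), grp["date"], grp["cc"].to_numpy())
        )
    return out


def write_cc_csv(series_collection, path) -> None:
    rows = []
    for s in series_collection:
        for d, v in zip(s.dates, s.cc):
            rows.append((s.unit_id, s.genotype, d.strftime("%Y-%m-%d"), v))
    pd.DataFrame(rows, columns=["unit_id", "genotype", "date", "cc"]).to_csv(
        path, index=False
    )


def read_scoring_csv(path) -> ScoringTable:
    """Read visual frost-damage scorings (genotype, score in 1-9)."""
    df = pd.read_csv(path)
    _require(df, ("genotype", "score"), path)
    return ScoringTable(df["genotype"].astype(str).tolist(), df["score"].to_numpy())


def write_scoring_csv(table: ScoringTable, path) -> None:
    pd.DataFrame(
        {"genotype": table.genotypes, "score": table.scores}
    ).to_csv(path, index=False)


def write_fdi_csv(fdi: FDISeries, schedule, path) -> None:
    """Write per-interval FDI with columns t_prev, t_now, fdi_degC_h."""
    sched = pd.DatetimeIndex(schedule)
    pd.DataFrame(
        {
            "t_prev": sched[:-1].strftime("%Y-%m-%dT%H:%M:%S"),
            "t_now": sched[1:].strftime("%Y-%m-%dT%H:%M:%S"),
            "fdi_degC_h": fdi.fdi,
        }
    ).to_csv(path, index=False)


def read_mask_png(path, plot_id: str = "", date: str = "") -> PlotMask:
    """Read an 8-bit 0/255 plant mask PNG."""
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., 0]
    vals = np.unique(img)
    if not np.isin(vals, (0, 255)).all():
        raise ValueError(f"{path}: mask is not binary 0/255 (values {vals[:5]}...)")
    return PlotMask((img == 255).astype(np.uint8), plot_id=plot_id or Path(path).stem, date=date)


def write_mask_png(mask: PlotMask, path) -> None:
    iio.imwrite(path, (mask.pixels * 255).astype(np.uint8))


def load_yaml(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: expected a YAML mapping")
    return data


def write_fit_result(result: FitResult, outdir) -> Path:
    """Serialize a fit: fit.json plus the two grid-profile CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "fit.json", "w", encoding="utf-8") as fh:
        json.dump(result.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    result.lag_profile.to_frame().to_csv(outdir / "lag_profile.csv", index=False)
    result.smooth_profile.to_frame().to_csv(outdir / "smooth_profile.csv", index=False)
    return outdir / "fit.json"
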
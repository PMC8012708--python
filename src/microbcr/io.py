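"""Readers and writers shared by all analysis stages.

Flat CSV for time series (time columns are explicitly unit-named: ``time_s``,
``time_h``), PNG sets or multi-page TIFF for frame stacks with a YAML
sidecar carrying acquisition metadata (fps, pixel scale, ROI).  Result
records embed the package version and a hash of the resolved configuration
so a run is reproducible from its outputs.
"""

from __future__ import annotations

import glob as _glob
import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from microbcr.errors import SchemaError
from microbcr.frames import FrameSequence
from microbcr.growth import CultivationRecord
from microbcr.oxygen import DOTSeries

__all__ = [
    "read_timeseries_csv",
    "read_dot_csv",
    "read_cultivation_csv",
    "read_mixing_csv",
    "read_frame_stack",
    "write_frame_stack",
    "write_dot_csv",
    "write_cultivation_csv",
    "result_record",
    "config_hash",
]

#: Fig.-7-style cultivation channel columns (time in hours)
CULTIVATION_COLUMNS = ["time_h", "bdw_g_l", "ph", "dot_percent",
                       "co2_offgas_percent", "o2_offgas_percent"]


def read_timeseries_csv(
    path: str | Path, schema: dict[str, bool], time_column: str | None = None
) -> pd.DataFrame:
    """Read and validate a time-series CSV.

    ``schema`` maps column names to a required flag; columns are matched by
    header name, so order is irrelevant.  Missing values stay as NaN.  The
    time column (the first required one, or ``time_column``) must be strictly
    increasing.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    df = pd.read_csv(path)
    for col, required in schema.items():
        if required and col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    tcol = time_column or next(c for c, req in schema.items() if req)
    t = df[tcol].to_numpy(dtype=float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise SchemaError(f"{path}: column {tcol!r} is not strictly increasing")
    return df[[c for c in schema if c in df.columns]]


def read_dot_csv(path: str | Path, c_star: float | None = None,
                 c0: float | None = None) -> DOTSeries:
    """Load a gassing-out trace from a ``time_s, dot_percent`` CSV."""
    df = read_timeseries_csv(path, {"time_s": True, "dot_percent": True})
    return DOTSeries(
        timestamps_s=df["time_s"].to_numpy(),
        dot=df["dot_percent"].to_numpy(),
        c_star=c_star,
        c0=c0,
    )


def write_dot_csv(series: DOTSeries, path: str | Path) -> None:
    pd.DataFrame({"time_s": series.timestamps_s, "dot_percent": series.dot}).to_csv(
        path, index=False
    )


def read_cultivation_csv(path: str | Path) -> CultivationRecord:
    """Load a multi-channel cultivation record; only time and BDW are
    mandatory."""
    schema = {c: c in ("time_h", "bdw_g_l") for c in CULTIVATION_COLUMNS}
    df = read_timeseries_csv(path, schema)

    def _opt(col: str):
        return df[col].to_numpy() if col in df.columns else None

    return CultivationRecord(
        timestamps_h=df["time_h"].to_numpy(),
        bdw=df["bdw_g_l"].to_numpy(),
        ph=_opt("ph"),
        dot=_opt("dot_percent"),
        co2_offgas=_opt("co2_offgas_percent"),
        o2_offgas=_opt("o2_offgas_percent"),
    )


def write_cultivation_csv(
    record: CultivationRecord, path: str | Path, float_format: str = "%.5g"
) -> None:
    data = {"time_h": record.timestamps_h, "bdw_g_l": record.bdw}
    for col, name in [("ph", "ph"), ("dot_percent", "dot"),
                      ("co2_offgas_percent", "co2_offgas"),
                      ("o2_offgas_percent", "o2_offgas")]:
        ch = getattr(record, name)
        if ch is not None:
            data[col] = ch
    pd.DataFrame(data).to_csv(path, index=False, float_format=float_format)


def read_mixing_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a pre-extracted ROI grey trace (``time_s, i_grey``)."""
    df = read_timeseries_csv(path, {"time_s": True, "i_grey": True})
    return df["time_s"].to_numpy(), df["i_grey"].to_numpy()


def _load_sidecar(meta: str | Path | dict) -> dict:
    if isinstance(meta, dict):
        return meta
    return yaml.safe_load(Path(meta).read_text())


def read_frame_stack(path_or_glob: str | Path, meta: str | Path | dict) -> FrameSequence:
    """Load a frame stack from a PNG file set or a multi-page TIFF.

    ``meta`` is the acquisition sidecar (YAML path or dict) and must provide
    ``fps`` and ``pixel_scale_mm``; ``roi`` as ``[row_min, row_max, col_min,
    col_max]`` is optional.  All frames must share one shape and be 8-bit.
    """
    info = _load_sidecar(meta)
    for key in ("fps", "pixel_scale_mm"):
        if key not in info:
            raise SchemaError(f"frame-stack metadata missing {key!r}")

    p = str(path_or_glob)
    if p.endswith((".tif", ".tiff")):
        frames = tifffile.imread(p)
        if frames.ndim == 2:
            frames = frames[None]
    else:
        files = sorted(_glob.glob(p)) if any(ch in p for ch in "*?[") else [p]
        if not files:
            raise SchemaError(f"no frames match {path_or_glob!r}")
        imgs = [iio.imread(f) for f in files]
        shapes = {im.shape for im in imgs}
        if len(shapes) > 1:
            raise SchemaError(f"mixed frame shapes in stack: {sorted(shapes)}")
        frames = np.stack(imgs)
    if frames.dtype != np.uint8:
        raise SchemaError(f"frames must be 8-bit greyscale, got {frames.dtype}")

    fps = float(info["fps"])
    roi = tuple(int(v) for v in info["roi"]) if "roi" in info else None
    return FrameSequence(
        frames=frames,
        timestamps=np.arange(len(frames)) / fps,
        fps=fps,
        pixel_scale_mm=float(info["pixel_scale_mm"]),
        roi=roi,
    )


def write_frame_stack(
    seq: FrameSequence, directory: str | Path, stem: str = "frame",
    fmt: str = "png",
) -> Path:
    """Write frames as numbered PNGs or one multi-page TIFF, plus the YAML
    metadata sidecar.  Returns the sidecar path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if fmt == "tiff":
        tifffile.imwrite(directory / f"{stem}.tiff", seq.frames)
    elif fmt == "png":
        width = len(str(len(seq) - 1))
        for i, frame in enumerate(seq.frames):
            iio.imwrite(directory / f"{stem}_{i:0{width}d}.png", frame)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    sidecar = directory / f"{stem}_meta.yaml"
    sidecar.write_text(
        yaml.safe_dump(
            {
                "fps": seq.fps,
                "pixel_scale_mm": seq.pixel_scale_mm,
                "roi": list(seq.roi),
            }
        )
    )
    return sidecar


def config_hash(config: dict) -> str:
    """Stable short hash of a resolved configuration dict."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def result_record(config: dict, **results) -> dict:
    """Assemble a result record embedding provenance (version, config hash)."""
    from microbcr import __version__

    return {
        "package_version": __version__,
        "config_hash": config_hash(config),
        "config": config,
        **results,
    }
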
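"""File formats: time-activity CSV, depth-profile CSV, NIfTI volumes,
cohort tables and JSON reports with provenance.

All tabular formats are UTF-8 CSV with a header row and '.' decimal;
volumes are NIfTI with voxel spacing (mm) in the header and the origin in
the affine translation.  Numeric payloads round-trip losslessly at double
precision.  Reports carry a provenance block (package version, seed, config
hash) so any result file can be traced to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .decay import TimeActivitySeries
from .profiles import DepthProfile, Volume3D

__all__ = [
    "read_series",
    "write_series",
    "read_profile",
    "write_profile",
    "read_volume",
    "write_volume",
    "read_table",
    "write_table",
    "write_json_report",
    "provenance_block",
    "SchemaError",
]


class SchemaError(ValueError):
    """A file does not conform to its documented schema."""


def _check_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_series(series: TimeActivitySeries, path) -> Path:
    """Write a time-activity series as ``t_s,value`` CSV plus a JSON sidecar.

    The sidecar (``<name>.csv.meta.json``) records the bin width and the
    t-zero convention, which the two CSV columns cannot carry.
    """
    path = Path(path)
    pd.DataFrame({"t_s": series.times, "value": series.values}).to_csv(
        path, index=False, float_format="%.17g"
    )
    meta = {
        "bin_width_s": series.bin_width,
        "t_zero_convention": series.t_zero_convention,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_series(path) -> TimeActivitySeries:
    """Read a ``t_s,value`` CSV (with its sidecar, if present)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, ["t_s", "value"], path)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        bin_width = float(meta["bin_width_s"])
        convention = str(meta["t_zero_convention"])
    else:
        t = df["t_s"].to_numpy()
        bin_width = float(np.median(np.diff(t))) if t.size > 1 else 1.0
        convention = "end_of_irradiation"
    return TimeActivitySeries(
        df["t_s"].to_numpy(float), df["value"].to_numpy(float), bin_width, convention
    )


def write_profile(profile: DepthProfile, path) -> Path:
    path = Path(path)
    pd.DataFrame({"depth_mm": profile.depths, "value": profile.values}).to_csv(
        path, index=False, float_format="%.17g"
    )
    return path


def read_profile(path) -> DepthProfile:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, ["depth_mm", "value"], path)
    return DepthProfile(df["depth_mm"].to_numpy(float), df["value"].to_numpy(float))


def write_volume(vol: Volume3D, path) -> Path:
    """Write a volume as NIfTI; spacing goes to the header, origin to the affine."""
    path = Path(path)
    affine = np.diag([*vol.spacing, 1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(vol.voxels.astype(np.float64), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    return path


def read_volume(path) -> Volume3D:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise SchemaError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    affine = img.affine
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in affine[:3, 3])
    return Volume3D(data, spacing, origin)


def read_table(path, required: Sequence[str]) -> pd.DataFrame:
    """Read a cohort CSV and validate its required columns."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - delegated parse errors
        raise SchemaError(f"{path}: cannot parse CSV ({exc})") from exc
    _check_columns(df, required, path)
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("ribpet")
    except Exception:  # pragma: no cover - not installed
        return "unknown"


def provenance_block(seed: int | None, config: Mapping[str, Any] | None) -> dict:
    """Provenance stamp: package version, seed and a hash of the run config."""
    cfg_json = json.dumps(config or {}, sort_keys=True, default=str)
    return {
        "package": "ribpet",
        "version": _package_version(),
        "seed": seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
    }


def write_json_report(
    payload: Mapping[str, Any],
    path,
    *,
    seed: int | None = None,
    config: Mapping[str, Any] | None = None,
) -> Path:
    """Write a JSON report with an attached provenance block."""
    path = Path(path)
    doc = dict(payload)
    doc["provenance"] = provenance_block(seed, config)
    path.write_text(json.dumps(doc, indent=1, sort_keys=False, default=float))
    return path
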
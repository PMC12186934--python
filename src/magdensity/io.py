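"""File formats: NIfTI volumes with YAML sidecars, density tables, reports.

Interchange format is NIfTI (.nii/.nii.gz); echo stacks are 4-D with echo
as the 4th axis, complex-valued or as a magnitude+phase pair, with a YAML
sidecar carrying echo times (ms), scanner name and field strength (T).
Affines are passed through untouched (identity when none is known).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import FormatError
from .phantom import EchoSeries
from .recon import FatWaterMaps, combine_mag_phase

__all__ = [
    "write_echo_series",
    "write_mag_phase",
    "read_echo_stack",
    "write_volume",
    "read_volume",
    "write_mask",
    "read_mask",
    "read_density_table",
    "write_density_table",
    "write_fatwater_maps",
    "report_to_jsonable",
    "write_report",
]

DENSITY_COLUMNS = ["subject_id", "side", "scanner", "magdensity_percent"]


def _sidecar_dict(series: EchoSeries, field_strength: float | None) -> dict:
    d = {
        "echo_times_ms": [float(t) for t in series.echo_times],
        "scanner_name": series.scanner_name,
        "provenance": series.provenance,
    }
    if field_strength is not None:
        d["field_strength_t"] = float(field_strength)
    return d


def write_echo_series(
    series: EchoSeries,
    path,
    sidecar_path=None,
    *,
    affine: np.ndarray | None = None,
    field_strength: float | None = None,
) -> Path:
    """Write a complex 4-D echo stack plus its YAML sidecar."""
    path = Path(path)
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(series.data, dtype=np.complex128), affine)
    nib.save(img, str(path))
    if sidecar_path is None:
        sidecar_path = path.with_suffix("").with_suffix(".yaml")
    with open(sidecar_path, "w") as fh:
        yaml.safe_dump(_sidecar_dict(series, field_strength), fh)
    return path


def write_mag_phase(
    series: EchoSeries,
    magnitude_path,
    phase_path,
    sidecar_path=None,
    *,
    affine: np.ndarray | None = None,
    field_strength: float | None = None,
) -> tuple[Path, Path]:
    """Write an echo stack as separate magnitude and phase NIfTI volumes."""
    if affine is None:
        affine = np.eye(4)
    mag = np.abs(series.data)
    ph = np.angle(series.data)
    nib.save(nib.Nifti1Image(mag, affine), str(magnitude_path))
    nib.save(nib.Nifti1Image(ph, affine), str(phase_path))
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            yaml.safe_dump(_sidecar_dict(series, field_strength), fh)
    return Path(magnitude_path), Path(phase_path)


def read_echo_stack(
    path_complex=None,
    path_magnitude=None,
    path_phase=None,
    sidecar=None,
) -> tuple[EchoSeries, np.ndarray, dict]:
    """Read a 4-D echo stack (complex, or magnitude+phase pair) + sidecar.

    Returns (series, affine, sidecar dict).  The sidecar must list one echo
    time per volume on the 4th axis.
    """
    if sidecar is None:
        raise FormatError("a YAML sidecar with echo_times_ms is required")
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    if not isinstance(meta, dict) or "echo_times_ms" not in meta:
        raise FormatError(f"sidecar {sidecar} lacks echo_times_ms")
    echo_times = [float(t) for t in meta["echo_times_ms"]]
    scanner = str(meta.get("scanner_name", ""))

    if path_complex is not None:
        img = nib.load(str(path_complex))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 4:
            raise FormatError(f"expected 4-D echo stack, got {data.ndim}-D")
        if not np.iscomplexobj(data):
            raise FormatError("complex-path input is not complex-valued")
        if data.shape[3] != len(echo_times):
            raise FormatError(
                f"{data.shape[3]} echoes on disk vs {len(echo_times)} in sidecar"
            )
        series = EchoSeries(
            data=data, echo_times=echo_times, scanner_name=scanner,
            provenance=f"read from {path_complex}",
        )
        return series, img.affine, meta

    if path_magnitude is None or path_phase is None:
        raise FormatError("provide path_complex or both path_magnitude and path_phase")
    mimg = nib.load(str(path_magnitude))
    pimg = nib.load(str(path_phase))
    mag = np.asanyarray(mimg.dataobj).astype(float)
    ph = np.asanyarray(pimg.dataobj).astype(float)
    if mag.ndim != 4:
        raise FormatError(f"expected 4-D echo stack, got {mag.ndim}-D")
    if mag.shape != ph.shape:
        raise FormatError("magnitude and phase grids differ")
    if mag.shape[3] != len(echo_times):
        raise FormatError(
            f"{mag.shape[3]} echoes on disk vs {len(echo_times)} in sidecar"
        )
    series = combine_mag_phase(mag, ph, echo_times, scanner_name=scanner)
    return series, mimg.affine, meta


def write_volume(data: np.ndarray, path, affine: np.ndarray | None = None) -> Path:
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=float), affine), str(path))
    return Path(path)


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj).astype(float), img.affine


def write_mask(mask: np.ndarray, path, affine: np.ndarray | None = None) -> Path:
    if affine is None:
        affine = np.eye(4)
    nib.save(
        nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), str(path)
    )
    return Path(path)


def read_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj).astype(bool)


def write_fatwater_maps(
    maps: FatWaterMaps, outdir, prefix: str = "", affine: np.ndarray | None = None
) -> dict[str, Path]:
    """Write water/fat/fat-fraction/field-map volumes under one directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, vol in (
        ("water", maps.water),
        ("fat", maps.fat),
        ("fat_fraction", maps.fat_fraction),
        ("field_map", maps.field_map),
    ):
        p = outdir / f"{prefix}{name}.nii.gz"
        write_volume(vol, p, affine)
        written[name] = p
    return written


def read_density_table(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a per-breast density table from CSV or XLSX.

    ``column_map`` renames source columns to the canonical layout
    (subject_id, side, scanner, magdensity_percent), so externally produced
    spreadsheets with their own headers can be ingested.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in DENSITY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"density table {path} missing columns {missing}")
    df["side"] = df["side"].astype(str).str.upper().str[0]
    return df[DENSITY_COLUMNS + [c for c in df.columns if c not in DENSITY_COLUMNS]]


def write_density_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else None
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def report_to_jsonable(report: dict) -> dict:
    return _jsonable(report)


def write_report(report: dict, json_path, text_path=None) -> Path:
    """Write a study report as JSON and, optionally, an aligned-text table."""
    json_path = Path(json_path)
    json_path.parent.mkdir(parents=True, exist_ok=True)
    with open(json_path, "w") as fh:
        json.dump(report_to_jsonable(report), fh, indent=2)
    if text_path is not None:
        lines = ["comparison                     n   meanD     t       p        r      LoA"]
        for stage in ("pre_calibration", "post_calibration"):
            for name, rep in report.get(stage, {}).items():
                lines.append(
                    f"{name:<28} {rep.n:>4} {rep.mean_delta:>7.3f} "
                    f"{rep.t_stat:>7.3f} {rep.p_value:>8.4f} {rep.pearson_r:>7.4f}  "
                    f"[{rep.ba_loa_low:.2f}, {rep.ba_loa_high:.2f}]"
                )
        Path(text_path).write_text("\n".join(lines) + "\n")
    return json_path
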
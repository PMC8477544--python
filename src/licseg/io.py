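"""Reading and writing stacks, masks and reports.

Supported stack inputs:

* ``portable-array`` — a single ``.npz`` container with arrays ``data``
  (H x W x E), ``echo_times_ms`` and ``spacing_mm``; the native interchange
  format of the phantom generator and the test suite.
* ``nifti`` — a 3-D NIfTI volume whose third axis is the echo dimension, with
  a JSON sidecar (same stem, ``.json``) carrying ``echo_times_ms`` and
  optionally ``pixel_spacing_mm``.
* ``dicom-series`` — a directory of single-frame DICOM files, one per echo;
  echo times come from the EchoTime tag and frames are sorted by TE.

Masks are written both as 8-bit PNG (0/255) and as uint8 NIfTI; LIC maps as
float32 NIfTI.  Reports serialise to JSON plus a flat CSV row so cohort runs
aggregate into one table.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .core import BinaryMask, MetadataError, ValidationError
from .metrics import AgreementStats, EvalReport
from .relaxometry import MultiEchoStack, ScalarMap

FORMATS = ("portable-array", "nifti", "dicom-series")


@dataclass
class RunReport:
    """Per-case record: config echo, metrics, flags, provenance."""

    case_id: str
    seed: int
    config: dict
    flags: list[str] = field(default_factory=list)
    median_lic_mg_g: float = float("nan")
    eval: EvalReport | None = None
    agreement: AgreementStats | None = None
    software_version: str = __version__

    def to_dict(self) -> dict:
        return _jsonable(dataclasses.asdict(self))

    def to_csv_row(self) -> dict:
        d = self.to_dict()
        row = {k: v for k, v in d.items() if not isinstance(v, (dict, list))}
        row["flags"] = ";".join(d["flags"])
        for key in ("eval", "agreement"):
            if d.get(key):
                row.update({f"{key}_{k}": v for k, v in d[key].items()})
        return row


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    return obj


def infer_format(path) -> str:
    p = Path(path)
    if p.is_dir():
        return "dicom-series"
    if p.suffix == ".npz":
        return "portable-array"
    if p.suffix == ".nii" or p.name.endswith(".nii.gz"):
        return "nifti"
    raise ValidationError(f"cannot infer stack format from {p.name!r}")


def save_stack_portable(path, stack: MultiEchoStack) -> None:
    np.savez(
        path,
        data=stack.data,
        echo_times_ms=stack.echo_times_ms,
        spacing_mm=np.asarray(stack.pixel_spacing_mm, dtype=float),
    )


def _load_portable(path) -> MultiEchoStack:
    with np.load(path) as z:
        missing = {"data", "echo_times_ms", "spacing_mm"} - set(z.files)
        if missing:
            raise MetadataError(f"portable container missing arrays: {sorted(missing)}")
        return MultiEchoStack(
            data=z["data"],
            echo_times_ms=z["echo_times_ms"],
            pixel_spacing_mm=tuple(np.asarray(z["spacing_mm"], dtype=float)),
        )


def _load_nifti(path) -> MultiEchoStack:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValidationError("NIfTI stack must be H x W x E")
    p = Path(path)
    stem = p.name[: -len(".nii.gz")] if p.name.endswith(".nii.gz") else p.stem
    sidecar = p.with_name(stem + ".json")
    if not sidecar.exists():
        raise MetadataError(f"echo-time sidecar {sidecar.name} not found")
    meta = json.loads(sidecar.read_text())
    if "echo_times_ms" not in meta:
        raise MetadataError("sidecar lacks echo_times_ms")
    te = np.asarray(meta["echo_times_ms"], dtype=float)
    spacing = tuple(meta.get("pixel_spacing_mm", np.abs(np.diag(img.affine)[:2]).tolist()))
    order = np.argsort(te, kind="stable")
    return MultiEchoStack(data=data[:, :, order], echo_times_ms=te[order], pixel_spacing_mm=spacing)


def _load_dicom_series(path) -> MultiEchoStack:
    import pydicom

    files = sorted(p for p in Path(path).iterdir() if p.suffix.lower() in (".dcm", ".ima", ""))
    if not files:
        raise ValidationError(f"no DICOM files in {path}")
    frames, tes, spacing = [], [], None
    for f in files:
        ds = pydicom.dcmread(str(f))
        te = getattr(ds, "EchoTime", None)
        if te is None:
            raise MetadataError(f"{f.name}: missing EchoTime tag")
        tes.append(float(te))
        frames.append(ds.pixel_array.astype(float))
        if spacing is None and getattr(ds, "PixelSpacing", None) is not None:
            spacing = tuple(float(v) for v in ds.PixelSpacing)
    shapes = {fr.shape for fr in frames}
    if len(shapes) != 1:
        raise ValidationError(f"mixed frame shapes in series: {sorted(shapes)}")
    order = np.argsort(tes, kind="stable")
    data = np.stack([frames[i] for i in order], axis=-1)
    te = np.asarray(tes, dtype=float)[order]
    return MultiEchoStack(data=data, echo_times_ms=te, pixel_spacing_mm=spacing or (1.0, 1.0))


def load_stack(path, format: str | None = None) -> MultiEchoStack:
    """Load a multi-echo stack; echoes are returned sorted by echo time."""
    fmt = format or infer_format(path)
    if fmt not in FORMATS:
        raise ValidationError(f"format must be one of {FORMATS}")
    if fmt == "portable-array":
        return _load_portable(path)
    if fmt == "nifti":
        return _load_nifti(path)
    return _load_dicom_series(path)


def write_mask_png(path, mask) -> None:
    px = np.asarray(getattr(mask, "pixels", mask), dtype=bool)
    iio.imwrite(Path(path), (px.astype(np.uint8) * 255))


def read_mask_png(path, pixel_spacing_mm=(1.0, 1.0)) -> BinaryMask:
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return BinaryMask(arr > 127, pixel_spacing_mm)


def _nifti_affine(spacing_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1] = spacing_mm
    return aff


def write_mask_nifti(path, mask: BinaryMask) -> None:
    img = nib.Nifti1Image(mask.pixels.astype(np.uint8), _nifti_affine(mask.pixel_spacing_mm))
    nib.save(img, str(path))


def write_map_nifti(path, scalar_map: ScalarMap) -> None:
    img = nib.Nifti1Image(
        scalar_map.values.astype(np.float32),
        _nifti_affine(scalar_map.valid_mask.pixel_spacing_mm),
    )
    nib.save(img, str(path))


def save_outputs(result, report: RunReport, outdir) -> list[Path]:
    """Write masks (PNG + NIfTI), the LIC map (NIfTI), and the report
    (JSON + CSV row + plain-text log).  Returns the written paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    masks = {
        "body": result.body,
        "restricted": result.restricted,
        "liver_entire": result.liver_entire,
        "liver_clinical": result.liver_clinical,
    }
    for name, mask in masks.items():
        png = out / f"{name}.png"
        nii = out / f"{name}.nii.gz"
        write_mask_png(png, mask)
        write_mask_nifti(nii, mask)
        written += [png, nii]

    lic_path = out / "lic_map.nii.gz"
    write_map_nifti(lic_path, result.lic_map)
    written.append(lic_path)

    json_path = out / "report.json"
    json_path.write_text(json.dumps(report.to_dict(), indent=2))
    csv_path = out / "report.csv"
    pd.DataFrame([report.to_csv_row()]).to_csv(csv_path, index=False)
    log_path = out / "run.log"
    lines = [f"licseg {report.software_version} case={report.case_id} seed={report.seed}"]
    lines += [f"flag: {f}" for f in report.flags] or ["flags: none"]
    lines.append(f"median LIC = {report.median_lic_mg_g:.4f} mg/g dw")
    log_path.write_text("\n".join(lines) + "\n")
    written += [json_path, csv_path, log_path]
    return written


def aggregate_reports_csv(reports: list[RunReport], path) -> pd.DataFrame:
    df = pd.DataFrame([r.to_csv_row() for r in reports])
    df.to_csv(path, index=False)
    return df
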
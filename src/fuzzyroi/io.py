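"""Readers and writers for the standard image and annotation formats.

Supported volume formats: DICOM series (read), NIfTI (read/write), NRRD
(read/write) and PNG slices/stacks (read/write).  Arrays follow the
``(depth, rows, cols)`` index convention with 0-based coordinates;
clustering operates in index space and DICOM patient-space metadata is not
propagated beyond spacing.

Annotation input is the LIDC XML dialect: per-reader nodule contours given
as pixel coordinates per slice, combined here into a 0-1000 consensus
score (equal vote weight per reader, e.g. 250 per reader when four read).
"""

from __future__ import annotations

import csv
import json
import platform
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import ClusterParams, ClusterState, ImageVolume, ParameterError
from .evaluation import CONSENSUS_MAX, EvalRecord, NoduleMask

__all__ = [
    "FormatError",
    "read_volume",
    "write_volume",
    "parse_lidc_xml",
    "write_outputs",
    "write_records_csv",
]


class FormatError(ValueError):
    """Unreadable, unsupported or inconsistent input file(s)."""


def _detect_format(path: Path, hint: str | None) -> str:
    if hint:
        return hint.lower()
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith(".nrrd"):
        return "nrrd"
    if name.endswith(".png"):
        return "png"
    if name.endswith(".dcm"):
        return "dicom"
    if path.is_dir():
        entries = sorted(path.iterdir())
        if any(e.suffix.lower() == ".png" for e in entries):
            return "png"
        return "dicom"
    raise FormatError(f"cannot infer format of {path}")


def read_volume(path, format: str | None = None) -> ImageVolume:
    """Read a volume from NIfTI, NRRD, a DICOM series or a PNG stack.

    DICOM rescale slope/intercept is applied so intensities come back in
    HU; DICOM slices are ordered by spatial position along the scan axis.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file or directory: {path}")
    fmt = _detect_format(path, format)
    if fmt == "nifti":
        return _read_nifti(path)
    if fmt == "nrrd":
        return _read_nrrd(path)
    if fmt == "dicom":
        return _read_dicom(path)
    if fmt == "png":
        return _read_png(path)
    raise FormatError(f"unsupported format {fmt!r}")


def _read_nifti(path: Path) -> ImageVolume:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"unreadable NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 2:
        data = data[..., np.newaxis]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 2D/3D NIfTI, got ndim={data.ndim}")
    # NIfTI stores (x, y, z) = (col, row, depth); our convention is (z, y, x)
    voxels = np.transpose(data, (2, 1, 0)).astype(np.float64)
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return ImageVolume(voxels=voxels, spacing=spacing)


def _write_nifti(vol_or_array, path: Path, spacing=(1.0, 1.0, 1.0)) -> None:
    import nibabel as nib

    arr, spacing = _coerce(vol_or_array, spacing)
    data = np.transpose(arr, (2, 1, 0))
    affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((spacing[2], spacing[1], spacing[0]))
    nib.save(img, str(path))


def _read_nrrd(path: Path) -> ImageVolume:
    import SimpleITK as sitk

    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:
        raise FormatError(f"unreadable NRRD file {path}: {exc}") from exc
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    sp = img.GetSpacing()  # (x, y, z)
    spacing = (float(sp[2]), float(sp[1]), float(sp[0])) if len(sp) == 3 else (1.0, float(sp[1]), float(sp[0]))
    return ImageVolume(voxels=arr.astype(np.float64), spacing=spacing)


def _write_nrrd(vol_or_array, path: Path, spacing=(1.0, 1.0, 1.0)) -> None:
    import SimpleITK as sitk

    arr, spacing = _coerce(vol_or_array, spacing)
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing((spacing[2], spacing[1], spacing[0]))
    sitk.WriteImage(img, str(path))


def _read_dicom(path: Path) -> ImageVolume:
    import pydicom

    files = [path] if path.is_file() else sorted(
        p for p in path.iterdir() if p.is_file() and not p.name.startswith(".")
    )
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception as exc:
            raise FormatError(f"unreadable DICOM file {f}: {exc}") from exc
        slices.append((f, ds))
    if not slices:
        raise FormatError(f"no DICOM files found under {path}")
    uids = {getattr(ds, "SeriesInstanceUID", None) for _, ds in slices}
    if len(uids) > 1:
        raise FormatError(f"mixed DICOM series under {path}: {sorted(map(str, uids))}")
    shapes = {(int(ds.Rows), int(ds.Columns)) for _, ds in slices}
    if len(shapes) > 1:
        raise FormatError(f"inconsistent slice shapes under {path}: {shapes}")

    def sort_key(item):
        _, ds = item
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None:
            return float(ipp[2])
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=sort_key)
    planes = []
    for f, ds in slices:
        try:
            arr = ds.pixel_array.astype(np.float64)
        except Exception as exc:
            raise FormatError(f"cannot decode pixel data in {f}: {exc}") from exc
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(arr * slope + intercept)
    ds0 = slices[0][1]
    ps = getattr(ds0, "PixelSpacing", [1.0, 1.0])
    dz = float(getattr(ds0, "SliceThickness", 1.0) or 1.0)
    spacing = (dz, float(ps[0]), float(ps[1]))
    return ImageVolume(voxels=np.stack(planes), spacing=spacing)


def _read_png(path: Path) -> ImageVolume:
    import imageio.v3 as iio

    files = [path] if path.is_file() else sorted(
        p for p in path.iterdir() if p.suffix.lower() == ".png"
    )
    if not files:
        raise FormatError(f"no PNG files found under {path}")
    planes = []
    for f in files:
        try:
            arr = np.asarray(iio.imread(str(f)))
        except Exception as exc:
            raise FormatError(f"unreadable PNG file {f}: {exc}") from exc
        if arr.ndim == 3:  # collapse RGB(A) to luminance
            arr = arr[..., :3].mean(axis=-1)
        planes.append(arr.astype(np.float64))
    if len({p.shape for p in planes}) > 1:
        raise FormatError(f"inconsistent PNG slice shapes under {path}")
    return ImageVolume(voxels=np.stack(planes))


def _write_png(vol_or_array, path: Path) -> None:
    import imageio.v3 as iio

    arr, _ = _coerce(vol_or_array, None)
    if np.any(arr < 0) or np.any(arr > np.iinfo(np.uint16).max):
        raise FormatError("PNG output supports non-negative 16-bit integer data only")
    data = np.round(arr).astype(np.uint16)
    path = Path(path)
    if data.shape[0] == 1:
        iio.imwrite(str(path), data[0])
    else:
        path.mkdir(parents=True, exist_ok=True)
        for z in range(data.shape[0]):
            iio.imwrite(str(path / f"slice_{z:04d}.png"), data[z])


def _coerce(vol_or_array, spacing):
    if isinstance(vol_or_array, ImageVolume):
        return vol_or_array.voxels, vol_or_array.spacing
    arr = np.asarray(vol_or_array)
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    return arr, spacing or (1.0, 1.0, 1.0)


def write_volume(vol_or_array, path, format: str | None = None, spacing=(1.0, 1.0, 1.0)) -> None:
    """Write a volume or label/mask grid to NIfTI, NRRD or PNG."""
    path = Path(path)
    fmt = format.lower() if format else None
    if fmt is None:
        name = path.name.lower()
        if name.endswith((".nii", ".nii.gz")):
            fmt = "nifti"
        elif name.endswith(".nrrd"):
            fmt = "nrrd"
        elif name.endswith(".png") or path.is_dir():
            fmt = "png"
        else:
            raise FormatError(f"cannot infer output format of {path}")
    if fmt == "nifti":
        _write_nifti(vol_or_array, path, spacing)
    elif fmt == "nrrd":
        _write_nrrd(vol_or_array, path, spacing)
    elif fmt == "png":
        _write_png(vol_or_array, path)
    else:
        raise FormatError(f"unsupported output format {fmt!r}")


# ---------------------------------------------------------------------------
# LIDC-dialect XML annotations
# ---------------------------------------------------------------------------


def parse_lidc_xml(
    path,
    shape: tuple[int, int, int],
    z_positions: Sequence[float] | None = None,
) -> NoduleMask:
    """Build a consensus nodule mask from an LIDC-dialect annotation file.

    Each reading session contributes one binary mask: every nodule ROI's
    contour polygon is filled, contour pixels inclusive.  Reader masks are
    combined by vote count scaled to [0, 1000] (four readers give scores
    in {0, 250, 500, 750, 1000}).

    ``z_positions`` maps each slice index to its ``imageZposition``; when
    omitted, Z positions are interpreted directly as slice indices.
    """
    from lxml import etree
    from skimage.draw import polygon, polygon_perimeter

    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise FormatError(f"malformed annotation XML {path}: {exc}") from exc
    root = tree.getroot()

    def local(elem, name):
        return elem.findall(f".//{{*}}{name}") + elem.findall(f".//{name}")

    def z_to_slice(zpos: float) -> int:
        if z_positions is None:
            idx = int(round(zpos))
        else:
            idx = int(np.argmin(np.abs(np.asarray(z_positions, dtype=float) - zpos)))
            if abs(float(z_positions[idx]) - zpos) > 1e-3 + max(
                np.diff(sorted(z_positions)).max() if len(z_positions) > 1 else 0.0, 0.0
            ):
                raise FormatError(f"imageZposition {zpos} matches no slice")
        if not 0 <= idx < shape[0]:
            raise FormatError(f"contour references slice {idx} outside volume depth {shape[0]}")
        return idx

    sessions = local(root, "readingSession")
    if not sessions:
        return NoduleMask(grid=np.zeros(shape), semantics="consensus")
    votes = np.zeros(shape, dtype=np.int64)
    for sess in sessions:
        mask = np.zeros(shape, dtype=bool)
        for nod in local(sess, "unblindedReadNodule"):
            for roi in local(nod, "roi"):
                inc = local(roi, "inclusion")
                included = not (inc and inc[0].text and inc[0].text.strip().upper() == "FALSE")
                zel = local(roi, "imageZposition")
                if not zel:
                    continue
                z = z_to_slice(float(zel[0].text))
                xs = [int(float(e.text)) for e in local(roi, "xCoord")]
                ys = [int(float(e.text)) for e in local(roi, "yCoord")]
                if not xs:
                    continue
                sl = np.zeros(shape[1:], dtype=bool)
                if len(xs) >= 3:
                    rr, cc = polygon(ys, xs, shape=shape[1:])
                    sl[rr, cc] = True
                    rr, cc = polygon_perimeter(ys, xs, shape=shape[1:], clip=True)
                    sl[rr, cc] = True
                else:  # degenerate contour: mark the listed pixels
                    for y, x in zip(ys, xs):
                        if 0 <= y < shape[1] and 0 <= x < shape[2]:
                            sl[y, x] = True
                if included:
                    mask[z] |= sl
                else:
                    mask[z] &= ~sl
        votes += mask
    scores = CONSENSUS_MAX * votes / len(sessions)
    return NoduleMask(grid=scores, semantics="consensus")


# ---------------------------------------------------------------------------
# run outputs
# ---------------------------------------------------------------------------


def _library_versions() -> dict[str, str]:
    import scipy
    import skimage

    from . import __version__

    return {
        "fuzzyroi": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "scikit-image": skimage.__version__,
    }


def write_outputs(
    state: ClusterState,
    selection: int | None,
    out_dir,
    params: ClusterParams,
    spacing=(1.0, 1.0, 1.0),
    format: str = "nifti",
    extra_meta: dict | None = None,
) -> dict[str, Path]:
    """Write label map, selected-cluster mask, iteration trace and metadata.

    Returns a mapping from artifact name to path.  The metadata sidecar
    records every clustering parameter plus library versions, so a run can
    be reproduced exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = {"nifti": ".nii.gz", "nrrd": ".nrrd", "png": ".png"}.get(format)
    if ext is None:
        raise FormatError(f"unsupported output format {format!r}")
    paths: dict[str, Path] = {}

    labels = state.labels()
    lab_out = labels if format != "png" else np.where(labels < 0, 0, labels + 1)
    paths["labels"] = out_dir / f"labels{ext}"
    write_volume(lab_out.astype(np.int16), paths["labels"], format=format, spacing=spacing)
    if selection is not None:
        mask = (labels == selection).astype(np.uint8)
        paths["mask"] = out_dir / f"nodule_mask{ext}"
        write_volume(mask, paths["mask"], format=format, spacing=spacing)

    paths["trace"] = out_dir / "trace.csv"
    with open(paths["trace"], "w", newline="") as fh:
        writer = csv.writer(fh)
        c = len(state.centroids)
        writer.writerow(
            ["iteration"] + [f"centroid_{i}" for i in range(c)] + ["objective", "max_delta"]
        )
        for it in range(state.iterations):
            cent = state.centroid_trace[it] if it < len(state.centroid_trace) else ()
            obj = state.objective_trace[it] if it < len(state.objective_trace) else ""
            dlt = state.delta_trace[it] if it < len(state.delta_trace) else ""
            writer.writerow([it + 1, *[f"{v!r}" for v in cent], obj, dlt])

    meta = {
        "c": params.c,
        "m": params.m,
        "epsilon": params.epsilon,
        "max_iter": params.max_iter,
        "p": params.p,
        "q": params.q,
        "alpha": params.alpha,
        "kernel_family": params.kernel.family,
        "sigma": params.kernel.sigma,
        "variance_scale": params.kernel.variance_scale,
        "kernel_b": params.kernel.b,
        "kernel_d": params.kernel.d,
        "window_mode": params.neighborhood.mode,
        "window_size": params.neighborhood.size,
        "include_center": params.neighborhood.include_center,
        "seed": params.seed,
        "iterations": state.iterations,
        "converged": state.converged,
        "selected_cluster": selection,
        "centroids": [float(v) for v in state.centroids],
        "versions": _library_versions(),
    }
    if extra_meta:
        meta.update(extra_meta)
    paths["metadata"] = out_dir / "metadata.json"
    with open(paths["metadata"], "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def write_records_csv(records: Sequence[EvalRecord], path) -> None:
    """Serialize evaluation records, one CSV row per record."""
    fields = [
        "slice_index", "algorithm", "params", "tp_count", "fp_count", "fn_count",
        "tp_pct", "fp_pct", "fp_denominator", "domain", "failed", "error",
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for rec in records:
            writer.writerow(rec.to_row())
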
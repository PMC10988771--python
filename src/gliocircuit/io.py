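"""Readers and writers for every external format the pipeline touches.

ECoG comes in as EDF (read through mne) or as a self-describing tab-separated
text fallback; trial markers, electrode coordinates and cohort tables are CSV;
volumes and masks are NIfTI-1 (nibabel); spherical meshes and per-vertex
labels are GIFTI with a CSV fallback.  Every writer/reader pair is an identity
on content at the format's precision (exact for text/NIfTI/GIFTI, 16-bit
quantisation for EDF).

EDF export is implemented here directly (ASCII header + int16 records)
because the pipeline only needs it to emit fixtures; reading uses mne.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError, RangeError, ShapeError
from .recording import EcogRecording, make_channel_table, make_marker_table
from .surface import SurfaceMesh, validate_labels

# ---------------------------------------------------------------------------
# ECoG recordings


def _parse_strip(channel_id: str) -> tuple[str, int]:
    """Parse 's<strip>e<index>' channel names; fall back to one shared strip."""
    cid = str(channel_id)
    if cid.startswith("s") and "e" in cid[1:]:
        s, _, e = cid[1:].partition("e")
        if s.isdigit() and e.isdigit():
            return f"strip{int(s)}", int(e)
    return "strip0", -1


def _markers_from_csv(path, fs: float, n_samples: int) -> pd.DataFrame:
    tbl = pd.read_csv(path, comment="#")
    required = {"trial_id", "condition", "onset_s", "offset_s"}
    if not required.issubset(tbl.columns):
        raise FormatError(f"marker table needs columns {sorted(required)}")
    onset = np.round(tbl["onset_s"].to_numpy() * fs).astype(np.int64)
    offset = np.round(tbl["offset_s"].to_numpy() * fs).astype(np.int64)
    markers = make_marker_table(tbl["trial_id"], tbl["condition"], onset, offset)
    if len(markers) and markers["offset"].max() > n_samples:
        raise RangeError("marker offset_s beyond recording duration")
    return markers


def read_ecog(path: str | Path, markers_path: str | Path) -> EcogRecording:
    """Read an ECoG recording (EDF or text fallback) plus its marker CSV."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # mne holds EEG-type channels in volts
        fs = float(raw.info["sfreq"])
        ids = list(raw.ch_names)
    else:
        data, fs, ids = _read_ecog_text(path)
    strips, idxs = zip(*(_parse_strip(c) for c in ids))
    channels = make_channel_table(ids, strips, None if -1 in idxs else idxs)
    markers = _markers_from_csv(markers_path, fs, data.shape[1])
    return EcogRecording(data=data, fs=fs, channels=channels, markers=markers,
                         provenance=[f"read:{path.name}"])


def _read_ecog_text(path: Path) -> tuple[np.ndarray, float, list]:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# gliocircuit-ecog"):
            raise FormatError("text ECoG file must start with '# gliocircuit-ecog fs=<Hz>'")
        try:
            fs = float(first.split("fs=")[1].split()[0])
        except (IndexError, ValueError) as exc:
            raise FormatError("missing or invalid fs= in text ECoG header") from exc
        header = fh.readline().strip()
        ids = header.split("\t")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return data.T.astype(np.float64), fs, ids


def write_ecog_text(rec: EcogRecording, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# gliocircuit-ecog fs={rec.fs}\n")
        fh.write("\t".join(str(c) for c in rec.channel_ids) + "\n")
        np.savetxt(fh, rec.data.T, delimiter="\t", fmt="%.10g")


def write_markers(rec: EcogRecording, path: str | Path) -> None:
    tbl = rec.markers.copy()
    tbl["onset_s"] = tbl.pop("onset") / rec.fs
    tbl["offset_s"] = tbl.pop("offset") / rec.fs
    tbl[["trial_id", "condition", "onset_s", "offset_s"]].to_csv(path, index=False)


def _edf_field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        raise FormatError(f"EDF header field too wide: {s!r}")
    return s.ljust(width).encode("ascii")


def write_edf(rec: EcogRecording, path: str | Path) -> None:
    """Write an EDF file (16-bit quantisation over each channel's range).

    Uses 1-second data records, so the recording is zero-padded up to a whole
    second; round-trips are exact in duration only for integer-second data.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    n_records = int(np.ceil(rec.n_samples / fs))
    n_sig = rec.n_channels

    data = np.zeros((n_sig, n_records * fs))
    data[:, : rec.n_samples] = rec.data
    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((data - pmin[:, None]) / scale[:, None]) + dmin
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(_edf_field("0", 8))
        fh.write(_edf_field("X X X X", 80))
        fh.write(_edf_field("Startdate X X X X", 80))
        fh.write(_edf_field("01.01.01", 8))
        fh.write(_edf_field("00.00.00", 8))
        fh.write(_edf_field(256 * (n_sig + 1), 8))
        fh.write(_edf_field("", 44))
        fh.write(_edf_field(n_records, 8))
        fh.write(_edf_field(1, 8))
        fh.write(_edf_field(n_sig, 4))
        for cid in rec.channel_ids:
            fh.write(_edf_field(str(cid)[:16], 16))
        for _ in range(n_sig):
            fh.write(_edf_field("", 80))
        for _ in range(n_sig):
            fh.write(_edf_field("uV", 8))
        for v in pmin:
            fh.write(_edf_field(f"{v:.7g}"[:8], 8))
        for v in pmax:
            fh.write(_edf_field(f"{v:.7g}"[:8], 8))
        fh.write(_edf_field(dmin, 8) * n_sig)
        fh.write(_edf_field(dmax, 8) * n_sig)
        for _ in range(n_sig):
            fh.write(_edf_field("", 80))
        fh.write(_edf_field(fs, 8) * n_sig)
        fh.write(_edf_field("", 32) * n_sig)
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())


def write_ecog(rec: EcogRecording, path: str | Path, markers_path: str | Path | None = None) -> None:
    """Write a recording as EDF or text depending on the file suffix."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        write_edf(rec, path)
    else:
        write_ecog_text(rec, path)
    if markers_path is not None:
        write_markers(rec, markers_path)


# ---------------------------------------------------------------------------
# Volumes (NIfTI-1)


def read_volume(path: str | Path, expected_rank: int | None = None):
    """Read a NIfTI volume; returns ``(data, affine)``."""
    img = nib.load(str(path))
    affine = img.affine
    if affine is None or not np.all(np.isfinite(affine)):
        raise FormatError(f"{path}: volume has no usable affine")
    data = np.asarray(img.get_fdata())
    if expected_rank is not None and data.ndim != expected_rank:
        raise ShapeError(f"{path}: expected {expected_rank}-D volume, got {data.ndim}-D")
    return data, affine


def write_volume(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    affine = np.asarray(affine, dtype=np.float64)
    if affine.shape != (4, 4) or not np.all(np.isfinite(affine)):
        raise FormatError("affine must be a finite 4x4 matrix")
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


# ---------------------------------------------------------------------------
# Surfaces (GIFTI, CSV fallback)


def read_surface(mesh_path: str | Path, labels_path: str | Path | None = None):
    """Read a mesh (GIFTI or CSV) and, optionally, per-vertex labels.

    Returns ``(SurfaceMesh, labels-or-None)``.
    """
    mesh_path = Path(mesh_path)
    if mesh_path.suffix.lower() == ".gii":
        img = nib.load(str(mesh_path))
        verts = faces = None
        for da in img.darrays:
            if da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
                verts = da.data
            elif da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
                faces = da.data
        if verts is None or faces is None:
            raise FormatError(f"{mesh_path}: GIFTI lacks POINTSET/TRIANGLE arrays")
        mesh = SurfaceMesh(verts, faces)
    else:
        tbl = pd.read_csv(mesh_path, comment="#")
        if not {"kind", "a", "b", "c"}.issubset(tbl.columns):
            raise FormatError("CSV mesh needs columns kind,a,b,c")
        v = tbl[tbl["kind"] == "v"][["a", "b", "c"]].to_numpy(dtype=np.float64)
        f = tbl[tbl["kind"] == "f"][["a", "b", "c"]].to_numpy(dtype=np.int64)
        mesh = SurfaceMesh(v, f)
    if labels_path is None:
        return mesh, None
    labels = read_labels(labels_path, mesh)
    return mesh, labels


def read_labels(labels_path: str | Path, mesh: SurfaceMesh) -> np.ndarray:
    labels_path = Path(labels_path)
    if labels_path.suffix.lower() == ".gii":
        img = nib.load(str(labels_path))
        labels = np.asarray(img.darrays[0].data)
    else:
        labels = pd.read_csv(labels_path, comment="#")["label"].to_numpy()
    return validate_labels(mesh, labels)


def write_surface(mesh: SurfaceMesh, mesh_path: str | Path,
                  labels: np.ndarray | None = None,
                  labels_path: str | Path | None = None) -> None:
    mesh_path = Path(mesh_path)
    if mesh_path.suffix.lower() == ".gii":
        img = nib.gifti.GiftiImage()
        img.add_gifti_data_array(nib.gifti.GiftiDataArray(
            mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"))
        img.add_gifti_data_array(nib.gifti.GiftiDataArray(
            mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"))
        nib.save(img, str(mesh_path))
    else:
        rows = [("v", *xyz) for xyz in mesh.vertices] + [("f", *ijk) for ijk in mesh.faces]
        pd.DataFrame(rows, columns=["kind", "a", "b", "c"]).to_csv(mesh_path, index=False)
    if labels is not None and labels_path is not None:
        pd.DataFrame({"label": np.asarray(labels, dtype=np.int64)}).to_csv(labels_path, index=False)


def write_surface_map(values: np.ndarray, valid: np.ndarray, path: str | Path,
                      meta: dict | None = None) -> None:
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "valid": np.asarray(valid, dtype=int)})
    write_table(df, path, meta)


def read_surface_map(path: str | Path):
    from .surface import SurfaceMap

    df = pd.read_csv(path, comment="#")
    values = df["value"].to_numpy()
    valid = df["valid"].to_numpy().astype(bool)
    values = np.where(valid, values, np.nan)
    return SurfaceMap(values, valid)


# ---------------------------------------------------------------------------
# Generic tables with a reproducibility header


def read_electrode_table(path: str | Path) -> pd.DataFrame:
    tbl = pd.read_csv(path, comment="#")
    required = {"electrode_id", "strip_id", "x_mm", "y_mm", "z_mm"}
    if not required.issubset(tbl.columns):
        raise FormatError(f"electrode table needs columns {sorted(required)}")
    return tbl


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write a CSV with '#'-prefixed header lines recording seed/config hash."""
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
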
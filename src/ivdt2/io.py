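"""Image containers and file I/O for multi-echo sagittal stacks.

A session's data is held as an :class:`EchoStack`: ``(n_slices, n_echoes,
height, width)`` with echo times in milliseconds.  Stacks are written as 4D
NIfTI volumes (x, y, slice, echo) with a JSON sidecar carrying the echo
times, and can be read back from NIfTI or from a directory of per-echo
DICOM files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PAPER_ECHO_TIMES",
    "EchoStack",
    "save_stack",
    "load_stack",
    "load_dicom_series",
    "save_label_volume",
    "load_support_points",
    "save_support_points",
]

#: The 16 echo times (ms) of the spin-echo multi-echo protocol: multiples of
#: 10.9 ms from 10.9 to 174.4 ms.
PAPER_ECHO_TIMES: tuple[float, ...] = tuple(round(10.9 * k, 1) for k in range(1, 17))


@dataclass
class EchoStack:
    """One session's multi-echo image data.

    Parameters
    ----------
    data:
        Array of shape ``(n_slices, n_echoes, height, width)``.  Rows (the
        third axis) run cephalocaudally, columns anteroposteriorly.
    echo_times:
        Echo times in ms, strictly increasing, one per echo.
    pixel_spacing:
        In-plane pixel size in mm (isotropic).
    slice_thickness, slice_gap:
        Slice geometry in mm.
    """

    data: np.ndarray
    echo_times: np.ndarray
    pixel_spacing: float = 0.781
    slice_thickness: float = 3.0
    slice_gap: float = 3.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be (n_slices, n_echoes, height, width)")
        if self.data.shape[1] != self.echo_times.size:
            raise ValueError("number of echoes does not match echo_times")
        if self.echo_times.size and (
            np.any(self.echo_times <= 0) or np.any(np.diff(self.echo_times) <= 0)
        ):
            raise ValueError("echo_times must be positive and strictly increasing")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def n_echoes(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        """In-plane (height, width)."""
        return self.data.shape[2], self.data.shape[3]


def _affine(stack: EchoStack) -> np.ndarray:
    slice_step = stack.slice_thickness + stack.slice_gap
    return np.diag([stack.pixel_spacing, stack.pixel_spacing, slice_step, 1.0])


def save_stack(stack: EchoStack, path: str | Path) -> Path:
    """Write a stack as 4D NIfTI (x, y, slice, echo) plus a JSON sidecar."""
    import nibabel as nib

    path = Path(path)
    # (slice, echo, row, col) -> (row, col, slice, echo)
    vol = np.ascontiguousarray(stack.data.transpose(2, 3, 0, 1)).astype(np.float32)
    nib.save(nib.Nifti1Image(vol, _affine(stack)), str(path))
    sidecar = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" else path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "echo_times_ms": list(map(float, stack.echo_times)),
                "pixel_spacing_mm": stack.pixel_spacing,
                "slice_thickness_mm": stack.slice_thickness,
                "slice_gap_mm": stack.slice_gap,
                **stack.meta,
            },
            indent=1,
        )
    )
    return path


def load_stack(path: str | Path) -> EchoStack:
    """Read a stack written by :func:`save_stack`."""
    import nibabel as nib

    path = Path(path)
    img = nib.load(str(path))
    vol = np.asanyarray(img.dataobj)
    if vol.ndim != 4:
        raise ValueError(f"{path} is not a 4D (x, y, slice, echo) volume")
    sidecar = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" else path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    echo_times = np.asarray(meta.pop("echo_times_ms", PAPER_ECHO_TIMES[: vol.shape[3]]))
    return EchoStack(
        data=vol.transpose(2, 3, 0, 1),
        echo_times=echo_times,
        pixel_spacing=float(meta.pop("pixel_spacing_mm", 0.781)),
        slice_thickness=float(meta.pop("slice_thickness_mm", 3.0)),
        slice_gap=float(meta.pop("slice_gap_mm", 3.0)),
        meta=meta,
    )


def load_dicom_series(directory: str | Path) -> EchoStack:
    """Assemble an :class:`EchoStack` from a directory of DICOM files.

    Files are grouped by slice position and sorted by echo time; every slice
    must provide the same set of echo times.
    """
    import pydicom

    directory = Path(directory)
    frames: dict[float, dict[float, np.ndarray]] = {}
    spacing = 0.781
    for f in sorted(directory.iterdir()):
        if f.is_dir():
            continue
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        te = float(getattr(ds, "EchoTime", 0.0))
        loc = float(getattr(ds, "SliceLocation", getattr(ds, "InstanceNumber", 0)))
        frames.setdefault(loc, {})[te] = ds.pixel_array.astype(np.float32)
        if hasattr(ds, "PixelSpacing"):
            spacing = float(ds.PixelSpacing[0])
    if not frames:
        raise ValueError(f"no DICOM images found in {directory}")
    locs = sorted(frames)
    tes = sorted(frames[locs[0]])
    data = np.stack([np.stack([frames[l][t] for t in tes]) for l in locs])
    return EchoStack(data=data, echo_times=np.asarray(tes), pixel_spacing=spacing)


def save_label_volume(labels: np.ndarray, path: str | Path, pixel_spacing: float = 0.781,
                      slice_step: float = 6.0) -> Path:
    """Write a per-slice label image stack ``(n_slices, H, W)`` as NIfTI."""
    import nibabel as nib

    path = Path(path)
    vol = np.ascontiguousarray(np.asarray(labels).transpose(1, 2, 0)).astype(np.int16)
    aff = np.diag([pixel_spacing, pixel_spacing, slice_step, 1.0])
    nib.save(nib.Nifti1Image(vol, aff), str(path))
    return path


def load_support_points(path: str | Path):
    """Read operator support points from CSV with columns slice, disc, x, y.

    Returns a dict ``(slice, disc) -> (n, 2) array of (row, col)``.
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = {"slice", "disc", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"support point file must have columns {sorted(required)}")
    out: dict[tuple[int, str], np.ndarray] = {}
    for (sl, disc), g in df.groupby(["slice", "disc"], sort=True):
        out[(int(sl), str(disc))] = np.column_stack([g["y"].to_numpy(), g["x"].to_numpy()]).astype(int)
    return out


def save_support_points(points: dict, path: str | Path) -> Path:
    import pandas as pd

    rows = []
    for (sl, disc), pts in points.items():
        for r, c in np.asarray(pts):
            rows.append({"slice": sl, "disc": disc, "x": int(c), "y": int(r)})
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)
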
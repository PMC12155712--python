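"""Volume I/O with JSON sidecars and blink removal by thresholding.

Volumes are stored as multi-page TIFF (one page per depth) or NIfTI, with
a JSON sidecar carrying the acquisition protocol, scan direction, spacing,
B-scan validity mask and free-form metadata.  Blink-corrupted B-scans are
detected from their mean intensity relative to the volume median and masked
out (never deleted) so acquisition timing stays contiguous.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .protocol import AcquisitionProtocol
from .volume import RasterVolume, VolumeError

SIDECAR_SCHEMA_VERSION = 1
DEFAULT_BLINK_THRESHOLD = 0.3


class DimensionMismatchError(VolumeError):
    """Grid shape disagrees with its sidecar."""


class VolumeUnusableError(RuntimeError):
    """Too many B-scans flagged as blinks to proceed."""


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii", ".tif", ".tiff"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def write_volume(volume: RasterVolume, path) -> Path:
    """Write grid + sidecar; returns the sidecar path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        nib.save(nib.Nifti1Image(np.asarray(volume.grid), np.eye(4)), path)
    else:
        tifffile.imwrite(path, volume.grid)
    sidecar = {
        "schema_version": SIDECAR_SCHEMA_VERSION,
        "shape": list(volume.grid.shape),
        "protocol": volume.protocol.to_dict(),
        "direction": volume.direction,
        "volume_index": volume.volume_index,
        "axial_um": volume.axial_um,
        "valid_bscan": volume.valid_bscan.astype(int).tolist(),
        "meta": volume.meta,
    }
    sc = _sidecar_path(path)
    sc.write_text(json.dumps(sidecar, indent=1))
    return sc


def read_volume(path, sidecar_path=None) -> RasterVolume:
    """Read a grid and its sidecar back into a :class:`RasterVolume`.

    Raises :class:`DimensionMismatchError` naming both shapes when the grid
    on disk disagrees with the sidecar's declared shape.
    """
    path = Path(path)
    sc = Path(sidecar_path) if sidecar_path else _sidecar_path(path)
    meta = json.loads(sc.read_text())
    if meta.get("schema_version") != SIDECAR_SCHEMA_VERSION:
        raise VolumeError(
            f"unsupported sidecar schema version {meta.get('schema_version')}")
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        grid = np.asanyarray(nib.load(path).dataobj).astype(np.float32)
    else:
        grid = tifffile.imread(path)
    declared = tuple(meta["shape"])
    if grid.shape != declared:
        raise DimensionMismatchError(
            f"grid on disk has shape {grid.shape} but sidecar declares {declared}")
    return RasterVolume(
        grid=grid,
        protocol=AcquisitionProtocol.from_dict(meta["protocol"]),
        direction=meta["direction"],
        volume_index=meta["volume_index"],
        axial_um=meta["axial_um"],
        valid_bscan=np.array(meta["valid_bscan"], bool),
        meta=meta.get("meta", {}),
    )


def detect_blinks(volume: RasterVolume,
                  rel_threshold: float = DEFAULT_BLINK_THRESHOLD) -> list[int]:
    """Flag blink B-scans: mean intensity < rel_threshold x median B-scan mean.

    The threshold is relative, so detection is invariant to global intensity
    scaling.  Flagged indices are recorded in ``volume.valid_bscan`` (masked,
    not deleted) and returned sorted.  If more than half the B-scans are
    flagged the volume is unusable.
    """
    if not 0.0 < rel_threshold < 1.0:
        raise ValueError("rel_threshold must be in (0, 1)")
    means = volume.grid.mean(axis=(0, 2))
    median = float(np.median(means))
    bright = float(np.quantile(means, 0.9))
    # when most B-scans are dark the median itself sits in the blink
    # population and the relative rule cannot work
    if median <= 0 or median < rel_threshold * bright:
        raise VolumeUnusableError(
            "median B-scan intensity at blink level: volume unusable")
    flagged = np.flatnonzero(means < rel_threshold * median)
    if flagged.size > volume.nslow // 2:
        raise VolumeUnusableError(
            f"{flagged.size}/{volume.nslow} B-scans below threshold: volume unusable")
    volume.valid_bscan[flagged] = False
    return flagged.tolist()


def validate(volume: RasterVolume) -> dict:
    """Basic geometry/consistency report (raises on hard violations)."""
    if np.any(volume.grid < 0):
        raise VolumeError("negative intensities")
    t = volume.timestamps()
    if np.any(np.diff(t.ravel()) <= 0):
        raise VolumeError("timestamps not strictly increasing")
    return {
        "shape": volume.grid.shape,
        "direction": volume.direction,
        "pitch_um": volume.protocol.pitch_um,
        "axial_um": volume.axial_um,
        "masked_bscans": int((~volume.valid_bscan).sum()),
        "t_start_s": float(t[0, 0]),
        "t_end_s": float(t[-1, -1]),
    }
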
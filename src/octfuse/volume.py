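"""The raster-volume container shared by all pipeline stages.

Coordinate convention (shared package-wide): 0-based voxel indices;
x is the fast axis of an x-fast volume, y its slow axis, z is depth
increasing posteriorly.  Physical positions are in micrometres at voxel
centres.  Grids are stored (nz, nslow, nfast).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .protocol import AcquisitionProtocol, X_FAST, Y_FAST


class VolumeError(ValueError):
    """Inconsistent raster-volume contents."""


@dataclass
class RasterVolume:
    """One raster-scanned OCT volume plus its acquisition metadata.

    Attributes
    ----------
    grid : (nz, nslow, nfast) float32, non-negative intensities.
    protocol : the acquisition protocol this volume belongs to.
    direction : "x-fast" or "y-fast".
    volume_index : position of this volume in the acquisition sequence.
    axial_um : axial voxel spacing in micrometres.
    valid_bscan : boolean mask over slow-axis B-scans; False marks
        blink-corrupted B-scans excluded from all downstream estimation.
    meta : free-form metadata (blink ground truth, simulation seeds, ...).
    """

    grid: np.ndarray
    protocol: AcquisitionProtocol
    direction: str
    volume_index: int = 0
    axial_um: float = 2.0
    valid_bscan: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3:
            raise VolumeError(f"grid must be 3D, got shape {self.grid.shape}")
        nz, nslow, nfast = self.grid.shape
        if (nslow, nfast) != (self.protocol.bscans_per_volume,
                              self.protocol.ascans_per_bscan):
            raise VolumeError(
                "grid transverse shape "
                f"{(nslow, nfast)} does not match protocol "
                f"{(self.protocol.bscans_per_volume, self.protocol.ascans_per_bscan)}")
        if self.direction not in (X_FAST, Y_FAST):
            raise VolumeError(f"unknown direction {self.direction!r}")
        if self.axial_um <= 0:
            raise VolumeError("axial spacing must be positive")
        if self.valid_bscan is None:
            self.valid_bscan = np.ones(nslow, dtype=bool)
        else:
            self.valid_bscan = np.asarray(self.valid_bscan, dtype=bool)
            if self.valid_bscan.shape != (nslow,):
                raise VolumeError("valid_bscan length must equal B-scan count")

    # ---- shapes -----------------------------------------------------------
    @property
    def nz(self) -> int:
        return self.grid.shape[0]

    @property
    def nslow(self) -> int:
        return self.grid.shape[1]

    @property
    def nfast(self) -> int:
        return self.grid.shape[2]

    # ---- timing & geometry ------------------------------------------------
    def timestamps(self) -> np.ndarray:
        """(nslow, nfast) per-A-scan acquisition times in seconds."""
        return self.protocol.timestamps(self.volume_index)

    def ascan_xy_um(self) -> tuple[np.ndarray, np.ndarray]:
        """Nominal (x_um, y_um) of each A-scan, each shaped (nslow, nfast).

        For an x-fast volume the fast index a runs along x and the slow
        index b along y; a y-fast volume swaps the roles.
        """
        pitch = self.protocol.pitch_um
        a = np.arange(self.nfast) * pitch
        b = np.arange(self.nslow) * pitch
        if self.direction == X_FAST:
            x = np.broadcast_to(a[None, :], (self.nslow, self.nfast))
            y = np.broadcast_to(b[:, None], (self.nslow, self.nfast))
        else:
            x = np.broadcast_to(b[:, None], (self.nslow, self.nfast))
            y = np.broadcast_to(a[None, :], (self.nslow, self.nfast))
        return np.ascontiguousarray(x, float), np.ascontiguousarray(y, float)

    def z_um(self) -> np.ndarray:
        """Axial voxel-centre depths (nz,) in micrometres."""
        return np.arange(self.nz) * self.axial_um

    def enface_mean(self) -> np.ndarray:
        """Mean-over-depth projection, (nslow, nfast)."""
        return self.grid.mean(axis=0)

    def copy(self) -> "RasterVolume":
        import copy as _copy
        return RasterVolume(self.grid.copy(), self.protocol, self.direction,
                            self.volume_index, self.axial_um,
                            self.valid_bscan.copy(), _copy.deepcopy(self.meta))
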
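"""Raster-scan acquisition protocol: geometry, timing and scan directions.

A volumetric OCT acquisition is a sequence of raster volumes scanned in
alternating orthogonal fast-axis directions ("x-fast" / "y-fast").  Each
volume is a stack of B-scans along its slow axis; each B-scan is a row of
A-scans along its fast axis.  The protocol fixes the field of view, the
A-scan counts and rates, and therefore the per-A-scan acquisition times
that the motion model interpolates over.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

X_FAST = "x-fast"
Y_FAST = "y-fast"


class ProtocolError(ValueError):
    """Invalid acquisition-protocol parameters."""


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Multi-volume orthogonal raster protocol.

    Defaults reproduce a 6 x 6 mm isotropic scan of 500 x 500 A-scans
    (12 um transverse pitch), six volumes of 2.4 s each acquired in
    alternating orthogonal directions within a 14.6 s acquisition.
    """

    fov_mm: float = 6.0
    ascans_per_bscan: int = 500
    bscans_per_volume: int = 500
    ascan_rate_hz: float = 128_000.0
    volume_duration_s: float = 2.4
    inter_volume_gap_s: float = 0.04
    n_volumes: int = 6
    first_direction: str = X_FAST

    def __post_init__(self) -> None:
        if self.n_volumes < 1:
            raise ProtocolError("n_volumes must be >= 1")
        if min(self.ascans_per_bscan, self.bscans_per_volume) < 2:
            raise ProtocolError("need at least 2 A-scans and 2 B-scans")
        if self.volume_duration_s <= 0 or self.ascan_rate_hz <= 0:
            raise ProtocolError("durations and rates must be positive")
        if self.inter_volume_gap_s < 0:
            raise ProtocolError("inter-volume gap must be >= 0")
        if self.first_direction not in (X_FAST, Y_FAST):
            raise ProtocolError(f"unknown direction {self.first_direction!r}")

    # ---- derived geometry -------------------------------------------------
    @property
    def pitch_um(self) -> float:
        """Transverse A-scan spacing (um), fov / A-scans per B-scan."""
        return self.fov_mm * 1000.0 / self.ascans_per_bscan

    @property
    def bscan_period_s(self) -> float:
        """Time between consecutive B-scan starts (flyback folded in)."""
        return self.volume_duration_s / self.bscans_per_volume

    @property
    def total_duration_s(self) -> float:
        return (self.n_volumes * self.volume_duration_s
                + (self.n_volumes - 1) * self.inter_volume_gap_s)

    @property
    def directions(self) -> list[str]:
        """Alternating fast-axis direction per volume."""
        other = Y_FAST if self.first_direction == X_FAST else X_FAST
        return [self.first_direction if v % 2 == 0 else other
                for v in range(self.n_volumes)]

    # ---- timing -----------------------------------------------------------
    def volume_start_s(self, volume_index: int) -> float:
        if not 0 <= volume_index < self.n_volumes:
            raise ProtocolError(f"volume index {volume_index} out of range")
        return volume_index * (self.volume_duration_s + self.inter_volume_gap_s)

    def timestamps(self, volume_index: int) -> np.ndarray:
        """Per-A-scan acquisition time, shape (bscans, ascans), seconds.

        t = volume start + bscan index * B-scan period + ascan index / rate.
        """
        t0 = self.volume_start_s(volume_index)
        b = np.arange(self.bscans_per_volume)[:, None] * self.bscan_period_s
        a = np.arange(self.ascans_per_bscan)[None, :] / self.ascan_rate_hz
        return t0 + b + a

    # ---- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "fov_mm": self.fov_mm,
            "ascans_per_bscan": self.ascans_per_bscan,
            "bscans_per_volume": self.bscans_per_volume,
            "ascan_rate_hz": self.ascan_rate_hz,
            "volume_duration_s": self.volume_duration_s,
            "inter_volume_gap_s": self.inter_volume_gap_s,
            "n_volumes": self.n_volumes,
            "first_direction": self.first_direction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        return cls(**d)
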
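"""Averaged en face slab projections above a reference surface.

A slab is the per-pixel mean of fused-volume voxels whose depth lies in a
half-open interval [reference - upper, reference - lower) micrometres,
i.e. ``lower`` to ``upper`` um *above* (anterior to) the reference surface.
The default slab — 50 um thick, 27 to 77 um above Bruch's membrane —
captures deposits accumulating on the RPE.  Only voxels with a nonzero
contribution count participate; pixels with no valid voxel are masked.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fuse import BRM, FusedVolume


class SlabError(ValueError):
    pass


@dataclass(frozen=True)
class SlabSpec:
    """Axial interval above a reference surface, aggregated by mean."""

    reference: str = BRM
    lower_um: float = 27.0
    upper_um: float = 77.0
    aggregation: str = "mean"

    def __post_init__(self) -> None:
        if not self.upper_um > self.lower_um >= 0:
            raise SlabError("need upper > lower >= 0")
        if self.aggregation != "mean":
            raise SlabError("only mean aggregation is supported")

    @property
    def thickness_um(self) -> float:
        return self.upper_um - self.lower_um


@dataclass
class EnFaceSlab:
    """2D slab projection; masked pixels hold NaN in ``image``."""

    image: np.ndarray            # (ny, nx) float32, >= 0 where valid
    mask: np.ndarray             # True where at least one voxel contributed
    spec: SlabSpec
    pitch_um: float
    visit: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape

    def filled(self, value: float = 0.0) -> np.ndarray:
        out = self.image.copy()
        out[~self.mask] = value
        return out

    def save(self, stem) -> None:
        import tifffile
        stem = Path(stem)
        stem.parent.mkdir(parents=True, exist_ok=True)
        img = self.filled(0.0)
        scale = float(img.max()) or 1.0
        tifffile.imwrite(stem.with_suffix(".tif"),
                         np.round(img / scale * 65535).astype(np.uint16))
        stem.with_suffix(".json").write_text(json.dumps({
            "reference": self.spec.reference,
            "lower_um": self.spec.lower_um, "upper_um": self.spec.upper_um,
            "pitch_um": self.pitch_um, "visit": self.visit,
            "intensity_scale": scale,
            "mask": self.mask.astype(int).tolist()}))

    @classmethod
    def load(cls, stem) -> "EnFaceSlab":
        import tifffile
        stem = Path(stem)
        meta = json.loads(stem.with_suffix(".json").read_text())
        img = tifffile.imread(stem.with_suffix(".tif")).astype(np.float32)
        img = img / 65535.0 * meta["intensity_scale"]
        mask = np.array(meta["mask"], bool)
        img[~mask] = np.nan
        return cls(img, mask,
                   SlabSpec(meta["reference"], meta["lower_um"],
                            meta["upper_um"]),
                   meta["pitch_um"], meta.get("visit", ""))


def make_slab(fused: FusedVolume, spec: SlabSpec | None = None,
              visit: str = "") -> EnFaceSlab:
    """Project the mean intensity of the slab interval above the reference.

    The fused volume must know the reference surface in its flattened frame
    (``fused.surfaces[spec.reference]``); for the flattening reference this
    is the constant target depth, for other layers the re-flattened depth
    map.  Voxel depths are voxel centres; the interval is half-open
    [ref - upper, ref - lower).
    """
    spec = spec or SlabSpec()
    if spec.reference not in fused.surfaces:
        raise SlabError(
            f"fused volume has no {spec.reference!r} surface; "
            f"known: {sorted(fused.surfaces)}")
    ref_um = np.asarray(fused.surfaces[spec.reference], float)
    nz = fused.nz
    dz = fused.axial_um
    # voxel-row interval per pixel: rows whose centre lies in [ref-up, ref-lo)
    lo_row = np.ceil((ref_um - spec.upper_um) / dz - 1e-9).astype(int)
    hi_row = np.ceil((ref_um - spec.lower_um) / dz - 1e-9).astype(int)
    if np.any(lo_row < 0) or np.any(hi_row > nz):
        raise SlabError("slab interval leaves the axial range")

    has = fused.counts > 0
    v = np.where(has, fused.grid, 0.0)
    csum_v = np.concatenate([np.zeros((1,) + v.shape[1:]),
                             np.cumsum(v, axis=0)])
    csum_n = np.concatenate([np.zeros((1,) + v.shape[1:]),
                             np.cumsum(has, axis=0)])
    take = lambda c, r: np.take_along_axis(
        c, r[None, ...], axis=0)[0]
    tot = take(csum_v, hi_row) - take(csum_v, lo_row)
    cnt = take(csum_n, hi_row) - take(csum_n, lo_row)
    mask = cnt > 0
    img = np.divide(tot, cnt, out=np.full(tot.shape, np.nan), where=mask)
    return EnFaceSlab(img.astype(np.float32), mask, spec, fused.pitch_um,
                      visit)


def compare_slabs(specs: list[SlabSpec],
                  fused: FusedVolume | dict[str, FusedVolume],
                  visit: str = "") -> list[EnFaceSlab]:
    """Batch slab generation with shared geometry (co-registered pixels).

    ``fused`` may be a single fused volume carrying all needed reference
    surfaces, or a mapping reference-layer -> fused volume for slabs that
    require re-flattening to a different surface.
    """
    out = []
    for spec in specs:
        fv = fused[spec.reference] if isinstance(fused, dict) else fused
        out.append(make_slab(fv, spec, visit))
    shapes = {s.shape for s in out}
    if len(shapes) > 1:
        raise SlabError(f"slab geometries differ: {shapes}")
    return out
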
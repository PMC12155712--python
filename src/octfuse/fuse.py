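"""Surface segmentation, surface averaging, flattening and volume merging.

Bruch's membrane (BrM) is located in each original B-scan by a
deterministic dynamic-programming surface finder: a minimum-cost continuous
path (bounded slope) through an axial-gradient cost image that rewards
strong bright-to-dark transitions, refined to the local reflectivity peak
of the membrane line.  The posterior RPE boundary (pRPE) is found as the
strongest remaining edge anterior to BrM.  Per-volume surfaces are
motion-corrected with the estimated displacement model and averaged onto a
common transverse grid; the averaged BrM depth is subtracted from all
A-scan positions so the merged, fused volume is flat at a fixed depth row.

Merging bins every motion-corrected sample into the output grid with
trilinear weights and stores per-voxel contribution counts; the fused
intensity is the weighted mean of all contributions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from ._gridops import bin_bilinear, bin_trilinear
from .motion import CorrectedSamples, DisplacementModel
from .volume import RasterVolume

BRM = "BrM"
PRPE = "pRPE"


class FusionError(RuntimeError):
    pass


@dataclass
class Surface:
    """Per-A-scan (scan frame) or per-pixel (fused frame) depth map in um.

    In the scan frame the array is (n_bscans, n_ascans) and ``volume``
    references the source; after :func:`mean_surface` it is (ny, nx) on the
    nominal transverse grid and ``volume`` is None.
    """

    depth_um: np.ndarray
    valid: np.ndarray
    layer: str
    volume: RasterVolume | None = None
    pitch_um: float = 0.0

    def __post_init__(self) -> None:
        self.depth_um = np.asarray(self.depth_um, float)
        self.valid = np.asarray(self.valid, bool)
        if self.depth_um.shape != self.valid.shape:
            raise ValueError("depth and validity shapes differ")
        if np.any(~np.isfinite(self.depth_um[self.valid])):
            raise ValueError("valid surface depths must be finite")

    def filled(self) -> np.ndarray:
        """Depth map with invalid positions filled from the nearest valid
        position (used before flattening; blink gaps leave holes)."""
        if self.valid.all():
            return self.depth_um
        if not self.valid.any():
            raise FusionError("surface has no valid positions")
        _, idx = ndimage.distance_transform_edt(~self.valid,
                                                return_indices=True)
        return self.depth_um[tuple(idx)]


# --------------------------------------------------------------------------
# segmentation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentOptions:
    slope_vox: int = 2            # max |dz| per A-scan step of the path
    step_penalty: float = 0.05    # transition cost per voxel of slope
    smooth_z: float = 1.0         # pre-smoothing (voxels) along depth
    smooth_fast: float = 1.0      # pre-smoothing along the fast axis
    mass_rel: float = 0.25        # bright-mass threshold, rel. to robust max
    brightness_pull: float = 2.0  # reward (voxels) for path brightness
    prpe_margin_vox: int = 3      # pRPE search ends this far above BrM
    min_brightness: float = 0.25  # rel. brightness for a BrM column to count


def _dp_path(cost: np.ndarray, slope: int, penalty: float) -> np.ndarray:
    """Minimum-cost continuous path through each B-scan.

    cost : (nb, nf, nz) — per B-scan, per A-scan column cost.
    Returns integer path (nb, nf).  Vectorized over B-scans; the recurrence
    runs along the fast axis with a bounded-slope transition window.
    """
    nb, nf, nz = cost.shape
    D = cost[:, 0].copy()
    back = np.zeros((nf, nb, nz), np.int8)
    offs = range(-slope, slope + 1)
    for a in range(1, nf):
        best = np.full((nb, nz), np.inf)
        arg = np.zeros((nb, nz), np.int8)
        for o in offs:
            src = np.full((nb, nz), np.inf)
            if o >= 0:
                src[:, o:] = D[:, :nz - o] if o else D
            else:
                src[:, :o] = D[:, -o:]
            src = src + penalty * abs(o)
            take = src < best
            best[take] = src[take]
            arg[take] = o
        D = best + cost[:, a]
        back[a] = arg
    path = np.zeros((nb, nf), np.int64)
    path[:, -1] = np.argmin(D, axis=1)
    rows = np.arange(nb)
    for a in range(nf - 1, 0, -1):
        path[:, a - 1] = path[:, a] - back[a, rows, path[:, a]]
    return path


def _axial_drop(grid_s: np.ndarray) -> np.ndarray:
    """Bright-to-dark axial edge strength, (nz, nb, nf) -> same shape."""
    d = -np.diff(grid_s, axis=0, append=grid_s[-1:])
    return np.clip(d, 0.0, None)


def _brm_path(g: np.ndarray, opts: SegmentOptions) -> np.ndarray:
    """BrM as the posterior-most bright structure: the DP path minimizes the
    above-threshold bright mass remaining *below* the path while rewarding
    brightness *at* the path — which parks it on the membrane line centre,
    posterior to the RPE complex but anterior to the dark choroid."""
    bright = float(np.quantile(g, 0.999))
    mass = np.clip(g - opts.mass_rel * bright, 0.0, None)
    # exclusive reverse cumulative sum along z: bright mass strictly below.
    # Units are intensity * voxels, so the brightness reward acts as an
    # effective line width: leaving a real line below the path always costs
    # more than the reward for sitting on something brighter above it.
    below = np.flip(np.cumsum(np.flip(mass, 0), axis=0), 0) - mass
    cost = (below - opts.brightness_pull * g) / bright
    return _dp_path(np.transpose(cost, (1, 2, 0)), opts.slope_vox,
                    opts.step_penalty)


def segment_surface(volume: RasterVolume, layer: str = BRM,
                    opts: SegmentOptions | None = None) -> Surface:
    """Locate BrM (or the posterior RPE boundary) in each original B-scan.

    BrM is the posterior-most continuous bright line (nothing reflective
    lies below it but choroid); the posterior RPE boundary is the last
    strong bright-to-dark edge anterior to BrM.  B-scans where the path has
    no reflective support are marked invalid.
    """
    opts = opts or SegmentOptions()
    if layer not in (BRM, PRPE):
        raise ValueError(f"unknown layer {layer!r}")
    g = ndimage.gaussian_filter(
        volume.grid.astype(np.float32),
        (opts.smooth_z, 0, opts.smooth_fast))
    bright = float(np.quantile(g, 0.999))
    brm = _brm_path(g, opts)
    nz = volume.nz
    gT = np.transpose(g, (1, 2, 0))             # (nb, nf, nz)

    if layer == BRM:
        # snap to the membrane line's reflectivity peak with sub-voxel
        # parabolic refinement (removes the mass/brightness trade-off bias)
        win = np.arange(-2, 3)
        idx = np.clip(brm[..., None] + win[None, None, :], 0, nz - 1)
        vals = np.take_along_axis(gT, idx, axis=2)
        peak = brm + win[np.argmax(vals, axis=2)]
        peak = np.clip(peak, 1, nz - 2)
        z0 = np.take_along_axis(gT, (peak - 1)[..., None], axis=2)[..., 0]
        z1 = np.take_along_axis(gT, peak[..., None], axis=2)[..., 0]
        z2 = np.take_along_axis(gT, (peak + 1)[..., None], axis=2)[..., 0]
        den = z0 - 2 * z1 + z2
        frac = np.where(np.abs(den) > 1e-9,
                        0.5 * (z0 - z2) / np.where(den == 0, 1, den), 0.0)
        frac = np.clip(frac, -0.5, 0.5)
        depth = (peak + frac) * volume.axial_um
        support = z1
        ok_col = support > opts.min_brightness * bright
    else:
        # posterior-most strong drop anterior of BrM: minimize the strong
        # drop mass left below the path (within the window) while sitting
        # on a strong drop
        drop = _axial_drop(g)
        colmax = drop.max(axis=0, keepdims=True)
        strong = np.clip(drop - 0.3 * colmax, 0.0, None)
        zidx = np.arange(nz)[:, None, None]
        lim = (brm - opts.prpe_margin_vox)[None, ...]
        strong = np.where(zidx < lim, strong, 0.0)
        below = np.flip(np.cumsum(np.flip(strong, 0), axis=0), 0) - strong
        dmax = max(float(drop.max()), 1e-6)
        cost = (below - drop) / dmax
        cost = np.where(zidx < lim, cost, 1e3)
        prpe = _dp_path(np.transpose(cost, (1, 2, 0)), opts.slope_vox,
                        opts.step_penalty)
        depth = prpe.astype(float) * volume.axial_um
        picked = np.take_along_axis(np.transpose(drop, (1, 2, 0)),
                                    prpe[..., None], axis=2)[..., 0]
        ok_col = picked > 0.1 * float(drop.max())

    valid = volume.valid_bscan[:, None] & ok_col
    # a B-scan whose columns mostly failed the support test is unreliable
    bad_b = ok_col.mean(axis=1) < 0.5
    valid[bad_b] = False
    return Surface(depth, valid, layer, volume, volume.protocol.pitch_um)


# --------------------------------------------------------------------------
# surface averaging and flattening
# --------------------------------------------------------------------------

def mean_surface(surfaces: list[Surface], model: DisplacementModel,
                 shape: tuple[int, int] | None = None) -> Surface:
    """Motion-correct each volume's surface and average depths per position.

    Each surface point is shifted by -evaluate(t) (transverse and axial),
    then binned bilinearly onto the nominal transverse grid; positions with
    no valid contribution are masked.
    """
    if not surfaces:
        raise ValueError("no surfaces given")
    pitch = surfaces[0].pitch_um
    layer = surfaces[0].layer
    if shape is None:
        n = max(max(s.volume.nslow, s.volume.nfast) for s in surfaces)
        shape = (n, n)
    Wt = np.zeros(shape[0] * shape[1])
    WD = np.zeros_like(Wt)
    for s in surfaces:
        if s.volume is None:
            raise ValueError("mean_surface needs scan-frame surfaces")
        vol = s.volume
        t = vol.timestamps().ravel()
        disp = model.evaluate(vol.volume_index, t)
        x, y = vol.ascan_xy_um()
        cx = (x.ravel() - disp[:, 0]) / pitch
        cy = (y.ravel() - disp[:, 1]) / pitch
        d = s.depth_um.ravel() - disp[:, 2]
        w = s.valid.ravel().astype(float)
        W, WD_ = bin_bilinear(cy, cx, d, shape, sample_weight=w)
        Wt += W
        WD += WD_
    valid = Wt > 1e-6
    depth = np.divide(WD, Wt, out=np.zeros_like(WD), where=valid)
    return Surface(depth.reshape(shape), valid.reshape(shape), layer,
                   None, pitch)


@dataclass
class FusedVolume:
    """Flattened, merged intensity grid with per-voxel contribution counts.

    The reference surface lies at row ``ref_row`` (so ``ref_row * axial_um``
    um from the top); ``surfaces`` holds depth maps of known layers in the
    flattened frame for slab generation.
    """

    grid: np.ndarray               # (nz, ny, nx) float32
    counts: np.ndarray             # (nz, ny, nx) float64 weights
    ref_layer: str
    ref_row: int
    axial_um: float
    pitch_um: float
    surfaces: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def nz(self) -> int:
        return self.grid.shape[0]

    def save(self, stem) -> None:
        import tifffile
        stem = Path(stem)
        stem.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(stem.with_suffix(".intensity.tif"), self.grid)
        tifffile.imwrite(stem.with_suffix(".counts.tif"),
                         self.counts.astype(np.float32))
        sc = {"ref_layer": self.ref_layer, "ref_row": self.ref_row,
              "axial_um": self.axial_um, "pitch_um": self.pitch_um,
              "surfaces": {k: v.tolist() for k, v in self.surfaces.items()},
              "meta": self.meta}
        stem.with_suffix(".json").write_text(json.dumps(sc))

    @classmethod
    def load(cls, stem) -> "FusedVolume":
        import tifffile
        stem = Path(stem)
        sc = json.loads(stem.with_suffix(".json").read_text())
        return cls(tifffile.imread(stem.with_suffix(".intensity.tif")),
                   tifffile.imread(stem.with_suffix(".counts.tif")).astype(float),
                   sc["ref_layer"], sc["ref_row"], sc["axial_um"],
                   sc["pitch_um"],
                   {k: np.array(v) for k, v in sc["surfaces"].items()},
                   sc.get("meta", {}))


def flatten_and_merge(samples: list[CorrectedSamples], ref: Surface,
                      target_row: int | None = None,
                      shape: tuple[int, int, int] | None = None
                      ) -> FusedVolume:
    """Flatten all corrected samples to the reference surface and merge.

    Every sample's axial position is shifted by (target - ref depth at its
    transverse position); samples are binned with trilinear weights; voxel
    intensity is the weighted mean of contributions and the summed weights
    are kept as contribution counts.  Transverse positions are never
    altered (en face topology is preserved).
    """
    if not samples:
        raise FusionError("no samples to merge")
    pitch = samples[0].pitch_um
    axial = samples[0].axial_um
    nz = max(s.nz for s in samples)
    if target_row is None:
        target_row = int(round(0.75 * nz))
    if shape is None:
        ref_shape = ref.depth_um.shape
        shape = (nz, ref_shape[0], ref_shape[1])
    target_um = target_row * axial

    ref_map = ref.filled()
    Wt = np.zeros(shape[0] * shape[1] * shape[2])
    WI = np.zeros_like(Wt)
    for s in samples:
        cx = s.xy_um[:, 0] / pitch
        cy = s.xy_um[:, 1] / pitch
        ref_at = ndimage.map_coordinates(ref_map, [cy, cx], order=1,
                                         mode="nearest")
        # axial shift: sample depth + dz, moved so ref sits at target
        shift_um = s.dz_um + target_um - ref_at
        z_um = np.arange(s.nz) * axial
        cz = (z_um[:, None] + shift_um[None, :]) / axial
        w = s.valid.astype(float)
        nzs = s.nz
        W_, WI_ = bin_trilinear(
            cz,
            np.broadcast_to(cy[None, :], (nzs, cy.size)),
            np.broadcast_to(cx[None, :], (nzs, cx.size)),
            s.columns, shape,
            sample_weight=np.broadcast_to(w[None, :], (nzs, w.size)))
        Wt += W_
        WI += WI_
    grid = np.divide(WI, Wt, out=np.zeros_like(WI), where=Wt > 1e-9)
    fused = FusedVolume(grid.reshape(shape).astype(np.float32),
                        Wt.reshape(shape), ref.layer, target_row, axial,
                        pitch)
    fused.surfaces[ref.layer] = np.full(shape[1:], target_um)
    return fused


def as_raster_volume(fused: FusedVolume, protocol, direction="x-fast"
                     ) -> RasterVolume:
    """View a fused grid as a RasterVolume (e.g. to re-segment surfaces);
    requires a protocol matching the fused transverse shape."""
    return RasterVolume(fused.grid, protocol, direction, 0, fused.axial_um)
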
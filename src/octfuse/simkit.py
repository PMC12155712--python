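"""Synthetic retina phantoms and raster-scan acquisition simulation.

The simulator builds a layered retinal reflectivity phantom (ILM, IS/OS,
RPE band, Bruch's membrane, optional soft drusen and subretinal drusenoid
deposits), simulates fixational eye motion (drift random walk plus Poisson
saccades), and resamples the phantom A-scan by A-scan along the acquisition
timeline to produce raster volumes corrupted by motion, illumination bias,
multiplicative speckle, detector noise and blinks.  Every corruption is
exported as ground truth so downstream estimators can be tested against it.

Geometry and units follow the package convention: depths in micrometres
increase posteriorly, voxel grids are (nz, nslow, nfast).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .protocol import AcquisitionProtocol, X_FAST
from .volume import RasterVolume


class PhantomConfigError(ValueError):
    """Phantom configuration violates layer-ordering or range invariants."""


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Druse:
    """Soft druse: sub-RPE dome elevating RPE/IS-OS/ILM but not BrM."""
    x_um: float
    y_um: float
    radius_um: float
    height_um: float


@dataclass(frozen=True)
class SDD:
    """Dot subretinal drusenoid deposit between RPE and photoreceptors.

    Stage 1 deposits sit on the RPE without disturbing the IS/OS; stage 2
    deposits reach and locally elevate the IS/OS; stage 3 deposits
    additionally reduce IS/OS reflectivity above the deposit.
    """
    x_um: float
    y_um: float
    radius_um: float
    stage: int = 1


@dataclass(frozen=True)
class PhantomConfig:
    """Layered-retina phantom parameters.

    Depths are layer *anterior* positions in um from the grid top, strictly
    ordered ILM < IS/OS < RPE < BrM.  The RPE band spans [rpe, brm); soft
    drusen insert reflective material between the elevated RPE band and the
    stationary BrM.
    """

    nx: int = 500
    ny: int = 500
    nz: int = 256
    pitch_um: float = 12.0
    axial_um: float = 2.0

    # layer anterior depths (um)
    ilm_um: float = 60.0
    isos_um: float = 220.0
    rpe_um: float = 270.0
    brm_um: float = 298.0
    rpe_band_um: float = 20.0      # RPE band thickness under drusen
    line_sigma_um: float = 4.0     # thin-layer Gaussian half-width

    # reflectivities (arbitrary linear units)
    refl_background: float = 0.02
    refl_inner: float = 0.10
    refl_outer_segments: float = 0.06
    refl_ilm: float = 0.50
    refl_isos: float = 0.90
    refl_rpe: float = 1.00
    refl_brm: float = 0.70
    refl_choroid: float = 0.05
    refl_druse: float = 0.50
    refl_sdd: float = 0.85

    undulation_amp_um: float = 0.0
    undulation_corr_um: float = 600.0

    drusen: tuple[Druse, ...] = ()
    sdds: tuple[SDD, ...] = ()

    # SDD geometry by stage: dome height (um) and IS/OS dimming factor
    sdd_heights_um: tuple[float, float, float] = (20.0, 55.0, 70.0)
    stage3_isos_dimming: float = 0.6
    isos_clearance_um: float = 4.0

    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 4:
            raise PhantomConfigError("grid too small")
        if self.pitch_um <= 0 or self.axial_um <= 0:
            raise PhantomConfigError("spacings must be positive")
        if not (self.ilm_um < self.isos_um < self.rpe_um < self.brm_um):
            raise PhantomConfigError(
                "layer depths must be ordered ILM < IS/OS < RPE < BrM")
        for s in self.sdds:
            if s.stage not in (1, 2, 3):
                raise PhantomConfigError(f"SDD stage must be 1-3, got {s.stage}")
            if s.radius_um <= 0:
                raise PhantomConfigError("SDD radius must be positive")
        for d in self.drusen:
            if d.radius_um <= 0 or d.height_um <= 0:
                raise PhantomConfigError("druse radius/height must be positive")


@dataclass
class Phantom:
    """Ground-truth reflectivity grid plus the surfaces that generated it."""

    grid: np.ndarray                       # (nz, ny, nx) float32
    surfaces: dict[str, np.ndarray]        # layer -> (ny, nx) depth um
    sdd_truth: list[SDD]
    config: PhantomConfig

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape


# --------------------------------------------------------------------------
# random-field helper
# --------------------------------------------------------------------------

def smooth_random_field(shape: tuple[int, int], corr_px: float,
                        amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean Gaussian random field with given correlation length (px)
    scaled to the requested peak amplitude (max |field| == amplitude)."""
    if amplitude == 0:
        return np.zeros(shape)
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=corr_px,
                                mode="reflect")
    peak = np.max(np.abs(f))
    if peak == 0:
        return np.zeros(shape)
    return f * (amplitude / peak)


def _dome(xx_um, yy_um, cx, cy, radius, height):
    """Spherical-cap height profile, zero outside the footprint."""
    r2 = (xx_um - cx) ** 2 + (yy_um - cy) ** 2
    h = np.zeros_like(r2)
    inside = r2 < radius ** 2
    h[inside] = height * np.sqrt(1.0 - r2[inside] / radius ** 2)
    return h


# --------------------------------------------------------------------------
# phantom construction
# --------------------------------------------------------------------------

def make_phantom(cfg: PhantomConfig) -> Phantom:
    """Render the layered phantom and its ground-truth surfaces.

    Raises :class:`PhantomConfigError` if undulation/drusen/SDD insertion
    breaks the strict layer ordering or pushes a surface off the grid.
    """
    rng = np.random.default_rng(cfg.seed)
    ny, nx = cfg.ny, cfg.nx
    x_um = np.arange(nx) * cfg.pitch_um
    y_um = np.arange(ny) * cfg.pitch_um
    xx, yy = np.meshgrid(x_um, y_um)            # (ny, nx)

    und = smooth_random_field((ny, nx), cfg.undulation_corr_um / cfg.pitch_um,
                              cfg.undulation_amp_um, rng)

    dome = np.zeros((ny, nx))
    for d in cfg.drusen:
        dome += _dome(xx, yy, d.x_um, d.y_um, d.radius_um, d.height_um)

    # SDD dome heights and the IS/OS elevation they force
    sdd_height = np.zeros((ny, nx))
    stage3_dim = np.zeros((ny, nx))
    for s in cfg.sdds:
        h = cfg.sdd_heights_um[s.stage - 1]
        prof = _dome(xx, yy, s.x_um, s.y_um, s.radius_um, h)
        sdd_height = np.maximum(sdd_height, prof)
        if s.stage == 3:
            stage3_dim = np.maximum(
                stage3_dim, cfg.stage3_isos_dimming * (prof > 0))

    gap = cfg.rpe_um - cfg.isos_um
    isos_lift = np.maximum(0.0, sdd_height - gap + cfg.isos_clearance_um)

    brm_s = cfg.brm_um + und
    rpe_s = cfg.rpe_um + und - dome
    isos_s = cfg.isos_um + und - dome - isos_lift
    ilm_s = cfg.ilm_um + und - dome

    depth_max = (cfg.nz - 1) * cfg.axial_um
    if not (np.all(ilm_s < isos_s) and np.all(isos_s < rpe_s)
            and np.all(rpe_s < brm_s)):
        raise PhantomConfigError("layer ordering violated after insertion")
    if ilm_s.min() < 0 or brm_s.max() > depth_max:
        raise PhantomConfigError("a surface leaves the axial grid range")

    prpe_s = np.minimum(rpe_s + cfg.rpe_band_um, brm_s)

    grid = np.empty((cfg.nz, ny, nx), dtype=np.float32)
    z_um = np.arange(cfg.nz) * cfg.axial_um
    sig = cfg.line_sigma_um
    # render in slow-axis chunks to bound peak memory on large phantoms
    chunk = max(1, int(8e6 / (cfg.nz * nx)))
    for j0 in range(0, ny, chunk):
        j1 = min(ny, j0 + chunk)
        z = z_um[:, None, None]
        ilm, isos = ilm_s[None, j0:j1], isos_s[None, j0:j1]
        rpe, brm = rpe_s[None, j0:j1], brm_s[None, j0:j1]
        g = np.full((cfg.nz, j1 - j0, nx), cfg.refl_background, dtype=np.float32)
        g[( z >= ilm) & (z < isos)] = cfg.refl_inner
        g[(z >= isos) & (z < rpe)] = cfg.refl_outer_segments
        g[z >= brm] = cfg.refl_choroid
        # RPE band then sub-RPE druse material down to BrM
        band_lo = np.minimum(rpe + cfg.rpe_band_um, brm)
        g[(z >= rpe) & (z < band_lo)] = cfg.refl_rpe
        g[(z >= band_lo) & (z < brm)] = cfg.refl_druse
        # SDD deposits resting on the RPE
        h = sdd_height[None, j0:j1]
        np.maximum(g, np.float32(cfg.refl_sdd) * ((z >= rpe - h) & (z < rpe) & (h > 0)),
                   out=g)
        # thin hyperreflective lines (max composition keeps peaks at the
        # configured reflectivities)
        dim = stage3_dim[None, j0:j1]
        for surf, amp in ((ilm, cfg.refl_ilm),
                          (isos, cfg.refl_isos * (1.0 - dim)),
                          (brm, cfg.refl_brm)):
            line = np.asarray(amp * np.exp(-0.5 * ((z - surf) / sig) ** 2),
                              dtype=np.float32)
            np.maximum(g, line, out=g)
        grid[:, j0:j1] = g

    surfaces = {"ILM": ilm_s, "ISOS": isos_s, "pRPE": prpe_s, "BrM": brm_s,
                "RPE": rpe_s}
    return Phantom(grid=grid, surfaces=surfaces, sdd_truth=list(cfg.sdds),
                   config=cfg)


# --------------------------------------------------------------------------
# eye motion
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MotionParams:
    """Fixational eye-motion statistics.

    drift_sd_um : transverse drift random-walk scale per axis (um/sqrt(s)).
    axial_sd_um : axial drift scale (um/sqrt(s)).
    saccade_rate_hz : Poisson rate of microsaccades (events/s).
    saccade_mean_um / saccade_sd_um : jump-amplitude distribution.
    """
    drift_sd_um: float = 10.0
    axial_sd_um: float = 5.0
    saccade_rate_hz: float = 0.0
    saccade_mean_um: float = 60.0
    saccade_sd_um: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.drift_sd_um, self.axial_sd_um, self.saccade_rate_hz,
               self.saccade_sd_um) < 0:
            raise ValueError("motion rates/scales must be >= 0")


@dataclass
class MotionTrace:
    """Time-continuous 3D eye displacement with saccade step discontinuities.

    The drift component is stored as piecewise-linear knots; saccades are
    instantaneous transverse jumps added for all t >= saccade time, so the
    trace is continuous between saccades and right-continuous at them.
    Displacements are in um, ordered (dx, dy, dz).
    """

    knot_t: np.ndarray              # (K,) strictly increasing, s
    knot_disp: np.ndarray           # (K, 3) um, drift component
    saccade_times: np.ndarray       # (M,) s
    saccade_jumps: np.ndarray       # (M, 3) um

    def __post_init__(self) -> None:
        self.knot_t = np.asarray(self.knot_t, float)
        self.knot_disp = np.asarray(self.knot_disp, float)
        self.saccade_times = np.asarray(self.saccade_times, float)
        self.saccade_jumps = np.asarray(self.saccade_jumps, float).reshape(-1, 3)
        if np.any(np.diff(self.knot_t) <= 0):
            raise ValueError("knot times must be strictly increasing")

    @property
    def t_span(self) -> tuple[float, float]:
        return float(self.knot_t[0]), float(self.knot_t[-1])

    def evaluate(self, t) -> np.ndarray:
        """Displacement at times t; shape t.shape + (3,)."""
        t = np.asarray(t, float)
        lo, hi = self.t_span
        if np.any(t < lo - 1e-9) or np.any(t > hi + 1e-9):
            raise ValueError("evaluation time outside the trace span")
        out = np.empty(t.shape + (3,))
        for ax in range(3):
            out[..., ax] = np.interp(t, self.knot_t, self.knot_disp[:, ax])
        for ts, jump in zip(self.saccade_times, self.saccade_jumps):
            out[t >= ts] += jump
        return out

    # ---- serialization (JSON round-trips doubles exactly) ----------------
    def to_dict(self) -> dict:
        return {"knot_t": self.knot_t.tolist(),
                "knot_disp": self.knot_disp.tolist(),
                "saccade_times": self.saccade_times.tolist(),
                "saccade_jumps": self.saccade_jumps.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "MotionTrace":
        return cls(np.array(d["knot_t"]), np.array(d["knot_disp"]),
                   np.array(d["saccade_times"]),
                   np.array(d["saccade_jumps"]).reshape(-1, 3))

    @classmethod
    def zero(cls, t0: float, t1: float) -> "MotionTrace":
        return cls(np.array([t0, t1]), np.zeros((2, 3)),
                   np.empty(0), np.empty((0, 3)))


def simulate_motion(duration_s: float, params: MotionParams,
                    t0: float = 0.0, dt: float = 1e-3) -> MotionTrace:
    """Draw one eye-motion realization over [t0, t0 + duration].

    Drift is an integrated Gaussian random walk sampled at ``dt`` (1 ms by
    default) with per-step sd = drift_sd * sqrt(dt); saccade events follow a
    Poisson process, each adding an instantaneous 2D transverse jump with
    amplitude |N(mean, sd)| in a uniformly random direction.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(params.seed)
    n = max(2, int(np.ceil(duration_s / dt)) + 1)
    t = np.linspace(t0, t0 + duration_s, n)
    dt_eff = duration_s / (n - 1)
    steps = rng.standard_normal((n - 1, 3))
    steps[:, :2] *= params.drift_sd_um * np.sqrt(dt_eff)
    steps[:, 2] *= params.axial_sd_um * np.sqrt(dt_eff)
    disp = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])

    n_sacc = rng.poisson(params.saccade_rate_hz * duration_s)
    times = np.sort(t0 + rng.uniform(0, duration_s, size=n_sacc))
    amps = np.abs(rng.normal(params.saccade_mean_um, params.saccade_sd_um,
                             size=n_sacc))
    angles = rng.uniform(0, 2 * np.pi, size=n_sacc)
    jumps = np.column_stack([amps * np.cos(angles), amps * np.sin(angles),
                             np.zeros(n_sacc)])
    return MotionTrace(t, disp, times, jumps)


# --------------------------------------------------------------------------
# acquisition
# --------------------------------------------------------------------------

def acquire(phantom: Phantom, protocol: AcquisitionProtocol,
            traces: list[MotionTrace] | None = None,
            bias=None,
            speckle_contrast: float = 0.0,
            detector_noise_sd: float = 0.0,
            seed: int = 0) -> list[RasterVolume]:
    """Simulate the multi-volume raster acquisition of a phantom.

    Each A-scan samples the phantom at its nominal transverse position plus
    the eye-motion trace evaluated at that A-scan's acquisition time
    (trilinear interpolation; sampling fully outside the phantom is filled
    with background and flagged).  Multiplicative illumination bias and
    speckle, then additive detector noise, are applied after sampling.

    Parameters
    ----------
    traces : one MotionTrace per volume, or None for a static acquisition.
    bias : None, a per-volume list, a (nslow, nfast) gain array, or a
        callable (volume_index, nslow, nfast) -> gain array.
    speckle_contrast : c in [0, 1]; intensities are multiplied by
        1 + c*(E-1) with E ~ Exp(1), i.e. fully developed speckle at c = 1.
    """
    cfg = phantom.config
    if traces is None:
        traces = [MotionTrace.zero(-1.0, protocol.total_duration_s + 1.0)
                  for _ in range(protocol.n_volumes)]
    if len(traces) != protocol.n_volumes:
        raise ValueError("need one motion trace per volume")

    nz = cfg.nz
    z_idx = np.arange(nz)
    ss = np.random.SeedSequence(seed)
    vol_rngs = [np.random.default_rng(s) for s in ss.spawn(protocol.n_volumes)]

    volumes: list[RasterVolume] = []
    for v in range(protocol.n_volumes):
        direction = protocol.directions[v]
        t = protocol.timestamps(v)                       # (nslow, nfast)
        nslow, nfast = t.shape
        vol = RasterVolume(np.zeros((nz, nslow, nfast), np.float32), protocol,
                           direction, v, cfg.axial_um)
        x_um, y_um = vol.ascan_xy_um()
        disp = traces[v].evaluate(t)                     # (nslow, nfast, 3)
        ix = (x_um + disp[..., 0]) / cfg.pitch_um
        iy = (y_um + disp[..., 1]) / cfg.pitch_um
        dz_vox = disp[..., 2] / cfg.axial_um

        clipped = ((ix < -0.5) | (ix > cfg.nx - 0.5)
                   | (iy < -0.5) | (iy > cfg.ny - 0.5))
        grid = vol.grid
        chunk = max(1, int(4e6 / (nz * nfast)))
        for b0 in range(0, nslow, chunk):
            b1 = min(nslow, b0 + chunk)
            sl = np.s_[b0:b1]
            cz = z_idx[:, None, None] + dz_vox[None, sl]
            cy = np.broadcast_to(iy[None, sl], cz.shape)
            cx = np.broadcast_to(ix[None, sl], cz.shape)
            grid[:, sl] = ndimage.map_coordinates(
                phantom.grid, [cz, cy, cx], order=1, mode="constant",
                cval=cfg.refl_background).astype(np.float32)
        if clipped.any():
            grid[:, clipped] = cfg.refl_background

        if bias is not None:
            g = bias(v, nslow, nfast) if callable(bias) else (
                bias[v] if isinstance(bias, (list, tuple)) else bias)
            g = np.asarray(g, np.float32)
            if g.shape != (nslow, nfast):
                raise ValueError("bias gain must be (nslow, nfast)")
            grid *= g[None]

        rng = vol_rngs[v]
        if speckle_contrast > 0:
            e = rng.exponential(1.0, size=grid.shape).astype(np.float32)
            grid *= 1.0 + speckle_contrast * (e - 1.0)
        if detector_noise_sd > 0:
            grid += rng.normal(0.0, detector_noise_sd,
                               size=grid.shape).astype(np.float32)
        np.clip(grid, 0.0, None, out=grid)

        vol.meta["clipped_ascans"] = int(clipped.sum())
        vol.meta["seed"] = seed
        volumes.append(vol)
    return volumes


def inject_blinks(volume: RasterVolume,
                  intervals: list[tuple[int, int]],
                  noise_floor: float = 0.005) -> RasterVolume:
    """Replace the B-scans in the given [start, stop) index ranges with the
    detector noise floor, recording the merged ranges as ground truth.

    Overlapping or adjacent ranges are merged.  Returns a new volume.
    """
    out = volume.copy()
    if not intervals:
        out.meta.setdefault("blinks", [])
        return out
    for b0, b1 in intervals:
        if not (0 <= b0 < b1 <= volume.nslow):
            raise ValueError(f"blink interval ({b0}, {b1}) outside B-scan range")
    merged: list[list[int]] = []
    for b0, b1 in sorted(intervals):
        if merged and b0 <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b1)
        else:
            merged.append([b0, b1])
    for b0, b1 in merged:
        out.grid[:, b0:b1, :] = noise_floor
    out.meta["blinks"] = [tuple(m) for m in merged]
    out.meta["noise_floor"] = noise_floor
    return out


# --------------------------------------------------------------------------
# scene helpers
# --------------------------------------------------------------------------

def random_sdds(n: int, extent_um: float, rng: np.random.Generator,
                margin_um: float = 100.0, min_sep_um: float = 150.0,
                radius_um: tuple[float, float] = (30.0, 60.0),
                stages: tuple[int, ...] = (1, 2, 3)) -> list[SDD]:
    """Place n dot SDDs uniformly with a minimum separation (dart throwing).

    Dot-SDD density in SDD-positive intermediate AMD eyes is a few deposits
    per mm^2; callers choose n accordingly for their field of view.
    """
    placed: list[SDD] = []
    tries = 0
    while len(placed) < n and tries < 10_000:
        tries += 1
        x = float(rng.uniform(margin_um, extent_um - margin_um))
        y = float(rng.uniform(margin_um, extent_um - margin_um))
        if any((x - s.x_um) ** 2 + (y - s.y_um) ** 2 < min_sep_um ** 2
               for s in placed):
            continue
        placed.append(SDD(x, y, float(rng.uniform(*radius_um)),
                          int(rng.choice(stages))))
    if len(placed) < n:
        raise PhantomConfigError(
            f"could not place {n} SDDs with {min_sep_um} um separation")
    return placed


def longitudinal_sdd_pair(extent_um: float, n_stable: int, n_regress: int,
                          n_fuse_pairs: int, n_new: int, seed: int,
                          pair_sep_um: float = 80.0,
                          min_sep_um: float = 250.0
                          ) -> tuple[list[SDD], list[SDD], dict]:
    """Baseline and follow-up SDD lists realizing known longitudinal fates.

    Stable deposits persist in place; regressed ones vanish; each fuse pair
    (two deposits ``pair_sep_um`` apart) is replaced by one larger deposit
    at the pair midpoint; new deposits appear only at follow-up.  Returns
    (baseline, followup, expected) where expected holds the category counts
    the tracker should recover (each member of a merged pair counts once
    under "fused").
    """
    rng = np.random.default_rng(seed)
    anchors = random_sdds(n_stable + n_regress + n_fuse_pairs + n_new,
                          extent_um, rng, margin_um=120.0,
                          min_sep_um=min_sep_um)
    stable = anchors[:n_stable]
    regress = anchors[n_stable:n_stable + n_regress]
    pair_anchor = anchors[n_stable + n_regress:
                          n_stable + n_regress + n_fuse_pairs]
    new = anchors[n_stable + n_regress + n_fuse_pairs:]

    baseline = list(stable) + list(regress)
    followup = list(stable)
    for a in pair_anchor:
        ang = rng.uniform(0, 2 * np.pi)
        dx = pair_sep_um / 2 * np.cos(ang)
        dy = pair_sep_um / 2 * np.sin(ang)
        r = float(rng.uniform(32, 45))
        baseline.append(SDD(a.x_um - dx, a.y_um - dy, r, a.stage))
        baseline.append(SDD(a.x_um + dx, a.y_um + dy, r, a.stage))
        followup.append(SDD(a.x_um, a.y_um, r * 1.5, a.stage))
    followup += [SDD(s.x_um, s.y_um, s.radius_um, s.stage) for s in new]
    expected = {"stable": n_stable, "regressed": n_regress,
                "fused": 2 * n_fuse_pairs, "new": n_new,
                "total": n_stable + n_regress + 2 * n_fuse_pairs + n_new}
    return baseline, followup, expected


# --------------------------------------------------------------------------
# ground-truth serialization
# --------------------------------------------------------------------------

def save_ground_truth(path, traces: list[MotionTrace] | None = None,
                      surfaces: dict[str, np.ndarray] | None = None,
                      sdds: list[SDD] | None = None) -> None:
    """Write simulation ground truth as JSON (bit-exact round-trip)."""
    d: dict = {}
    if traces is not None:
        d["traces"] = [tr.to_dict() for tr in traces]
    if surfaces is not None:
        d["surfaces"] = {k: v.tolist() for k, v in surfaces.items()}
    if sdds is not None:
        d["sdds"] = [asdict(s) for s in sdds]
    Path(path).write_text(json.dumps(d))


def load_ground_truth(path) -> dict:
    d = json.loads(Path(path).read_text())
    out: dict = {}
    if "traces" in d:
        out["traces"] = [MotionTrace.from_dict(t) for t in d["traces"]]
    if "surfaces" in d:
        out["surfaces"] = {k: np.array(v) for k, v in d["surfaces"].items()}
    if "sdds" in d:
        out["sdds"] = [SDD(**s) for s in d["sdds"]]
    return out
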
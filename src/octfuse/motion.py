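"""Per-A-scan 3D eye-motion estimation from orthogonal raster volumes.

The eye displacement during each raster volume is modeled as a continuous,
time-dependent 3D function — a uniform B-spline over the volume's
acquisition span — and estimated jointly across volumes by minimizing the
squared disagreement of log-scaled intensities between each volume and a
reconstruction of the others at motion-corrected positions, plus first- and
second-derivative penalties on the spline coefficients.  Orthogonal fast-axis
directions make both transverse axes and the axial direction observable.

Sign convention: the model stores *eye displacement*.  During acquisition a
beam aimed at nominal position n records the retina at n + s(t) where s is
the apparent content offset, so s = -displacement; correction therefore
shifts each A-scan's nominal position by -evaluate(t), which places the
sample where the sampled content actually lives.

Optimization is multi-resolution (spatial pyramid and control-point
density), quasi-Newton (L-BFGS-B) with analytic gradients, with a
leave-one-out reconstruction as the moving reference and a zero-mean gauge
constraint across volumes to remove the unobservable global offset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.interpolate import BSpline
from scipy.optimize import minimize
from scipy.sparse import csr_matrix

from ._gridops import block_mean, bin_trilinear
from .protocol import X_FAST, Y_FAST
from .simkit import MotionTrace
from .volume import RasterVolume


class MotionEstimationError(RuntimeError):
    """Motion estimation cannot proceed (insufficient/unsuitable volumes)."""


# --------------------------------------------------------------------------
# displacement model
# --------------------------------------------------------------------------

@dataclass
class _VolumeSpline:
    knots: np.ndarray          # (n + k + 1,)
    coeffs: np.ndarray         # (n, 3) um
    k: int                     # spline order (1 = piecewise linear, 3 = cubic)

    @property
    def t_span(self) -> tuple[float, float]:
        return float(self.knots[self.k]), float(self.knots[-self.k - 1])

    @property
    def control_times(self) -> np.ndarray:
        """Greville abscissae — the effective control-point times."""
        k = self.k
        n = self.coeffs.shape[0]
        return np.array([self.knots[i + 1:i + k + 1].mean() for i in range(n)])

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, float)
        lo, hi = self.t_span
        if np.any(t < lo - 1e-9) or np.any(t > hi + 1e-9):
            raise ValueError(
                f"time outside model span [{lo:.4f}, {hi:.4f}] s")
        tc = np.clip(t, lo, hi)
        return BSpline(self.knots, self.coeffs, self.k, axis=0)(tc)


@dataclass
class DisplacementModel:
    """Per-volume continuous 3D eye-displacement functions (um vs s)."""

    splines: dict[int, _VolumeSpline] = field(default_factory=dict)
    reg_weights: tuple[float, float] = (0.0, 0.0)
    diagnostics: dict = field(default_factory=dict)

    def evaluate(self, volume_index: int, t) -> np.ndarray:
        """3D displacement (um) at time(s) t for one volume; errors outside
        the volume's acquisition span (no extrapolation)."""
        if volume_index not in self.splines:
            raise KeyError(f"no model for volume {volume_index}")
        return self.splines[volume_index](t)

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", True))

    # ---- gauge ------------------------------------------------------------
    def gauge_fix(self) -> "DisplacementModel":
        """Constrain the mean displacement across all volumes to zero per
        axis (removes the unobservable global offset deterministically)."""
        if not self.splines:
            return self
        mean = np.mean([sp.coeffs.mean(axis=0) for sp in self.splines.values()],
                       axis=0)
        for sp in self.splines.values():
            sp.coeffs = sp.coeffs - mean
        return self

    # ---- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "reg_weights": list(self.reg_weights),
            "diagnostics": _jsonable(self.diagnostics),
            "volumes": {
                str(v): {"knots": sp.knots.tolist(),
                         "coeffs": sp.coeffs.tolist(), "k": sp.k}
                for v, sp in self.splines.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DisplacementModel":
        m = cls(reg_weights=tuple(d.get("reg_weights", (0.0, 0.0))),
                diagnostics=d.get("diagnostics", {}))
        for v, e in d["volumes"].items():
            m.splines[int(v)] = _VolumeSpline(
                np.array(e["knots"]), np.array(e["coeffs"]), int(e["k"]))
        return m

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "DisplacementModel":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def zero(cls, volumes: list[RasterVolume]) -> "DisplacementModel":
        m = cls()
        for vol in volumes:
            t = vol.timestamps()
            t0, t1 = float(t.min()), float(t.max())
            dt = max(t1 - t0, 1e-3)
            knots = np.array([t0 - dt, t0 - 1e-6, t1 + 1e-6, t1 + dt])
            m.splines[vol.volume_index] = _VolumeSpline(
                knots, np.zeros((2, 3)), 1)
        return m


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def model_from_trace(traces: dict[int, MotionTrace] | list[MotionTrace],
                     volumes: list[RasterVolume]) -> DisplacementModel:
    """Build the displacement model equivalent to simulator ground truth.

    The simulator trace is the apparent sampling offset, so the model (eye
    displacement) is its negation, tabulated on the trace's own knots plus
    tight knot pairs bracketing each saccade so steps survive the piecewise-
    linear representation.
    """
    if not isinstance(traces, dict):
        traces = {vol.volume_index: tr for vol, tr in zip(volumes, traces)}
    model = DisplacementModel()
    eps = 1e-7
    for vol in volumes:
        tr = traces[vol.volume_index]
        t = vol.timestamps()
        t0, t1 = float(t.min()) - 1e-6, float(t.max()) + 1e-6
        nodes = tr.knot_t[(tr.knot_t > t0) & (tr.knot_t < t1)]
        extra = []
        for ts in tr.saccade_times:
            if t0 < ts < t1:
                extra += [ts - eps, ts]
        nodes = np.unique(np.concatenate([[t0], nodes, extra, [t1]]))
        lo, hi = tr.t_span
        vals = -tr.evaluate(np.clip(nodes, lo, hi))
        knots = np.concatenate([[nodes[0] - 1e-3], nodes, [nodes[-1] + 1e-3]])
        model.splines[vol.volume_index] = _VolumeSpline(knots, vals, 1)
    return model


# --------------------------------------------------------------------------
# corrected samples
# --------------------------------------------------------------------------

@dataclass
class CorrectedSamples:
    """Motion-corrected per-A-scan positions with their intensity columns.

    One entry per A-scan (slow-major order); ``valid`` is False for A-scans
    of masked (blink) B-scans.  Axial positions of column voxel j are
    z0 + j * axial_um + dz_um.
    """

    volume_index: int
    direction: str
    xy_um: np.ndarray          # (M, 2) corrected transverse positions
    dz_um: np.ndarray          # (M,) axial displacement of the column
    t_s: np.ndarray            # (M,)
    valid: np.ndarray          # (M,) bool
    columns: np.ndarray        # (nz, M) float32 intensities
    axial_um: float
    pitch_um: float
    n_fast: int = 0            # A-scans per B-scan (slow-major layout)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.xy_um)) or not np.all(np.isfinite(self.dz_um)):
            raise ValueError("corrected positions must be finite")

    @property
    def nz(self) -> int:
        return self.columns.shape[0]

    def copy(self) -> "CorrectedSamples":
        return CorrectedSamples(self.volume_index, self.direction,
                                self.xy_um.copy(), self.dz_um.copy(),
                                self.t_s.copy(), self.valid.copy(),
                                self.columns.copy(), self.axial_um,
                                self.pitch_um, self.n_fast)


def correct(volume: RasterVolume, model: DisplacementModel) -> CorrectedSamples:
    """Shift each unmasked A-scan's nominal position by -evaluate(t).

    Geometry-only: intensities are untouched.  The resulting scattered
    samples are the input to illumination estimation and fusion.
    """
    t = volume.timestamps().ravel()
    x, y = volume.ascan_xy_um()
    disp = model.evaluate(volume.volume_index, t)      # (M, 3)
    xy = np.column_stack([x.ravel() - disp[:, 0], y.ravel() - disp[:, 1]])
    dz = -disp[:, 2]
    valid = np.repeat(volume.valid_bscan, volume.nfast)
    cols = volume.grid.reshape(volume.nz, -1)
    return CorrectedSamples(volume.volume_index, volume.direction, xy, dz, t,
                            valid, cols, volume.axial_um,
                            volume.protocol.pitch_um, volume.nfast)


# --------------------------------------------------------------------------
# estimation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MotionOptions:
    """Multi-resolution registration settings.

    pyramid_factors : transverse downsampling per level (coarse to fine).
    ctrl_bscans : control-point spacing in B-scan periods per level.
    outer_passes / maxiter : alternation and L-BFGS budgets per level.
    lam1 / lam2 : first-/second-difference penalties on spline coefficients
        (per um^2, relative to the mean-squared log-intensity data term).
        Defaults are calibrated so drift at fixational amplitudes is
        recovered to a few micrometres without over-smoothing saccades.
    log_scale : intensity compression I -> log1p(I / log_scale).
    """

    pyramid_factors: tuple[int, ...] = (4, 2, 1)
    ctrl_bscans: tuple[int, ...] = (4, 2, 1)
    outer_passes: tuple[int, ...] = (3, 2, 2)
    maxiter: tuple[int, ...] = (40, 25, 12)
    obj_stride: tuple[tuple[int, int], ...] = ((1, 1), (1, 1), (2, 2))
    lam1: float = 1e-4
    lam2: float = 1e-3
    log_scale: float = 0.05
    min_weight: float = 0.05
    ftol: float = 1e-6
    max_axial_factor: int = 2
    spline_order: int = 3
    # axial rows used for estimation; None = auto-crop to the retina band
    # (rows with signal above 10% of peak, padded), "full" = no crop
    crop_z: tuple[int, int] | str | None = None


@dataclass
class _LevelVolume:
    """One volume's downsampled data at a pyramid level."""
    index: int
    log: np.ndarray            # (nzl, n_asc) log intensities
    x_um: np.ndarray           # (n_asc,)
    y_um: np.ndarray
    t_s: np.ndarray
    w_asc: np.ndarray          # (n_asc,) validity weight
    B: csr_matrix              # (n_asc, n_ctrl) spline design matrix
    knots: np.ndarray
    z_um: np.ndarray           # (nzl,) depths of the downsampled rows


def _auto_crop_z(volumes: list[RasterVolume], rel: float = 0.1,
                 pad: int = 16) -> tuple[int, int]:
    """Axial band holding the retina: rows whose mean intensity exceeds
    ``rel`` x the peak row mean in any volume, padded by ``pad`` rows."""
    prof = np.max([v.grid.mean(axis=(1, 2)) for v in volumes], axis=0)
    above = np.flatnonzero(prof > rel * prof.max())
    nz = volumes[0].nz
    if above.size == 0:
        return 0, nz
    return max(0, int(above[0]) - pad), min(nz, int(above[-1]) + 1 + pad)


def _make_knots(t0: float, t1: float, dt_c: float, k: int) -> np.ndarray:
    n_ctrl = int(np.ceil((t1 - t0) / dt_c)) + k + 1
    return t0 + (np.arange(n_ctrl + k + 1) - k) * dt_c


def _prepare_level(volumes: list[RasterVolume], factor: int, ctrl_b: int,
                   opts: MotionOptions) -> tuple[list[_LevelVolume], float, float]:
    fz = min(factor, opts.max_axial_factor)
    if opts.crop_z is None or opts.crop_z == "auto":
        crop = _auto_crop_z(volumes)
    elif opts.crop_z == "full":
        crop = (0, volumes[0].nz)
    else:
        crop = opts.crop_z
    lvs = []
    for vol in volumes:
        z0, z1 = crop
        grid = vol.grid[z0:z1]
        g = block_mean(grid, (fz, factor, factor))
        log = np.log1p(g / opts.log_scale).astype(np.float32)
        nzl = g.shape[0]
        x, y = vol.ascan_xy_um()
        t = vol.timestamps()
        xb = block_mean(x, (factor, factor)).ravel()
        yb = block_mean(y, (factor, factor)).ravel()
        tb = block_mean(t, (factor, factor)).ravel()
        wb = block_mean(np.repeat(vol.valid_bscan.astype(float)[:, None],
                                  vol.nfast, axis=1), (factor, factor)).ravel()
        wb = (wb > 0.5).astype(np.float64)
        dt_c = ctrl_b * vol.protocol.bscan_period_s
        knots = _make_knots(float(t.min()) - 1e-9, float(t.max()) + 1e-9, dt_c,
                            opts.spline_order)
        B = BSpline.design_matrix(tb, knots, opts.spline_order).tocsr()
        z_um = (z0 + np.arange(nzl) * fz + (fz - 1) / 2.0) * vol.axial_um
        lvs.append(_LevelVolume(vol.volume_index, log.reshape(nzl, -1),
                                xb, yb, tb, wb, B, knots, z_um))
    pitch_l = volumes[0].protocol.pitch_um * factor
    axial_l = volumes[0].axial_um * fz
    return lvs, pitch_l, axial_l


def _grid_level(lv: _LevelVolume, coeffs: np.ndarray, shape, pitch_l, axial_l,
                z0_um) -> tuple[np.ndarray, np.ndarray]:
    """Bin one level-volume's corrected samples onto the reference grid."""
    disp = lv.B @ coeffs                                  # (n_asc, 3)
    cx = (lv.x_um - disp[:, 0]) / pitch_l
    cy = (lv.y_um - disp[:, 1]) / pitch_l
    cz_col = (lv.z_um[:, None] - disp[None, :, 2] - z0_um) / axial_l
    nzl = lv.z_um.size
    cxf = np.broadcast_to(cx[None, :], (nzl, cx.size))
    cyf = np.broadcast_to(cy[None, :], (nzl, cy.size))
    swf = np.broadcast_to(lv.w_asc[None, :], (nzl, cx.size))
    return bin_trilinear(cz_col, cyf, cxf, lv.log, shape, sample_weight=swf)


def _objective_and_grad(coeffs_flat, lv: _LevelVolume, ref, grads, refvalid,
                        pitch_l, axial_l, z0_um, stride, lam1, lam2,
                        scale=None):
    """Objective in optionally rescaled coordinates: ``scale`` converts the
    optimization variables (voxel units, so axes are balanced and line
    searches well-conditioned) to micrometres."""
    n_ctrl = lv.B.shape[1]
    C = coeffs_flat.reshape(n_ctrl, 3)
    if scale is not None:
        C = C * scale[None, :]
    zs, fs = stride
    asc = slice(None, None, fs)
    disp = (lv.B @ C)[asc]
    x = lv.x_um[asc]
    y = lv.y_um[asc]
    w = lv.w_asc[asc]
    L = lv.log[::zs, asc]
    z = lv.z_um[::zs]
    nzl, nasc = L.shape

    cx = np.broadcast_to(((x - disp[:, 0]) / pitch_l)[None, :], (nzl, nasc))
    cy = np.broadcast_to(((y - disp[:, 1]) / pitch_l)[None, :], (nzl, nasc))
    cz = (z[:, None] - disp[None, :, 2] - z0_um) / axial_l

    coords = [cz, cy, cx]
    r_ref = ndimage.map_coordinates(ref, coords, order=1, mode="constant")
    m = ndimage.map_coordinates(refvalid, coords, order=1, mode="constant")
    m = (m > 0.99) * w[None, :]
    r = (L - r_ref) * m
    n_eff = max(m.sum(), 1.0)
    cost = float((r * r).sum() / n_eff)

    grad = np.zeros((n_ctrl, 3))
    Bs = lv.B[asc]
    for ax, (gfield, spacing) in enumerate((
            (grads[2], pitch_l),     # x
            (grads[1], pitch_l),     # y
            (grads[0], axial_l))):   # z
        g = ndimage.map_coordinates(gfield, coords, order=1, mode="constant")
        # r = L - Ref(p), p_ax = nominal - d_ax  =>  dr/dd_ax = +dRef/dp_ax
        col = (2.0 / n_eff) * (r * g).sum(axis=0) / spacing
        grad[:, ax] = Bs.T @ col

    if n_ctrl >= 2 and lam1 > 0:
        d1 = np.diff(C, axis=0)
        cost += lam1 * float((d1 * d1).sum()) / n_ctrl
        g1 = np.zeros_like(C)
        g1[:-1] -= 2 * d1
        g1[1:] += 2 * d1
        grad += lam1 * g1 / n_ctrl
    if n_ctrl >= 3 and lam2 > 0:
        d2 = np.diff(C, n=2, axis=0)
        cost += lam2 * float((d2 * d2).sum()) / n_ctrl
        g2 = np.zeros_like(C)
        g2[:-2] += 2 * d2
        g2[1:-1] -= 4 * d2
        g2[2:] += 2 * d2
        grad += lam2 * g2 / n_ctrl
    if scale is not None:
        grad = grad * scale[None, :]
    return cost, grad.ravel()


def pairwise_disagreement(volumes: list[RasterVolume],
                          model: DisplacementModel,
                          factor: int = 4,
                          opts: MotionOptions | None = None) -> float:
    """Weighted between-volume variance of log intensities after correction,
    measured on a fixed coarse grid.  Used as the cross-stage objective."""
    opts = opts or MotionOptions()
    lvs, pitch_l, axial_l = _prepare_level(volumes, factor, 1, opts)
    z0_um = min(lv.z_um[0] for lv in lvs)
    shape = _ref_shape(lvs, pitch_l, axial_l, z0_um)
    Ws, Is = [], []
    for lv in lvs:
        C = _coeffs_on_basis(model, lv)
        W, WI = _grid_level(lv, C, shape, pitch_l, axial_l, z0_um)
        Ws.append(W)
        Is.append(np.divide(WI, W, out=np.zeros_like(WI), where=W > 1e-6))
    Wtot = np.sum(Ws, axis=0)
    mean = np.divide(np.sum([W * I for W, I in zip(Ws, Is)], axis=0), Wtot,
                     out=np.zeros_like(Wtot), where=Wtot > 0)
    nvol = np.sum([W > 1e-6 for W in Ws], axis=0)
    sel = nvol >= 2
    num = np.sum([W * (I - mean) ** 2 for W, I in zip(Ws, Is)], axis=0)[sel]
    den = Wtot[sel]
    return float(num.sum() / max(den.sum(), 1e-12))


def _ref_shape(lvs, pitch_l, axial_l, z0_um):
    x_max = max(lv.x_um.max() for lv in lvs)
    y_max = max(lv.y_um.max() for lv in lvs)
    z_max = max(lv.z_um[-1] for lv in lvs)
    return (int(round((z_max - z0_um) / axial_l)) + 1,
            int(round(y_max / pitch_l)) + 1,
            int(round(x_max / pitch_l)) + 1)


def _coeffs_on_basis(model: DisplacementModel, lv: _LevelVolume) -> np.ndarray:
    """Least-squares refit of a model onto a level's spline basis."""
    if lv.index not in model.splines:
        return np.zeros((lv.B.shape[1], 3))
    vals = model.evaluate(lv.index, lv.t_s)
    BtB = (lv.B.T @ lv.B).toarray()
    BtB += 1e-9 * np.eye(BtB.shape[0])
    return np.linalg.solve(BtB, lv.B.T @ vals)


def estimate_motion(volumes: list[RasterVolume],
                    opts: MotionOptions | None = None) -> DisplacementModel:
    """Jointly estimate per-volume continuous 3D displacement functions.

    Requires at least two usable volumes covering both fast-axis directions.
    Returns a gauge-fixed model with per-stage objectives and convergence
    status in ``model.diagnostics``; on non-convergence the best iterate is
    returned with ``diagnostics['converged'] = False``.
    """
    opts = opts or MotionOptions()
    usable = [v for v in volumes if v.valid_bscan.sum() >= 2]
    if len(usable) < 2:
        raise MotionEstimationError("need at least 2 usable volumes")
    dirs = {v.direction for v in usable}
    if dirs != {X_FAST, Y_FAST}:
        raise MotionEstimationError(
            "need both fast-axis directions represented")

    model = DisplacementModel(reg_weights=(opts.lam1, opts.lam2))
    stage_obj = [pairwise_disagreement(usable, DisplacementModel.zero(usable),
                                       factor=opts.pyramid_factors[0],
                                       opts=opts)]
    converged = True

    coeffs: dict[int, np.ndarray] = {}
    for li, (factor, ctrl_b) in enumerate(zip(opts.pyramid_factors,
                                              opts.ctrl_bscans)):
        lvs, pitch_l, axial_l = _prepare_level(usable, factor, ctrl_b, opts)
        z0_um = min(lv.z_um[0] for lv in lvs)
        shape = _ref_shape(lvs, pitch_l, axial_l, z0_um)
        # carry the previous level's model onto the new basis
        coeffs = {lv.index: (_coeffs_on_basis(model, lv) if model.splines
                             else np.zeros((lv.B.shape[1], 3)))
                  for lv in lvs}
        binned = {lv.index: _grid_level(lv, coeffs[lv.index], shape,
                                        pitch_l, axial_l, z0_um)
                  for lv in lvs}
        Wtot = np.sum([b[0] for b in binned.values()], axis=0)
        WItot = np.sum([b[1] for b in binned.values()], axis=0)
        for _ in range(opts.outer_passes[li]):
            for lv in lvs:
                # Gauss-Seidel: the reference always reflects the other
                # volumes' *current* corrections (leave-one-out)
                W, WI = binned[lv.index]
                Wl, WIl = Wtot - W, WItot - WI
                refvalid = (Wl > opts.min_weight).astype(np.float32)
                ref = np.divide(WIl, Wl, out=np.zeros_like(WIl),
                                where=Wl > opts.min_weight)
                ref = ref.reshape(shape).astype(np.float32)
                refvalid = refvalid.reshape(shape)
                grads = np.gradient(ref)
                scale = np.array([pitch_l, pitch_l, axial_l])
                res = minimize(
                    _objective_and_grad,
                    (coeffs[lv.index] / scale[None, :]).ravel(),
                    args=(lv, ref, grads, refvalid, pitch_l, axial_l, z0_um,
                          opts.obj_stride[li], opts.lam1, opts.lam2, scale),
                    jac=True, method="L-BFGS-B",
                    # ftol is absolute for costs < 1, so scale it to stay a
                    # relative criterion; the projected-gradient stop is
                    # disabled (gradients are small in these units)
                    options={"maxiter": opts.maxiter[li],
                             "ftol": opts.ftol * 1e-2, "gtol": 1e-12})
                coeffs[lv.index] = res.x.reshape(-1, 3) * scale[None, :]
                if not res.success and "ITERATIONS" not in str(res.message).upper():
                    converged = False
                new = _grid_level(lv, coeffs[lv.index], shape, pitch_l,
                                  axial_l, z0_um)
                Wtot += new[0] - W
                WItot += new[1] - WI
                binned[lv.index] = new
        # gauge: zero mean displacement across volumes per axis (the
        # objective is invariant, so this never changes the fit quality)
        mean = np.mean([c.mean(axis=0) for c in coeffs.values()], axis=0)
        for c in coeffs.values():
            c -= mean
        model = DisplacementModel(reg_weights=(opts.lam1, opts.lam2))
        for lv in lvs:
            model.splines[lv.index] = _VolumeSpline(
                lv.knots, coeffs[lv.index].copy(), opts.spline_order)
        stage_obj.append(pairwise_disagreement(
            usable, model, factor=opts.pyramid_factors[0], opts=opts))

    model.gauge_fix()
    model.diagnostics = {"stage_objectives": stage_obj,
                         "converged": converged,
                         "final_objective": stage_obj[-1]}
    return model
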
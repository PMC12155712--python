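"""Illumination-bias estimation and cross-volume brightness matching.

Illumination bias in raster-scanned OCT is modeled as a multiplicative gain,
smooth (band-limited) along each B-scan's fast axis, one curve per B-scan
per volume.  Because consecutive B-scans of one volume are nearly
simultaneous while orthogonal volumes revisit the same location seconds
apart, the bias is estimated from the disagreement of spatially overlapping
A-scans across motion-corrected volumes: a linear least-squares problem in
log intensity over a small number of control points per B-scan, with
smoothness coupling along the slow axis.  The small control-point count is
the feature-preservation constraint — per-A-scan image structure cannot be
absorbed by an 8-point curve.

A separate global scale per volume matches overall brightness toward the
brightest volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import lsmr

from .motion import CorrectedSamples


class InsufficientOverlapError(RuntimeError):
    """Too few A-scans with a cross-volume neighbour to estimate gain."""


@dataclass
class GainField:
    """Per-volume, per-B-scan smooth gain curves plus global scales.

    ``log_ctrl[v]`` has shape (n_bscans, n_ctrl): log-gain control points
    evenly spaced along the fast axis, interpolated linearly per A-scan.
    All gains are positive by construction (exp of finite values).
    """

    log_ctrl: dict[int, np.ndarray] = field(default_factory=dict)
    scale: dict[int, float] = field(default_factory=dict)
    n_fast: int = 0

    def gain_per_ascan(self, volume_index: int,
                       n_fast: int | None = None) -> np.ndarray:
        """(n_bscans, n_fast) multiplicative gain for one volume."""
        c = self.log_ctrl[volume_index]
        nf = n_fast or self.n_fast
        a = np.linspace(0.0, c.shape[1] - 1.0, nf)
        i0 = np.clip(a.astype(int), 0, c.shape[1] - 2)
        w = a - i0
        logg = c[:, i0] * (1 - w) + c[:, i0 + 1] * w
        return np.exp(logg)

    def max_relative_step(self) -> float:
        """Largest relative gain change per control interval (smoothness
        diagnostic for the band-limit invariant)."""
        steps = [np.abs(np.diff(c, axis=1)).max() if c.shape[1] > 1 else 0.0
                 for c in self.log_ctrl.values()]
        return float(np.expm1(max(steps))) if steps else 0.0

    def to_dict(self) -> dict:
        return {"n_fast": self.n_fast,
                "scale": {str(k): v for k, v in self.scale.items()},
                "log_ctrl": {str(k): v.tolist()
                             for k, v in self.log_ctrl.items()}}

    @classmethod
    def from_dict(cls, d: dict) -> "GainField":
        return cls(log_ctrl={int(k): np.array(v)
                             for k, v in d["log_ctrl"].items()},
                   scale={int(k): float(v) for k, v in d["scale"].items()},
                   n_fast=int(d["n_fast"]))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "GainField":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class GainOptions:
    n_ctrl: int = 8                 # control points per B-scan (band limit)
    smooth_slow: float = 40.0       # coupling of adjacent B-scans' curves
    smooth_fast: float = 1.0        # second-difference penalty along ctrl
    ridge: float = 1e-3             # pins the unobservable global log level
    floor: float = 0.02             # above-noise threshold for summaries
    min_overlap: float = 0.25       # required fraction of A-scans overlapping


def _ascan_log_summary(s: CorrectedSamples, floor: float,
                       band_sigma: float = 0.0) -> np.ndarray:
    """Per-A-scan log of mean above-floor intensity (illumination proxy).

    ``band_sigma`` low-passes the summary along each B-scan's fast axis so
    that structure above the gain model's band limit never enters the fit
    (the feature-preservation constraint acts on the data side too).
    """
    cols = np.asarray(s.columns, np.float64)
    logs = np.log(np.maximum(cols.mean(axis=0), floor / 10.0))
    if band_sigma > 0:
        nf = _n_fast(s)
        logs = ndimage.gaussian_filter1d(
            logs.reshape(-1, nf), band_sigma, axis=1, mode="reflect").ravel()
    return logs


def _fast_basis(n_fast: int, n_ctrl: int) -> np.ndarray:
    """(n_fast, n_ctrl) linear-interpolation weights along the fast axis."""
    a = np.linspace(0.0, n_ctrl - 1.0, n_fast)
    i0 = np.clip(a.astype(int), 0, n_ctrl - 2)
    w = a - i0
    B = np.zeros((n_fast, n_ctrl))
    B[np.arange(n_fast), i0] = 1 - w
    B[np.arange(n_fast), i0 + 1] = w
    return B


def estimate_gain(samples: list[CorrectedSamples],
                  opts: GainOptions | None = None) -> GainField:
    """Estimate per-B-scan smooth gain curves from cross-volume overlap.

    Minimizes the squared log-intensity disagreement between spatially
    overlapping A-scans of different volumes over band-limited gain curves
    (linear least squares), with slow-axis smoothness coupling and a ridge
    that fixes the unobservable common log level at zero.
    """
    opts = opts or GainOptions()
    if len(samples) < 2:
        raise ValueError("need at least 2 volumes to estimate gain")
    pitch = samples[0].pitch_um
    vols = [s.volume_index for s in samples]
    nb = {s.volume_index: int(s.t_s.size // _n_fast(s)) for s in samples}
    nf = {s.volume_index: _n_fast(s) for s in samples}

    # en face pixel assignment (nearest nominal-pitch pixel)
    keys, logs, rows_b, rows_a, valid = {}, {}, {}, {}, {}
    extent = 0
    for s in samples:
        ix = np.rint(s.xy_um[:, 0] / pitch).astype(np.int64)
        iy = np.rint(s.xy_um[:, 1] / pitch).astype(np.int64)
        extent = max(extent, ix.max() + 1, iy.max() + 1)
        keys[s.volume_index] = (iy, ix)
        logs[s.volume_index] = _ascan_log_summary(s, opts.floor)
        m = nf[s.volume_index]
        rows_b[s.volume_index] = np.arange(s.t_s.size) // m
        rows_a[s.volume_index] = np.arange(s.t_s.size) % m
        valid[s.volume_index] = s.valid.copy()

    # per (pixel, volume) means of log intensity and of basis weights
    npix = extent * extent
    pix_mean_log = {}
    pix_rows = {}
    offsets = {}
    off = 0
    for v in vols:
        offsets[v] = off
        off += nb[v] * opts.n_ctrl
    n_unknown = off

    counts = {}
    for s in samples:
        v = s.volume_index
        iy, ix = keys[v]
        ok = (valid[v] & (iy >= 0) & (iy < extent) & (ix >= 0) & (ix < extent))
        pid = iy * extent + ix
        pid = np.where(ok, pid, 0)
        w = ok.astype(float)
        cnt = np.bincount(pid, weights=w, minlength=npix)
        lsum = np.bincount(pid, weights=w * logs[v], minlength=npix)
        counts[v] = cnt
        pix_mean_log[v] = np.divide(lsum, cnt, out=np.zeros(npix),
                                    where=cnt > 0)
        # mean basis row per pixel: sparse (npix, nb*n_ctrl)
        Bf = _fast_basis(nf[v], opts.n_ctrl)
        data_cols = rows_b[v][:, None] * opts.n_ctrl + np.arange(opts.n_ctrl)
        Bw = Bf[rows_a[v]] * w[:, None]
        M = sparse.csr_matrix(
            (Bw.ravel(),
             (np.repeat(pid, opts.n_ctrl), data_cols.ravel())),
            shape=(npix, nb[v] * opts.n_ctrl))
        d = sparse.diags(np.divide(1.0, cnt, out=np.zeros(npix),
                                   where=cnt > 0))
        pix_rows[v] = d @ M

    nvol_at_pix = np.sum([counts[v] > 0 for v in vols], axis=0)
    shared = nvol_at_pix >= 2
    frac = min((counts[v] > 0)[shared].sum() / max((counts[v] > 0).sum(), 1)
               for v in vols)
    if frac < opts.min_overlap:
        raise InsufficientOverlapError(
            f"only {frac:.0%} of A-scans have a cross-volume neighbour")

    sel = np.flatnonzero(shared)
    nsel = sel.size
    nv = len(vols)
    mean_log = np.mean([pix_mean_log[v][sel] for v in vols], axis=0)
    mean_row = sum(pix_rows[v][sel] for v in vols) / nv

    blocks, rhs = [], []
    for v in vols:
        A_v = sparse.hstack([
            (pix_rows[u][sel] if u == v else sparse.csr_matrix(
                (nsel, nb[u] * opts.n_ctrl))) for u in vols]).tocsr()
        A_v = A_v - sparse.hstack(
            [pix_rows[u][sel] / nv for u in vols]).tocsr()
        blocks.append(A_v)
        rhs.append(pix_mean_log[v][sel] - mean_log)
    A = sparse.vstack(blocks)
    b = np.concatenate(rhs)

    # regularization: slow-axis first differences, fast-axis second
    # differences, and a small ridge
    regs, zeros = [], []
    for v in vols:
        nbl, nc = nb[v], opts.n_ctrl
        base = offsets[v]
        if nbl > 1:
            i = np.arange((nbl - 1) * nc)
            bsc = i // nc
            col0 = base + bsc * nc + i % nc
            D = sparse.csr_matrix(
                (np.concatenate([np.full(i.size, -1.0), np.ones(i.size)]),
                 (np.concatenate([i, i]),
                  np.concatenate([col0, col0 + nc]))),
                shape=(i.size, n_unknown))
            regs.append(opts.smooth_slow * D)
        if nc > 2:
            i = np.arange(nbl * (nc - 2))
            bsc = i // (nc - 2)
            c0 = base + bsc * nc + i % (nc - 2)
            D2 = sparse.csr_matrix(
                (np.concatenate([np.ones(i.size), -2 * np.ones(i.size),
                                 np.ones(i.size)]),
                 (np.tile(i, 3),
                  np.concatenate([c0, c0 + 1, c0 + 2]))),
                shape=(i.size, n_unknown))
            regs.append(opts.smooth_fast * D2)
    regs.append(opts.ridge * sparse.eye(n_unknown))
    A_full = sparse.vstack([A] + regs).tocsr()
    b_full = np.concatenate([b] + [np.zeros(r.shape[0]) for r in regs])

    sol = lsmr(A_full, b_full, atol=1e-8, btol=1e-8, maxiter=400)[0]

    gf = GainField(n_fast=max(nf.values()))
    for v in vols:
        gf.log_ctrl[v] = sol[offsets[v]:offsets[v] + nb[v] * opts.n_ctrl] \
            .reshape(nb[v], opts.n_ctrl)
        gf.scale[v] = 1.0
    return gf


def _n_fast(s: CorrectedSamples) -> int:
    if s.n_fast:
        return s.n_fast
    raise ValueError("CorrectedSamples.n_fast not set")


def apply_gain(samples: CorrectedSamples, gain: GainField) -> CorrectedSamples:
    """Divide intensities by the per-A-scan gain (and apply the volume's
    global brightness scale); positions are untouched."""
    v = samples.volume_index
    nf = _n_fast(samples)
    with np.errstate(invalid="ignore"):
        g = gain.gain_per_ascan(v, nf).ravel()
    if not np.all(g > 0) or not np.all(np.isfinite(g)):
        raise ValueError("gain must be positive everywhere")
    out = samples.copy()
    scale = gain.scale.get(v, 1.0)
    out.columns = (out.columns * (scale / g)[None, :]).astype(np.float32)
    return out


def robust_mean(samples: CorrectedSamples, floor: float = 0.02,
                trim: float = 0.9) -> float:
    """Trimmed mean of above-noise voxel intensities (the 'brightness' of a
    volume): values above ``floor``, excluding the top (1-trim) tail."""
    vals = np.asarray(samples.columns, np.float64)
    vals = vals[:, samples.valid].ravel()
    vals = vals[vals > floor]
    if vals.size == 0:
        return 0.0
    hi = np.quantile(vals, trim)
    sel = vals[vals <= hi]
    return float(sel.mean()) if sel.size else float(vals.mean())


def match_brightness(samples: list[CorrectedSamples],
                     floor: float = 0.02) -> dict[int, float]:
    """Per-volume scale factors toward the brightest volume.

    The volume with the highest robust mean gets scale 1; every other
    volume is scaled *up* so its robust mean matches it (all scales >= 1).
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 volumes")
    means = {s.volume_index: robust_mean(s, floor) for s in samples}
    target = max(means.values())
    return {v: (target / m if m > 0 else 1.0) for v, m in means.items()}
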
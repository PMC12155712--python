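"""Shared low-level grid operations: block downsampling and trilinear binning."""

from __future__ import annotations

import numpy as np


def block_mean(arr: np.ndarray, factors: tuple[int, ...]) -> np.ndarray:
    """Block-average ``arr`` by integer factors per axis (edges cropped)."""
    sl = tuple(slice(0, (s // f) * f) for s, f in zip(arr.shape, factors))
    a = arr[sl]
    for ax, f in enumerate(factors):
        if f > 1:
            shp = a.shape[:ax] + (a.shape[ax] // f, f) + a.shape[ax + 1:]
            a = a.reshape(shp).mean(axis=ax + 1)
    return a


def bin_bilinear(cy: np.ndarray, cx: np.ndarray, values: np.ndarray,
                 shape: tuple[int, int],
                 sample_weight: np.ndarray | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """2D analogue of :func:`bin_trilinear` (returns flat W, WI)."""
    ny, nx = shape
    n = ny * nx
    cy = np.asarray(cy, np.float64).ravel()
    cx = np.asarray(cx, np.float64).ravel()
    vals = np.asarray(values, np.float64).ravel()
    sw = None if sample_weight is None else \
        np.asarray(sample_weight, np.float64).ravel()
    y0 = np.floor(cy).astype(np.int64)
    x0 = np.floor(cx).astype(np.int64)
    fy, fx = cy - y0, cx - x0
    W = np.zeros(n)
    WI = np.zeros(n)
    for dy in (0, 1):
        wy = fy if dy else 1.0 - fy
        yi = y0 + dy
        oky = (yi >= 0) & (yi < ny)
        for dx in (0, 1):
            wx = fx if dx else 1.0 - fx
            xi = x0 + dx
            ok = oky & (xi >= 0) & (xi < nx)
            w = wy * wx
            if sw is not None:
                w = w * sw
            w = np.where(ok, w, 0.0)
            idx = np.where(ok, yi * nx + xi, 0)
            W += np.bincount(idx, weights=w, minlength=n)
            WI += np.bincount(idx, weights=w * vals, minlength=n)
    return W, WI


def bin_trilinear(cz: np.ndarray, cy: np.ndarray, cx: np.ndarray,
                  values: np.ndarray, shape: tuple[int, int, int],
                  sample_weight: np.ndarray | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Scatter samples onto a regular grid with trilinear weights.

    Coordinates are in voxel units of the target grid.  Returns flat
    accumulators (W, WI) of length prod(shape); out-of-range corner
    contributions are dropped.
    """
    nz, ny, nx = shape
    n = nz * ny * nx
    cz = np.asarray(cz, np.float64).ravel()
    cy = np.asarray(cy, np.float64).ravel()
    cx = np.asarray(cx, np.float64).ravel()
    vals = np.asarray(values, np.float64).ravel()
    if sample_weight is not None:
        sw = np.asarray(sample_weight, np.float64).ravel()
    else:
        sw = None

    z0 = np.floor(cz).astype(np.int64)
    y0 = np.floor(cy).astype(np.int64)
    x0 = np.floor(cx).astype(np.int64)
    fz, fy, fx = cz - z0, cy - y0, cx - x0

    W = np.zeros(n)
    WI = np.zeros(n)
    for dz in (0, 1):
        wz = fz if dz else 1.0 - fz
        zi = z0 + dz
        okz = (zi >= 0) & (zi < nz)
        for dy in (0, 1):
            wy = fy if dy else 1.0 - fy
            yi = y0 + dy
            oky = okz & (yi >= 0) & (yi < ny)
            for dx in (0, 1):
                wx = fx if dx else 1.0 - fx
                xi = x0 + dx
                ok = oky & (xi >= 0) & (xi < nx)
                w = wz * wy * wx
                if sw is not None:
                    w = w * sw
                w = np.where(ok, w, 0.0)
                idx = np.where(ok, (zi * ny + yi) * nx + xi, 0)
                W += np.bincount(idx, weights=w, minlength=n)
                WI += np.bincount(idx, weights=w * vals, minlength=n)
    return W, WI
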
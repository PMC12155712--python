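"""Longitudinal tracking of dot subretinal drusenoid deposits (SDDs).

En face slabs from different visits are rigidly registered (phase
correlation plus small-angle rotation refinement), deposits are detected as
scale-space blobs, and each baseline deposit is followed to the later visit
and classified into the four longitudinal categories:

* new — present at follow-up but not at baseline;
* regressed — present at baseline but gone at follow-up;
* fused — merged with a nearby deposit (several baseline deposits share one
  follow-up deposit);
* stable — matched one-to-one.

Quadrant location (superonasal / superotemporal / inferonasal /
inferotemporal) is assigned about the fovea, with the nasal direction
determined by laterality in the standard fundus orientation (nasal is -x
for a right eye, +x for a left eye).  Summary tables report per-category
and per-quadrant counts with percentages rounded half-up to one decimal.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import blob_log
from skimage.registration import phase_cross_correlation
from skimage.transform import rotate

from .enface import EnFaceSlab

CATEGORIES = ("stable", "regressed", "fused", "new")
QUADRANTS = ("superonasal", "superotemporal", "inferonasal",
             "inferotemporal")


class RegistrationError(RuntimeError):
    """Visits cannot be registered reliably."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SDDetection:
    """One detected deposit in the slab frame."""
    id: int
    x_um: float
    y_um: float
    diameter_um: float
    peak_contrast: float
    visit: str = ""


@dataclass(frozen=True)
class VisitTransform:
    """Rigid 2D map from the baseline slab frame to the follow-up frame:
    p_followup = R(rotation) @ p_baseline + translation."""
    rotation_rad: float
    tx_um: float
    ty_um: float
    score: float

    def apply(self, xy_um: np.ndarray) -> np.ndarray:
        c, s = np.cos(self.rotation_rad), np.sin(self.rotation_rad)
        R = np.array([[c, -s], [s, c]])
        return np.asarray(xy_um) @ R.T + np.array([self.tx_um, self.ty_um])


@dataclass(frozen=True)
class ChangeRecord:
    """Longitudinal fate of one tracked deposit."""
    category: str
    baseline_ids: tuple[int, ...]
    followup_id: int | None
    quadrant: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        n_base, has_follow = len(self.baseline_ids), self.followup_id is not None
        ok = {"new": n_base == 0 and has_follow,
              "regressed": n_base >= 1 and not has_follow,
              "fused": n_base >= 1 and has_follow,
              "stable": n_base == 1 and has_follow}[self.category]
        if not ok:
            raise ValueError(
                f"{self.category} record with {n_base} baseline ids, "
                f"followup={self.followup_id}")


@dataclass
class SummaryTable:
    """Counts and round-half-up percentages per category and quadrant."""
    category_counts: dict[str, int]
    category_pct: dict[str, float | None]
    quadrant_counts: dict[str, int]
    quadrant_pct: dict[str, float | None]
    total: int

    def to_frame(self):
        import pandas as pd
        rows = [{"group": "category", "name": k,
                 "count": self.category_counts[k],
                 "percent": self.category_pct[k]} for k in CATEGORIES]
        rows += [{"group": "quadrant", "name": k,
                  "count": self.quadrant_counts[k],
                  "percent": self.quadrant_pct[k]} for k in QUADRANTS]
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        lines = [f"tracked SDDs: {self.total}"]
        for k in CATEGORIES:
            p = self.category_pct[k]
            lines.append(f"  {k:<10} {self.category_counts[k]:>4} "
                         f"({'--' if p is None else f'{p:.1f}%'})")
        qtot = sum(self.quadrant_counts.values())
        if qtot:
            lines.append(f"baseline quadrants: {qtot}")
            for k in QUADRANTS:
                p = self.quadrant_pct[k]
                lines.append(f"  {k:<15} {self.quadrant_counts[k]:>4} "
                             f"({'--' if p is None else f'{p:.1f}%'})")
        return "\n".join(lines)


# --------------------------------------------------------------------------
# visit registration
# --------------------------------------------------------------------------

def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / den) if den > 0 else 0.0


def _shift_ncc(base: np.ndarray, follow: np.ndarray,
               shift_px: np.ndarray) -> float:
    moved = ndimage.shift(base, shift_px, order=1, mode="constant",
                          cval=float(np.mean(base)))
    return _ncc(moved, follow)


def register_visits(baseline: EnFaceSlab, followup: EnFaceSlab,
                    max_rotation_deg: float = 5.0,
                    min_score: float = 0.35) -> VisitTransform:
    """Rigid registration of two visits' slabs.

    Translation from upsampled phase correlation, then a golden-section
    refinement of a small rotation about the image centre maximizing
    normalized cross-correlation.  Raises :class:`RegistrationError` when
    the final correlation score stays below ``min_score``.
    """
    if abs(baseline.pitch_um - followup.pitch_um) > 1e-9:
        raise ValueError("slabs must share the pixel pitch")
    a = baseline.filled(float(np.nanmean(baseline.image)))
    b = followup.filled(float(np.nanmean(followup.image)))
    if a.shape != b.shape:
        raise ValueError("slab shapes differ")

    def score_rot(theta_deg: float) -> tuple[float, np.ndarray]:
        ar = rotate(a, theta_deg, preserve_range=True, order=1,
                    mode="edge") if theta_deg else a
        shift, _, _ = phase_cross_correlation(b, ar, upsample_factor=20,
                                              normalization=None)
        return _shift_ncc(ar, b, shift), shift

    lo, hi = -max_rotation_deg, max_rotation_deg
    invphi = (np.sqrt(5) - 1) / 2
    c, d = hi - invphi * (hi - lo), lo + invphi * (hi - lo)
    fc, _ = score_rot(c)
    fd, _ = score_rot(d)
    for _ in range(12):
        if fc > fd:
            hi, d, fd = d, c, fc
            c = hi - invphi * (hi - lo)
            fc, _ = score_rot(c)
        else:
            lo, c, fc = c, d, fd
            d = lo + invphi * (hi - lo)
            fd, _ = score_rot(d)
    theta = c if fc > fd else d
    s0, _ = score_rot(0.0)
    score, shift = score_rot(theta)
    if s0 >= score:               # prefer pure translation when rotation
        theta, score = 0.0, s0    # does not genuinely help
        _, shift = score_rot(0.0)
    if score < min_score:
        raise RegistrationError(
            f"visits unregistrable (score {score:.2f} < {min_score})")

    pitch = baseline.pitch_um
    # rotate() spins about the image centre; express as rotation + shift
    # about the origin of the physical frame
    th = np.deg2rad(-theta)      # image-frame CCW deg -> math convention
    cy = (a.shape[0] - 1) / 2 * pitch
    cx = (a.shape[1] - 1) / 2 * pitch
    cth, sth = np.cos(th), np.sin(th)
    R = np.array([[cth, -sth], [sth, cth]])
    centre = np.array([cx, cy])
    t_rot = centre - R @ centre
    t_shift = np.array([shift[1], shift[0]]) * pitch
    t = t_rot + t_shift
    return VisitTransform(th, float(t[0]), float(t[1]), score)


# --------------------------------------------------------------------------
# detection
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectOptions:
    min_radius_um: float = 25.0
    max_radius_um: float = 125.0
    n_scales: int = 6
    threshold: float = 0.1        # LoG response threshold (normalized image)
    overlap: float = 0.5          # non-maximum suppression by blob overlap
    background_sigma_um: float = 300.0


def detect_sdd(slab: EnFaceSlab, opts: DetectOptions | None = None,
               visit: str | None = None) -> list[SDDetection]:
    """Scale-space (Laplacian-of-Gaussian) blob detection of dot SDDs.

    The slab is background-subtracted with a wide Gaussian and normalized
    before detection; bright blobs with equivalent radius in the configured
    range and LoG response above threshold are kept after non-maximum
    suppression by overlap.  Masked pixels are treated as background.
    """
    opts = opts or DetectOptions()
    pitch = slab.pitch_um
    img = slab.filled(float(np.nanmedian(slab.image)))
    bg = ndimage.gaussian_filter(img, opts.background_sigma_um / pitch)
    high = img - bg
    scale = float(np.quantile(np.abs(high), 0.999))
    if scale <= 0:
        return []
    norm = np.clip(high / scale, -2.0, 2.0)
    blobs = blob_log(norm,
                     min_sigma=opts.min_radius_um / pitch / np.sqrt(2),
                     max_sigma=opts.max_radius_um / pitch / np.sqrt(2),
                     num_sigma=opts.n_scales,
                     threshold=opts.threshold,
                     overlap=opts.overlap)
    dets = []
    for i, (cy, cx, sigma) in enumerate(blobs):
        if not slab.mask[int(round(cy)), int(round(cx))]:
            continue
        r_um = sigma * np.sqrt(2) * pitch
        dets.append(SDDetection(
            id=i, x_um=float(cx * pitch), y_um=float(cy * pitch),
            diameter_um=float(2 * r_um),
            peak_contrast=float(norm[int(round(cy)), int(round(cx))]),
            visit=visit if visit is not None else slab.visit))
    return dets


# --------------------------------------------------------------------------
# change classification
# --------------------------------------------------------------------------

def classify_changes(base: list[SDDetection], follow: list[SDDetection],
                     tf: VisitTransform | None = None,
                     match_radius_um: float = 60.0) -> list[ChangeRecord]:
    """Four-category longitudinal classification of tracked deposits.

    Baseline detections are mapped through the visit transform; each is
    assigned its nearest follow-up detection within the match radius.
    Two or more baseline deposits sharing one nearest follow-up are each
    ``fused``; a mutual nearest pair is ``stable``; an unmatched baseline
    is ``regressed``; an unclaimed follow-up is ``new``.  One record per
    baseline deposit plus one per new follow-up deposit.
    """
    if match_radius_um <= 0:
        raise ValueError("match radius must be positive")
    records: list[ChangeRecord] = []
    if not base and not follow:
        return records
    bxy = np.array([[d.x_um, d.y_um] for d in base], float).reshape(-1, 2)
    fxy = np.array([[d.x_um, d.y_um] for d in follow], float).reshape(-1, 2)
    if tf is not None and len(base):
        bxy = tf.apply(bxy)

    if len(base) and len(follow):
        dist = np.sqrt(((bxy[:, None, :] - fxy[None, :, :]) ** 2).sum(-1))
        nearest_f = np.argmin(dist, axis=1)
        nearest_f_d = dist[np.arange(len(base)), nearest_f]
    else:
        nearest_f = np.zeros(len(base), int)
        nearest_f_d = np.full(len(base), np.inf)

    in_radius = nearest_f_d <= match_radius_um
    claimed_follow: set[int] = set()
    # group baseline deposits by their claimed follow-up target
    groups: dict[int, list[int]] = {}
    for bi in range(len(base)):
        if in_radius[bi]:
            groups.setdefault(int(nearest_f[bi]), []).append(bi)

    for fi, members in groups.items():
        claimed_follow.add(fi)
        cat = "fused" if len(members) >= 2 else "stable"
        for bi in members:
            records.append(ChangeRecord(cat, (base[bi].id,), follow[fi].id))
    for bi in range(len(base)):
        if not in_radius[bi]:
            records.append(ChangeRecord("regressed", (base[bi].id,), None))
    for fi in range(len(follow)):
        if fi not in claimed_follow:
            records.append(ChangeRecord("new", (), follow[fi].id))
    return records


def assign_quadrant(det: SDDetection, fovea_um: tuple[float, float],
                    laterality: str) -> str:
    """Quadrant of a detection about the fovea.

    Smaller y (row coordinate) is superior.  In the fundus orientation the
    nasal retina lies at -x for a right eye (OD) and +x for a left eye
    (OS).  Ties break toward superior and nasal.
    """
    if laterality not in ("OD", "OS"):
        raise ValueError("laterality must be 'OD' or 'OS'")
    dx = det.x_um - fovea_um[0]
    dy = det.y_um - fovea_um[1]
    superior = dy <= 0
    nasal = (dx <= 0) if laterality == "OD" else (dx >= 0)
    return ("supero" if superior else "infero") + \
        ("nasal" if nasal else "temporal")


def summarize(records: list[ChangeRecord]) -> SummaryTable:
    """Counts and percentages (round-half-up, 1 decimal) per category, and
    the baseline quadrant distribution over records carrying a quadrant."""
    cat_counts = {c: 0 for c in CATEGORIES}
    quad_counts = {q: 0 for q in QUADRANTS}
    for r in records:
        cat_counts[r.category] += 1
        if r.quadrant is not None:
            quad_counts[r.quadrant] += 1
    total = sum(cat_counts.values())
    qtot = sum(quad_counts.values())
    return SummaryTable(
        category_counts=cat_counts,
        category_pct={c: percent(n, total) for c, n in cat_counts.items()},
        quadrant_counts=quad_counts,
        quadrant_pct={q: percent(n, qtot) for q, n in quad_counts.items()},
        total=total)


def percent(count: int, total: int) -> float | None:
    """100 * count / total rounded half-up to one decimal (None if empty)."""
    if total == 0:
        return None
    q = decimal.Decimal(100 * count) / decimal.Decimal(total)
    return float(q.quantize(decimal.Decimal("0.1"),
                            rounding=decimal.ROUND_HALF_UP))


def records_with_quadrants(records: list[ChangeRecord],
                           base: list[SDDetection],
                           follow: list[SDDetection],
                           fovea_um: tuple[float, float],
                           laterality: str) -> list[ChangeRecord]:
    """Attach quadrants: baseline-anchored records use the (first) baseline
    detection's position; new deposits use the follow-up position."""
    by_id_b = {d.id: d for d in base}
    by_id_f = {d.id: d for d in follow}
    out = []
    for r in records:
        det = by_id_b[r.baseline_ids[0]] if r.baseline_ids else \
            by_id_f[r.followup_id]
        out.append(ChangeRecord(r.category, r.baseline_ids, r.followup_id,
                                assign_quadrant(det, fovea_um, laterality)))
    return out
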
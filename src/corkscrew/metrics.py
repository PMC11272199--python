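"""Tortuosity morphometry of vessel centerlines.

The measurements follow the standard vascular-morphometry battery:

- TI, tortuosity index: actual centerline arc length (AL) divided by the
  straight distance between its endpoints (DL); TI >= 1, dimensionless.
- BL, bending length: maximum perpendicular distance from the centerline
  to the infinite line through its endpoints, in mm.
- curvature: reciprocal of the radius of the circle best fitting the
  curve locally, realized as the three-point circumradius (Menger
  curvature) over a sample window; 1/mm.
- turning points: direction-of-bending reversals, detected as unit
  normal jumps with ||dN||^2 >= 1 (a rotation of at least 60 degrees of
  the bending direction since the last counted event), with a minimum
  arc-length separation between events.
- ICM = turns x TI, and cw-ICM = max curvature x turns x TI, the
  curvature-weighted inflection count metric (curvature in 1/mm).

A vessel is called tortuous when it shows a corkscrew-like course:
five or more turns and/or TI exceeding 1.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .centerline import Centerline

__all__ = [
    "TortuosityMetrics", "ti", "bending_length", "curvature_profile",
    "turning_points", "turn_count_winding", "cw_icm", "is_tortuous",
    "compute_metrics", "count_tortuous_per_slice", "pvs_colocalization",
    "TORTUOUS_MIN_TURNS", "TORTUOUS_TI_THRESHOLD",
]

#: Default tortuous-vessel criteria: corkscrew vessels typically show
#: five or more turns and a tortuosity index above 1.05.
TORTUOUS_MIN_TURNS = 5
TORTUOUS_TI_THRESHOLD = 1.05


@dataclass
class TortuosityMetrics:
    """Per-vessel tortuosity measurements (lengths mm, curvature 1/mm)."""

    al_mm: float
    dl_mm: float
    ti: float
    bl_mm: float
    kappa_max_per_mm: float
    n_turns: int
    icm: float
    cw_icm: float
    is_tortuous: bool


def _points(centerline):
    if isinstance(centerline, Centerline):
        return centerline.points
    return np.asarray(centerline, dtype=float).reshape(-1, 3)


def ti(centerline):
    """Tortuosity index.  Returns ``(TI, AL_mm, DL_mm)``."""
    pts = _points(centerline)
    if len(pts) < 2:
        raise ValueError("TI needs at least two points")
    al = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    dl = float(np.linalg.norm(pts[-1] - pts[0]))
    if dl <= 1e-12:
        raise ValueError("DL = 0: endpoints coincide (closed curve)")
    return al / dl, al, dl


def bending_length(centerline):
    """Maximum perpendicular distance to the endpoint chord line, mm."""
    pts = _points(centerline)
    if len(pts) < 3:
        raise ValueError("BL needs at least three points")
    chord = pts[-1] - pts[0]
    dl = np.linalg.norm(chord)
    if dl <= 1e-12:
        raise ValueError("DL = 0: endpoints coincide")
    u = chord / dl
    rel = pts - pts[0]
    perp = rel - np.outer(rel @ u, u)
    return float(np.linalg.norm(perp, axis=1).max())


def _menger_curvature(p0, p1, p2):
    a = np.linalg.norm(p1 - p0, axis=-1)
    b = np.linalg.norm(p2 - p1, axis=-1)
    c = np.linalg.norm(p2 - p0, axis=-1)
    area2 = np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=-1)  # 2*area
    denom = a * b * c
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(denom > 0, 2.0 * area2 / denom, 0.0)
    return kappa


def curvature_profile(centerline, window=2):
    """Per-point Menger curvature and its maximum.

    Curvature at interior point i is the reciprocal circumradius of the
    triple (i - w, i, i + w); the centerline should be uniformly
    resampled so the window has consistent physical extent.  Collinear
    triples give zero.  Returns ``(kappa, kappa_max)`` where ``kappa``
    has one entry per interior point ``i in [w, n-1-w]``.
    """
    pts = _points(centerline)
    w = int(window)
    if w < 1:
        raise ValueError("window must be >= 1")
    if len(pts) < 2 * w + 1:
        raise ValueError("too few points for the curvature window")
    kappa = _menger_curvature(pts[: -2 * w], pts[w: -w], pts[2 * w:])
    return kappa, float(kappa.max())


def _discrete_normals(pts, arclen, kappa_min):
    """Unit bending-direction normals at interior points.

    The discrete normal at point i is the normalized change of the unit
    tangent, defined only where the discrete curvature exceeds
    ``kappa_min`` (the bending direction is meaningless on straight
    runs).  Returns (normals, arclens, valid) over interior points.
    """
    tangents = np.diff(pts, axis=0)
    seg = np.linalg.norm(tangents, axis=1)
    t_unit = tangents / seg[:, None]
    dn = np.diff(t_unit, axis=0)                  # at interior points
    ds = 0.5 * (seg[:-1] + seg[1:])
    kappa_disc = np.linalg.norm(dn, axis=1) / ds
    valid = kappa_disc >= kappa_min
    normals = np.zeros_like(dn)
    nz = np.linalg.norm(dn, axis=1)
    ok = nz > 0
    normals[ok] = dn[ok] / nz[ok, None]
    return normals, arclen[1:-1], valid & ok


def turning_points(centerline, gap_mm=0.2, kappa_min=0.2):
    """Count direction-of-bending reversals along the centerline.

    Walking the interior points with a well-defined bending normal, an
    event is counted whenever the squared jump of the unit normal since
    the last event reaches 1 (a rotation of >= 60 degrees) and at least
    ``gap_mm`` of arc has passed since the previous event.  The
    reference normal is reset at each event, so slow continuous rotation
    (a helix) accumulates events while digitization chatter is gated by
    ``kappa_min`` and ``gap_mm``.  A straight line counts 0.
    """
    pts = _points(centerline)
    if len(pts) < 3:
        return 0
    if isinstance(centerline, Centerline):
        s = centerline.arclen
    else:
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
    normals, s_mid, valid = _discrete_normals(pts, s, kappa_min)
    n_ref = None
    s_last = -np.inf
    count = 0
    for n_i, s_i, ok in zip(normals, s_mid, valid):
        if not ok:
            continue
        if n_ref is None:
            n_ref = n_i
            continue
        if np.sum((n_i - n_ref) ** 2) >= 1.0 and s_i - s_last >= gap_mm:
            count += 1
            n_ref = n_i
            s_last = s_i
    return count


def turn_count_winding(centerline, kappa_min=0.2):
    """Alternative turn counter: full revolutions of the bending normal.

    Accumulates the unsigned angle swept by the unit bending normal over
    valid interior points and returns ``total / (2*pi)`` — for an ideal
    helix this is the number of helical periods.  Provided because a
    visual "corkscrew turn" may mean either a bending reversal (see
    :func:`turning_points`) or a full winding.
    """
    pts = _points(centerline)
    if len(pts) < 3:
        return 0.0
    if isinstance(centerline, Centerline):
        s = centerline.arclen
    else:
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
    normals, _, valid = _discrete_normals(pts, s, kappa_min)
    nv = normals[valid]
    if len(nv) < 2:
        return 0.0
    dots = np.clip(np.sum(nv[1:] * nv[:-1], axis=1), -1.0, 1.0)
    return float(np.arccos(dots).sum() / (2 * np.pi))


def cw_icm(ti_value, kappa_max, n_turns):
    """Inflection count metrics.  Returns ``(ICM, cw_ICM)``.

    ICM = turns x TI;  cw-ICM = max curvature x turns x TI.
    """
    icm = float(n_turns) * float(ti_value)
    return icm, float(kappa_max) * icm


def is_tortuous(ti_value=None, n_turns=None, rule="both",
                min_turns=TORTUOUS_MIN_TURNS,
                ti_threshold=TORTUOUS_TI_THRESHOLD, metrics=None):
    """Apply the tortuous-vessel criterion.

    rule="turns": n_turns >= 5;  rule="ti": TI > 1.05;
    rule="both" (default): both conditions.
    """
    if metrics is not None:
        ti_value, n_turns = metrics.ti, metrics.n_turns
    if rule == "turns":
        return n_turns >= min_turns
    if rule == "ti":
        return ti_value > ti_threshold
    if rule == "both":
        return (n_turns >= min_turns) and (ti_value > ti_threshold)
    raise ValueError(f"unknown tortuosity rule {rule!r}")


def compute_metrics(centerline, window=2, gap_mm=0.2, kappa_min=0.2,
                    rule="both"):
    """All tortuosity measurements for one (resampled) centerline."""
    t, al, dl = ti(centerline)
    bl = bending_length(centerline)
    _, kmax = curvature_profile(centerline, window=window)
    n_turns = turning_points(centerline, gap_mm=gap_mm, kappa_min=kappa_min)
    icm, cwicm = cw_icm(t, kmax, n_turns)
    return TortuosityMetrics(
        al_mm=al, dl_mm=dl, ti=t, bl_mm=bl, kappa_max_per_mm=kmax,
        n_turns=n_turns, icm=icm, cw_icm=cwicm,
        is_tortuous=is_tortuous(t, n_turns, rule=rule),
    )


def count_tortuous_per_slice(masks, tortuous_flags, axis=2):
    """Average per-slice count of distinct tortuous vessels.

    ``masks`` is a sequence of boolean volumes (one per vessel) and
    ``tortuous_flags`` the matching booleans.  For every slice along
    ``axis`` the number of distinct tortuous vessels intersecting it is
    counted; the mean over all slices (including empty ones) is
    returned.
    """
    masks = list(masks)
    if not masks:
        raise ValueError("need at least one mask volume")
    n_slices = masks[0].shape[axis]
    if n_slices == 0:
        raise ValueError("volume has zero slices")
    reduce_axes = tuple(a for a in range(3) if a != axis)
    counts = np.zeros(n_slices)
    for m, flag in zip(masks, tortuous_flags):
        if not flag:
            continue
        counts += np.any(m, axis=reduce_axes).astype(float)
    return float(counts.mean())


def _fill_tube_lumen(mask):
    """Fill the lumen of a sheath even when it is an open-ended tube.

    3D hole filling only closes fully enclosed cavities; a perivascular
    sheath is an annulus open at both ends, so the lumen is additionally
    filled slice-wise along each grid axis.
    """
    filled = ndimage.binary_fill_holes(mask)
    for axis in range(3):
        for k in range(mask.shape[axis]):
            sl = [slice(None)] * 3
            sl[axis] = k
            sl = tuple(sl)
            filled[sl] |= ndimage.binary_fill_holes(mask[sl])
    return filled


def pvs_colocalization(pvs_mask, artery_masks, tortuous_flags,
                       containment=0.5):
    """PVS counts and their co-localization with tortuous arteries.

    PVS sheaths are counted as 26-connected components of ``pvs_mask``.
    Each component is hole-filled (a sheath is an annulus around the
    vessel; the enclosed lumen counts as inside), and a PVS is said to
    contain an enclosed tortuous artery if at least ``containment`` of
    some flagged artery's voxels lie inside it.  Returns a dict with
    ``n_pvs``, ``n_pvs_with_tortuous_artery`` and ``ratio`` (0 when no
    PVS exist).
    """
    pvs = np.asarray(pvs_mask, dtype=bool)
    struct = ndimage.generate_binary_structure(3, 3)
    labels, n_pvs = ndimage.label(pvs, structure=struct)
    n_with = 0
    for cid in range(1, n_pvs + 1):
        filled = _fill_tube_lumen(labels == cid)
        for art, flag in zip(artery_masks, tortuous_flags):
            if not flag:
                continue
            total = art.sum()
            if total and (art & filled).sum() / total >= containment:
                n_with += 1
                break
    ratio = n_with / n_pvs if n_pvs else 0.0
    return {"n_pvs": int(n_pvs),
            "n_pvs_with_tortuous_artery": int(n_with),
            "ratio": float(ratio)}
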
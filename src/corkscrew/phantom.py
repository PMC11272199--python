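"""Synthetic vascular phantoms for small-vessel tortuosity analysis.

This module builds the ground truth the rest of the pipeline is tested
against: parametric vessel centerlines (straight, sinusoid, helix /
"corkscrew", smoothed random walks), their voxelization onto anisotropic
image grids, a dual-echo pre/post-contrast rendering that mimics the
qualitative signal behaviour of USPIO-enhanced gradient-echo imaging
(arteries visible only post-contrast, veins visible in both, veins darker,
post-contrast blooming), and age-structured synthetic cohorts whose
tortuous-vessel count follows a quadratic law in age.

All geometry is expressed in physical millimetres.  The voxel-center
convention is ``center = (index + 0.5) * spacing`` with 0-based indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "ParametricCurve",
    "VesselInstance",
    "ImageVolume",
    "PhantomSpec",
    "CohortModel",
    "make_curve",
    "voxel_centers",
    "voxelize",
    "voxelize_pvs",
    "render_dual_echo",
    "generate_cohort",
    "QUADRATIC_AGE_COEFFS",
]

#: Coefficients (a, b, c) of the quadratic mean model for the number of
#: tortuous arteries as a function of age in years:
#: ``count = a*age**2 + b*age + c``.
QUADRATIC_AGE_COEFFS = (0.037, -1.458, 35.34)

_CURVE_KINDS = ("straight", "sinusoid", "helix", "random_walk")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParametricCurve:
    """An arc-length-ordered 3D polyline sampled from an analytic curve.

    Attributes
    ----------
    kind : str
        One of ``straight``, ``sinusoid``, ``helix``, ``random_walk``.
    params : dict
        The geometric parameters the curve was built from (mm units).
    samples : (n, 3) ndarray
        Ordered sample points in physical mm; consecutive points distinct.
    """

    kind: str
    params: dict
    samples: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 2:
            raise ValueError("curve needs at least 2 sample points of dim 3")
        seg = np.linalg.norm(np.diff(s, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("consecutive curve samples must be distinct")
        object.__setattr__(self, "samples", s)

    @property
    def arc_length(self) -> float:
        """Total polyline arc length in mm."""
        return float(np.linalg.norm(np.diff(self.samples, axis=0), axis=1).sum())


@dataclass(frozen=True)
class VesselInstance:
    """A ground-truth phantom vessel: centerline, lumen radius and class.

    ``radius_mm`` is the lumen radius; cerebral small vessels of interest
    here have diameters of roughly 50-300 um (0.025-0.15 mm radius), though
    any positive radius is accepted.  ``pvs_radius_mm`` > radius adds a
    perivascular-space sheath (0 disables it).
    """

    curve: ParametricCurve
    radius_mm: float
    vclass: str  # "artery" | "vein"
    pvs_radius_mm: float = 0.0
    truth_tortuous: bool = False

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if self.vclass not in ("artery", "vein"):
            raise ValueError(f"unknown vessel class {self.vclass!r}")
        if self.pvs_radius_mm != 0 and self.pvs_radius_mm <= self.radius_mm:
            raise ValueError("pvs_radius_mm must be 0 or exceed radius_mm")


@dataclass
class ImageVolume:
    """A 3D scalar image with physical spacing and acquisition context."""

    data: np.ndarray
    spacing_mm: tuple
    TE_ms: float = 15.0
    contrast_state: str = "pre"  # "pre" | "post"
    noise_sigma: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("ImageVolume expects a 3D array")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm) or len(self.spacing_mm) != 3:
            raise ValueError("spacing must be three positive values")
        if np.any(self.data < 0):
            raise ValueError("intensities must be nonnegative")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class PhantomSpec:
    """Complete description of one synthetic dual-echo acquisition.

    Rendering parameters are deliberately simple conventions, not MR
    physics: they reproduce the contrast ordering of USPIO imaging
    (see :func:`render_dual_echo`).
    """

    fov_mm: tuple = (12.0, 8.0, 6.0)
    spacing_mm: tuple = (0.25, 0.25, 1.0)
    vessels: list = field(default_factory=list)
    TE1_ms: float = 15.0
    TE2_ms: float = 25.0
    seed: int = 0
    noise_sigma: float = 0.02
    a_artery: float = 0.6     # artery attenuation at TE1, post only
    a_vein: float = 0.35      # vein attenuation at TE1, pre and post
    te2_factor: float = 0.8   # extra attenuation of vessels at the long TE
    bloom_mm: float = 0.15    # post-contrast apparent-radius increase
    pvs_intensity: float = 1.3  # PVS sheath intensity in pre volumes

    def __post_init__(self):
        self.fov_mm = tuple(float(v) for v in self.fov_mm)
        self.spacing_mm = tuple(float(v) for v in self.spacing_mm)
        for a in (self.a_artery, self.a_vein, self.te2_factor):
            if not (0 < a <= 1):
                raise ValueError("attenuation factors must lie in (0, 1]")
        if self.TE1_ms >= self.TE2_ms:
            raise ValueError("TE1 must be shorter than TE2")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")

    @property
    def shape(self):
        return tuple(
            int(round(f / s)) for f, s in zip(self.fov_mm, self.spacing_mm)
        )


# ---------------------------------------------------------------------------
# curve construction
# ---------------------------------------------------------------------------

def _basis(axis):
    """Orthonormal frame (u, e1, e2) with u along ``axis``."""
    u = np.asarray(axis, dtype=float)
    n = np.linalg.norm(u)
    if n == 0:
        raise ValueError("axis must be a nonzero vector")
    u = u / n
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(u, helper)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return u, e1, e2


def _n_samples(params, arc_estimate, default_density=100.0):
    n = params.get("n_samples")
    if n is None:
        n = max(2, int(np.ceil(default_density * arc_estimate)) + 1)
    return int(n)


def make_curve(kind, params, seed=None):
    """Build a :class:`ParametricCurve` of the given kind.

    Parameters by kind (all lengths in mm):

    - ``straight``: length_mm; optional n_samples (default 2).
    - ``sinusoid``: amplitude_mm, period_mm, n_periods; planar sine wave
      along the axis, displaced along the first transverse direction.
    - ``helix``: radius_mm, pitch_mm, n_turns; circular helix — the
      idealized "corkscrew" geometry of degenerated small arteries.
    - ``random_walk``: length_mm, step_mm, optional lateral_sd_mm
      (default 0.3*step), smoothing window (default 5) and target_ti:
      a smoothed lateral random walk, with the lateral amplitude scaled
      by bisection until the tortuosity index matches target_ti (1%).

    Optional common params: ``origin`` (3-vector, default 0), ``axis``
    (default +x), ``phase`` (helix/sinusoid start phase, radians),
    ``n_samples``.  Samples of analytic kinds match the closed-form
    coordinates exactly at the sample parameters.
    """
    if kind not in _CURVE_KINDS:
        raise ValueError(f"unknown curve kind {kind!r}")
    params = dict(params)
    origin = np.asarray(params.get("origin", (0.0, 0.0, 0.0)), dtype=float)
    axis = params.get("axis", (1.0, 0.0, 0.0))
    u, e1, e2 = _basis(axis)
    phase = float(params.get("phase", 0.0))

    if kind == "straight":
        length = float(params["length_mm"])
        if length <= 0:
            raise ValueError("length_mm must be positive")
        n = int(params.get("n_samples", 2))
        t = np.linspace(0.0, length, n)
        pts = origin + t[:, None] * u

    elif kind == "sinusoid":
        amp = float(params["amplitude_mm"])
        period = float(params["period_mm"])
        n_periods = float(params["n_periods"])
        if amp <= 0 or period <= 0 or n_periods <= 0:
            raise ValueError("sinusoid parameters must be positive")
        length = period * n_periods
        arc_est = length * np.sqrt(1 + (2 * np.pi * amp / period) ** 2 / 2)
        n = _n_samples(params, arc_est)
        x = np.linspace(0.0, length, n)
        y = amp * np.sin(2 * np.pi * x / period + phase)
        pts = origin + x[:, None] * u + y[:, None] * e1

    elif kind == "helix":
        r = float(params["radius_mm"])
        pitch = float(params["pitch_mm"])
        n_turns = float(params["n_turns"])
        if r <= 0 or pitch <= 0 or n_turns <= 0:
            raise ValueError("helix parameters must be positive")
        arc_est = n_turns * np.hypot(2 * np.pi * r, pitch)
        n = _n_samples(params, arc_est)
        theta = np.linspace(0.0, 2 * np.pi * n_turns, n)
        pts = (
            origin
            + (pitch * theta / (2 * np.pi))[:, None] * u
            + r * np.cos(theta + phase)[:, None] * e1
            + r * np.sin(theta + phase)[:, None] * e2
        )

    else:  # random_walk
        length = float(params["length_mm"])
        step = float(params.get("step_mm", 0.1))
        if length <= 0 or step <= 0:
            raise ValueError("random_walk parameters must be positive")
        lateral_sd = float(params.get("lateral_sd_mm", 0.3 * step))
        window = int(params.get("window", 5))
        rng = np.random.default_rng(seed)
        n = max(3, int(np.ceil(length / step)) + 1)
        lat = rng.normal(0.0, lateral_sd, size=(n, 2)).cumsum(axis=0)
        kernel = np.ones(max(1, window)) / max(1, window)
        lat = np.column_stack(
            [np.convolve(lat[:, j], kernel, mode="same") for j in range(2)]
        )
        lat -= lat[0]
        along = np.linspace(0.0, length, n)

        def assemble(scale):
            return (
                origin
                + along[:, None] * u
                + scale * lat[:, 0, None] * e1
                + scale * lat[:, 1, None] * e2
            )

        target_ti = params.get("target_ti")
        scale = 1.0
        if target_ti is not None:
            scale = _fit_ti_scale(assemble, float(target_ti))
        pts = assemble(scale)

    # drop any accidental duplicate consecutive samples (random_walk only)
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 0
    return ParametricCurve(kind=kind, params=params, samples=pts[keep])


def _polyline_ti(pts):
    al = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
    dl = np.linalg.norm(pts[-1] - pts[0])
    return al / dl


def _fit_ti_scale(assemble, target_ti, tol=0.01, max_iter=60):
    """Bisect the lateral scale of a random walk to a target TI."""
    if target_ti < 1:
        raise ValueError("target TI cannot be below 1")
    lo, hi = 0.0, 1.0
    while _polyline_ti(assemble(hi)) < target_ti and hi < 1e4:
        hi *= 2.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        ti = _polyline_ti(assemble(mid))
        if abs(ti - target_ti) <= tol * target_ti:
            return mid
        if ti < target_ti:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------

def voxel_centers(shape, spacing_mm):
    """(nx*ny*nz, 3) array of physical voxel-center coordinates."""
    axes = [
        (np.arange(n) + 0.5) * s for n, s in zip(shape, spacing_mm)
    ]
    grid = np.meshgrid(*axes, indexing="ij")
    return np.stack([g.ravel() for g in grid], axis=1)


def _densify(samples, step):
    """Resample a polyline so consecutive points are at most ``step`` apart."""
    seg = np.linalg.norm(np.diff(samples, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(2, int(np.ceil(s[-1] / step)) + 1)
    t = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(t, s, samples[:, j]) for j in range(3)])


def _tube_mask(samples, radius, shape, spacing):
    """Boolean mask of voxels whose center lies within ``radius`` of a curve.

    Distances are Euclidean in physical mm, so anisotropic grids are
    handled exactly.  The curve is densified to 1/8 of the smallest
    spacing, bounding the polyline-vs-point-set error well below a voxel.
    """
    step = min(spacing) / 8.0
    dense = _densify(samples, step)
    tree = cKDTree(dense)
    centers = voxel_centers(shape, spacing)
    dist, _ = tree.query(centers, k=1, distance_upper_bound=radius + step)
    mask = dist <= radius
    return mask.reshape(shape)


_SUPERSAMPLE = (2, 2, 5)  # sub-voxel sampling per axis for volume fractions


def _tube_fraction(samples, radius, shape, spacing, supersample=_SUPERSAMPLE):
    """Per-voxel volume fraction occupied by a tube around a curve.

    Each voxel box is probed on a regular sub-grid (finer along the
    coarse slice axis) and the fraction of probes within ``radius`` of
    the densified curve is returned.  This is the partial-volume kernel
    of the renderer: thin vessels crossing between slice centers still
    contribute proportional signal instead of vanishing.
    """
    step = min(spacing) / 8.0
    dense = _densify(samples, step)
    tree = cKDTree(dense)
    spacing = np.asarray(spacing, dtype=float)
    offsets = [
        (np.arange(k) + 0.5) / k - 0.5 for k in supersample
    ]
    frac = np.zeros(shape)
    centers = voxel_centers(shape, spacing)
    for ox in offsets[0]:
        for oy in offsets[1]:
            for oz in offsets[2]:
                pts = centers + np.array([ox, oy, oz]) * spacing
                dist, _ = tree.query(pts, k=1,
                                     distance_upper_bound=radius + step)
                frac += (dist <= radius).reshape(shape)
    return frac / np.prod(supersample)


def _annulus_mask(samples, r_in, r_out, shape, spacing):
    step = min(spacing) / 8.0
    dense = _densify(samples, step)
    tree = cKDTree(dense)
    centers = voxel_centers(shape, spacing)
    dist, _ = tree.query(centers, k=1, distance_upper_bound=r_out + step)
    mask = (dist <= r_out) & (dist > r_in)
    return mask.reshape(shape)


def voxelize(vessels, spec):
    """Rasterize vessels onto the spec's grid.

    Returns ``(labels, masks)`` where ``labels`` is an integer volume
    (0 background, k = index of vessel k-1 + 1; earlier vessels win on
    overlap) and ``masks`` the per-vessel boolean volumes.  A vessel
    whose radius is below half the smallest spacing triggers a sub-voxel
    warning (post-contrast blooming compensates for it downstream).
    """
    shape = spec.shape
    labels = np.zeros(shape, dtype=np.int32)
    masks = []
    for k, v in enumerate(vessels):
        if v.radius_mm < min(spec.spacing_mm) / 2.0:
            warnings.warn(
                f"vessel {k}: radius {v.radius_mm} mm is sub-voxel on this grid",
                stacklevel=2,
            )
        m = _tube_mask(v.curve.samples, v.radius_mm, shape, spec.spacing_mm)
        masks.append(m)
        labels[m & (labels == 0)] = k + 1
    return labels, masks


def voxelize_pvs(vessels, spec):
    """Boolean volume of all perivascular-space sheaths (annuli)."""
    shape = spec.shape
    pvs = np.zeros(shape, dtype=bool)
    for v in vessels:
        if v.pvs_radius_mm > 0:
            pvs |= _annulus_mask(
                v.curve.samples, v.radius_mm, v.pvs_radius_mm, shape,
                spec.spacing_mm,
            )
    return pvs


# ---------------------------------------------------------------------------
# dual-echo rendering
# ---------------------------------------------------------------------------

def render_dual_echo(spec, return_truth=False):
    """Render the four magnitude volumes of a dual-echo pre/post study.

    The signal model is a deliberate simplification reproducing the
    contrast ordering of USPIO dual-echo GRE, not Bloch physics:

    - background tissue has intensity 1.0;
    - veins (deoxygenated blood) attenuate in all four volumes to
      ``a_vein`` at TE1, with an extra ``te2_factor`` at TE2;
    - arteries are invisible pre-contrast and attenuate to ``a_artery``
      post-contrast only (``a_artery > a_vein``: veins are darker);
    - post-contrast the agent adds its attenuation to veins too
      (vein post = a_vein * a_artery) and the apparent vessel cross
      section blooms: the effective radius grows by ``bloom_mm``
      (isotropic in physical units);
    - attenuation is weighted by the per-voxel lumen volume fraction
      (partial volume), so a voxel fully inside an artery reads exactly
      ``a_artery`` post-contrast while boundary voxels are intermediate;
    - PVS sheaths render hyperintense (CSF-like) in the pre volumes;
    - i.i.d. Gaussian noise of sd ``noise_sigma`` is added per volume
      (independent, seeded draws), and intensities clipped at 0.

    Returns a dict with keys ``pre_TE1, pre_TE2, post_TE1, post_TE2``;
    with ``return_truth=True`` also a dict of ground-truth masks and
    labels.
    """
    shape = spec.shape
    _, masks = voxelize(spec.vessels, spec)
    # veins carry an intrinsic deoxyhemoglobin susceptibility halo, so
    # their apparent radius includes the bloom even pre-contrast; the
    # arterial halo appears only once the contrast agent circulates
    frac_pre = [
        _tube_fraction(
            v.curve.samples,
            v.radius_mm + (spec.bloom_mm if v.vclass == "vein" else 0.0),
            shape, spec.spacing_mm)
        for v in spec.vessels
    ]
    frac_post = [
        _tube_fraction(v.curve.samples, v.radius_mm + spec.bloom_mm, shape,
                       spec.spacing_mm)
        for v in spec.vessels
    ]
    pvs = voxelize_pvs(spec.vessels, spec)
    pvs_frac = np.zeros(shape)
    for v in spec.vessels:
        if v.pvs_radius_mm > 0:
            f_out = _tube_fraction(v.curve.samples, v.pvs_radius_mm, shape,
                                   spec.spacing_mm)
            f_in = _tube_fraction(v.curve.samples, v.radius_mm, shape,
                                  spec.spacing_mm)
            pvs_frac = np.maximum(pvs_frac, np.clip(f_out - f_in, 0, 1))

    def paint(contrast, te_factor):
        vol = np.ones(shape)
        if contrast == "pre":
            vol += (spec.pvs_intensity - 1.0) * pvs_frac
        for v, fp, fb in zip(spec.vessels, frac_pre, frac_post):
            if contrast == "pre":
                if v.vclass != "vein":
                    continue
                a, f = spec.a_vein * te_factor, fp
            else:
                a = spec.a_artery if v.vclass == "artery" \
                    else spec.a_vein * spec.a_artery
                a, f = a * te_factor, fb
            vol = np.minimum(vol, vol * (1 - f) + a * f)
        return vol

    seeds = np.random.SeedSequence(spec.seed).spawn(4)
    out = {}
    keys = ("pre_TE1", "pre_TE2", "post_TE1", "post_TE2")
    for key, child in zip(keys, seeds):
        contrast, echo = key.split("_")
        te_factor = 1.0 if echo == "TE1" else spec.te2_factor
        vol = paint(contrast, te_factor)
        if spec.noise_sigma > 0:
            rng = np.random.default_rng(child)
            vol = vol + rng.normal(0.0, spec.noise_sigma, size=shape)
        out[key] = ImageVolume(
            data=np.clip(vol, 0.0, None),
            spacing_mm=spec.spacing_mm,
            TE_ms=spec.TE1_ms if echo == "TE1" else spec.TE2_ms,
            contrast_state=contrast,
            noise_sigma=spec.noise_sigma,
        )
    if return_truth:
        truth = {
            "masks": masks,
            "bloomed": [f > 0.5 for f in frac_post],
            "pvs": pvs,
            "vclass": [v.vclass for v in spec.vessels],
            "truth_tortuous": [v.truth_tortuous for v in spec.vessels],
        }
        return out, truth
    return out


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortModel:
    """Generative model for age-structured cohort tables.

    The mean tortuous-vessel count follows the quadratic age law
    ``a*age^2 + b*age + c`` with additive Gaussian noise (sd
    ``count_sd``), floored at 0 and kept continuous (counts are
    per-slice averages, not integers).  TI / BL / cw-ICM means rise
    linearly in age; slopes and anchors are calibrated to the young
    (mean age 32) vs old (mean age 62) group summaries of the source
    cohort: TI 1.10 -> 1.14, BL 0.31 -> 0.60 mm, cw-ICM 7.89 -> 12.31.
    Covariates are drawn from the cohort's marginal summaries.
    """

    quad_a: float = QUADRATIC_AGE_COEFFS[0]
    quad_b: float = QUADRATIC_AGE_COEFFS[1]
    quad_c: float = QUADRATIC_AGE_COEFFS[2]
    count_sd: float = 15.0
    age_min: float = 21.0
    age_max: float = 70.0
    ti_anchor: tuple = (32.0, 1.10)
    ti_slope: float = (1.14 - 1.10) / 30.0
    ti_sd: float = 0.03
    bl_anchor: tuple = (32.0, 0.31)
    bl_slope: float = (0.60 - 0.31) / 30.0
    bl_sd: float = 0.11
    cwicm_anchor: tuple = (32.0, 7.89)
    cwicm_slope: float = (12.31 - 7.89) / 30.0
    cwicm_sd: float = 2.75
    p_female: float = 19 / 37
    bmi_mean: float = 25.3
    bmi_sd: float = 4.8
    sbp_mean: float = 120.0
    sbp_sd: float = 13.4
    dbp_mean: float = 72.0
    dbp_sd: float = 11.9
    p_hypercholesterolemia: float = 5 / 37
    p_diabetes: float = 3 / 37
    p_smoking: float = 2 / 37
    p_alcohol: float = 5 / 37

    def expected_count(self, age):
        age = np.asarray(age, dtype=float)
        return self.quad_a * age**2 + self.quad_b * age + self.quad_c


def generate_cohort(n, seed, model=None, with_phantoms=False,
                    max_phantom_vessels=6):
    """Draw a synthetic cohort table of ``n`` subjects.

    Ages are uniform on [age_min, age_max].  Returns a DataFrame with
    columns subject_id, age_years, sex, bmi, sbp_mmHg, dbp_mmHg, the four
    risk flags, n_tortuous, ti_mean, bl_mean_mm, cwicm_mean.  With
    ``with_phantoms=True`` also returns a list of per-subject
    :class:`PhantomSpec` whose corkscrew-vessel count tracks (capped)
    the subject's n_tortuous.
    """
    if n < 2:
        raise ValueError("cohort needs n >= 2 subjects")
    model = model or CohortModel()
    if model.count_sd < 0:
        raise ValueError("count noise sd must be nonnegative")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    age = rng.uniform(model.age_min, model.age_max, size=n)
    count = model.expected_count(age) + rng.normal(0, model.count_sd, size=n)
    count = np.clip(count, 0.0, None)

    def linked(anchor, slope, sd, floor):
        a0, v0 = anchor
        mean = v0 + slope * (age - a0)
        return np.clip(mean + rng.normal(0, sd, size=n), floor, None)

    ti = linked(model.ti_anchor, model.ti_slope, model.ti_sd, 1.0)
    bl = linked(model.bl_anchor, model.bl_slope, model.bl_sd, 0.0)
    cwicm = linked(model.cwicm_anchor, model.cwicm_slope, model.cwicm_sd, 0.0)

    table = pd.DataFrame({
        "subject_id": [f"S{i:04d}" for i in range(n)],
        "age_years": age,
        "sex": np.where(rng.random(n) < model.p_female, "F", "M"),
        "bmi": rng.normal(model.bmi_mean, model.bmi_sd, size=n),
        "sbp_mmHg": rng.normal(model.sbp_mean, model.sbp_sd, size=n),
        "dbp_mmHg": rng.normal(model.dbp_mean, model.dbp_sd, size=n),
        "hypercholesterolemia": rng.random(n) < model.p_hypercholesterolemia,
        "diabetes": rng.random(n) < model.p_diabetes,
        "smoking": rng.random(n) < model.p_smoking,
        "alcohol": rng.random(n) < model.p_alcohol,
        "n_tortuous": count,
        "ti_mean": ti,
        "bl_mean_mm": bl,
        "cwicm_mean": cwicm,
    })
    if not with_phantoms:
        return table

    specs = []
    children = ss.spawn(n + 1)[1:]
    for i, child in enumerate(children):
        k = int(min(max_phantom_vessels, round(count[i] / 20.0)))
        specs.append(corkscrew_population_spec(
            n_vessels=max(1, k), seed=int(child.generate_state(1)[0] % (2**31)),
        ))
    return table, specs


# ---------------------------------------------------------------------------
# default corkscrew populations (shared by tests, examples, acceptance)
# ---------------------------------------------------------------------------

#: Default corkscrew geometry ranges: helix radius, pitch per turn (mm)
#: and number of turns, chosen so pipeline TI falls in the 1.1-2.5 band
#: reported for degenerated medullary arteries in histology.
CORKSCREW_RADIUS_RANGE = (0.1, 0.2)
CORKSCREW_PITCH_RANGE = (0.3, 0.6)
CORKSCREW_TURNS_RANGE = (5, 8)
DEFAULT_VESSEL_RADIUS_MM = 0.1


def corkscrew_vessel(rng, fov_mm=(12.0, 8.0, 6.0), spacing_mm=(0.25, 0.25, 1.0),
                     lane=None, vclass="artery", pvs=False):
    """Draw one corkscrew vessel with default geometry ranges.

    The helix axis runs along y (in-plane on the anisotropic grid) so the
    winding is resolved by the fine in-plane sampling, mirroring how
    medullary arteries course within axial slices.  ``lane`` optionally
    fixes the (x, z) position in mm; the z position snaps to a
    slice-center plane.
    """
    r = rng.uniform(*CORKSCREW_RADIUS_RANGE)
    pitch = rng.uniform(*CORKSCREW_PITCH_RANGE)
    n_turns = int(rng.integers(CORKSCREW_TURNS_RANGE[0],
                               CORKSCREW_TURNS_RANGE[1] + 1))
    phase = rng.uniform(0, 2 * np.pi)
    length = pitch * n_turns
    margin = r + DEFAULT_VESSEL_RADIUS_MM + 0.5
    if lane is None:
        x = rng.uniform(margin, fov_mm[0] - margin)
        z = rng.uniform(margin, fov_mm[2] - margin)
    else:
        x, z = lane
    # snap the axis onto a slice-center plane
    z = (np.floor(z / spacing_mm[2]) + 0.5) * spacing_mm[2]
    y0 = 0.5 * (fov_mm[1] - length)
    curve = make_curve("helix", {
        "radius_mm": r, "pitch_mm": pitch, "n_turns": n_turns,
        "phase": phase, "axis": (0.0, 1.0, 0.0), "origin": (x, y0, z),
    })
    return VesselInstance(
        curve=curve, radius_mm=DEFAULT_VESSEL_RADIUS_MM, vclass=vclass,
        pvs_radius_mm=0.45 if pvs else 0.0, truth_tortuous=True,
    )


def straight_vessel(x, z, fov_mm=(12.0, 8.0, 6.0), spacing_mm=(0.25, 0.25, 1.0),
                    vclass="vein", radius_mm=DEFAULT_VESSEL_RADIUS_MM,
                    margin_mm=0.5):
    """A straight vessel along y spanning the FOV minus a margin."""
    z = (np.floor(z / spacing_mm[2]) + 0.5) * spacing_mm[2]
    curve = make_curve("straight", {
        "length_mm": fov_mm[1] - 2 * margin_mm,
        "axis": (0.0, 1.0, 0.0), "origin": (x, margin_mm, z),
        "n_samples": 50,
    })
    return VesselInstance(curve=curve, radius_mm=radius_mm, vclass=vclass,
                          truth_tortuous=False)


def corkscrew_population_spec(n_vessels=4, seed=0, fov_mm=(12.0, 8.0, 6.0),
                              spacing_mm=(0.25, 0.25, 1.0), noise_sigma=0.0,
                              **spec_kwargs):
    """A PhantomSpec holding ``n_vessels`` corkscrew arteries on a lane grid."""
    rng = np.random.default_rng(seed)
    margin = 1.0
    xs = np.linspace(margin, fov_mm[0] - margin, max(2, n_vessels))[:n_vessels]
    zs = [fov_mm[2] / 2 + (i % 2 - 0.5) * min(2.0, fov_mm[2] / 3)
          for i in range(n_vessels)]
    vessels = [
        corkscrew_vessel(rng, fov_mm, spacing_mm, lane=(x, z))
        for x, z in zip(xs, zs)
    ]
    return PhantomSpec(fov_mm=fov_mm, spacing_mm=spacing_mm, vessels=vessels,
                       seed=seed, noise_sigma=noise_sigma, **spec_kwargs)
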
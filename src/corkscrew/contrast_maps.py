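"""Arteriogram / venogram synthesis and slab intensity projections.

Dual-echo pre-contrast magnitudes yield a synthetic arteriogram by
nonlinear subtraction of the long echo from the short echo; the venogram
(after a T2*-shortening intravascular agent) is the post/pre ratio of the
short-echo magnitudes, so attenuated (vessel) voxels fall below 1 while
static background stays near 1.  Sliding-slab maximum / minimum intensity
projections (MIP / mIP) compress the maps for display: mIP highlights
dark tubular structures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import ImageVolume

__all__ = ["ProjectionSlab", "mra_nonlinear", "mrv_ratio", "project"]


@dataclass
class ProjectionSlab:
    """Result of a sliding-slab intensity projection."""

    mode: str                  # "MIP" | "mIP"
    axis: int
    slab_thickness_slices: int
    data: np.ndarray           # reduced 3D array (n - thickness + 1 slabs)

    def __post_init__(self):
        if self.slab_thickness_slices < 1:
            raise ValueError("slab thickness must be >= 1")


def _check_same_grid(a: ImageVolume, b: ImageVolume):
    if a.shape != b.shape or a.spacing_mm != b.spacing_mm:
        raise ValueError("volumes must share shape and spacing")


def mra_nonlinear(pre_te1: ImageVolume, pre_te2: ImageVolume, gamma=2.0):
    """Synthesize a pre-contrast arteriogram (MRA_nl).

    The short-echo magnitude retains more signal in flowing arterial
    blood than the long echo, so the clamped difference TE1 - TE2
    highlights arteries.  The difference is raised to ``gamma``
    elementwise (monotone contrast expansion; the "nonlinear" step) and
    min-max rescaled to [0, 1].  Voxels where the long-echo signal is
    not below the short-echo signal map to 0.
    """
    _check_same_grid(pre_te1, pre_te2)
    if pre_te1.TE_ms >= pre_te2.TE_ms:
        raise ValueError("TE1 must be shorter than TE2")
    diff = np.clip(pre_te1.data - pre_te2.data, 0.0, None) ** float(gamma)
    top = diff.max()
    if top > 0:
        diff = diff / top
    return ImageVolume(data=diff, spacing_mm=pre_te1.spacing_mm,
                       TE_ms=pre_te1.TE_ms, contrast_state="pre",
                       noise_sigma=pre_te1.noise_sigma)


def mrv_ratio(post_te1: ImageVolume, pre_te1: ImageVolume, eps=1e-6):
    """Synthesize a venogram: post-contrast / pre-contrast TE1 ratio.

    Background maps to ~1; contrast-attenuated (vessel) voxels to < 1.
    The denominator is floored at ``eps`` so the result is NaN-free.
    """
    _check_same_grid(post_te1, pre_te1)
    ratio = post_te1.data / np.clip(pre_te1.data, eps, None)
    return ImageVolume(data=ratio, spacing_mm=post_te1.spacing_mm,
                       TE_ms=post_te1.TE_ms, contrast_state="post",
                       noise_sigma=post_te1.noise_sigma)


def project(volume, mode, axis=2, slab_thickness=4):
    """Sliding-slab MIP or mIP along ``axis``.

    Every window of ``slab_thickness`` consecutive slices is reduced by
    max (MIP) or min (mIP), giving ``n_slices - thickness + 1`` slabs
    along the projection axis (thickness 1 is the identity).
    """
    data = volume.data if isinstance(volume, ImageVolume) else np.asarray(volume)
    if mode not in ("MIP", "mIP"):
        raise ValueError("mode must be 'MIP' or 'mIP'")
    t = int(slab_thickness)
    if t < 1 or t > data.shape[axis]:
        raise ValueError("slab thickness must lie in [1, axis extent]")
    windows = np.lib.stride_tricks.sliding_window_view(data, t, axis=axis)
    out = windows.max(axis=-1) if mode == "MIP" else windows.min(axis=-1)
    return ProjectionSlab(mode=mode, axis=axis, slab_thickness_slices=t,
                          data=out)
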
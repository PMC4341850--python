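"""Geometric volume transforms that also map point coordinates.

Used to verify that the junction-degree features are invariant under
axis-aligned 90-degree rotations, axis flips, integer translations and
integer upsampling of the input volume.  Each transform returns the new
volume together with a function mapping (possibly fractional) voxel-index
coordinates of the old volume to the new one, so seeds and ground-truth
positions can be carried along.
"""

from __future__ import annotations

import numpy as np

from .volume_io import LabelVolume


def flip_volume(vol: LabelVolume, axis: int):
    """Mirror the volume along one axis."""
    n = vol.shape[axis]
    voxels = np.flip(vol.voxels, axis=axis).copy()

    def map_point(p):
        p = np.asarray(p, dtype=float).copy()
        p[axis] = (n - 1) - p[axis]
        return p

    return LabelVolume(voxels, spacing=vol.spacing, origin=vol.origin), map_point


def transpose_volume(vol: LabelVolume, perm):
    """Permute the volume axes; spacing components are permuted along."""
    perm = tuple(perm)
    voxels = np.transpose(vol.voxels, perm).copy()
    spacing = vol.spacing[list(perm)]
    origin = vol.origin[list(perm)]

    def map_point(p):
        p = np.asarray(p, dtype=float)
        return p[list(perm)]

    return LabelVolume(voxels, spacing=spacing, origin=origin), map_point


def rot90_volume(vol: LabelVolume, axes=(0, 1)):
    """Rotate 90 degrees in the plane of two axes (swap axes, then flip)."""
    a, b = axes
    perm = list(range(3))
    perm[a], perm[b] = perm[b], perm[a]
    v1, f1 = transpose_volume(vol, perm)
    v2, f2 = flip_volume(v1, a)

    def map_point(p):
        return f2(f1(p))

    return v2, map_point


def translate_volume(vol: LabelVolume, shifts):
    """Pad the volume with background so all indices move by ``shifts``."""
    shifts = tuple(int(s) for s in shifts)
    pad = [(s, 0) for s in shifts]
    voxels = np.pad(vol.voxels, pad, mode="constant")

    def map_point(p):
        return np.asarray(p, dtype=float) + np.asarray(shifts, dtype=float)

    return LabelVolume(voxels, spacing=vol.spacing, origin=vol.origin), map_point


def upsample_volume(vol: LabelVolume, factor: int = 2):
    """Replicate every voxel ``factor`` times per axis (spacing unchanged).

    Physical lengths grow by ``factor``, so length parameters must be scaled
    proportionally when comparing features across the transform.
    """
    voxels = vol.voxels
    for axis in range(3):
        voxels = np.repeat(voxels, factor, axis=axis)

    def map_point(p):
        return np.asarray(p, dtype=float) * factor + (factor - 1) / 2.0

    return LabelVolume(voxels.copy(), spacing=vol.spacing, origin=vol.origin), map_point
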
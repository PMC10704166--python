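"""Synthetic geometries for verification: slabs and face terminals.

These helpers build the analytic benchmark scenes used by the test-suite
oracles and the acceptance computations: uniform or layered rectangular
slabs, and synthetic "electrodes" whose terminals cover a whole end face so
that a slab carries a spatially uniform current.
"""

from __future__ import annotations

import numpy as np

from .electrodes import ElectrodeGeometry
from .phantom import GM, LabeledHeadVolume


def make_slab(
    shape: tuple[int, int, int],
    voxel_size_mm: float,
    label: int = GM,
    pad_background: int = 0,
) -> LabeledHeadVolume:
    """A rectangular block of one tissue, optionally padded by background."""
    p = pad_background
    full = tuple(s + 2 * p for s in shape)
    labels = np.zeros(full, dtype=np.int16)
    sl = tuple(slice(p, p + s) for s in shape)
    labels[sl] = label
    origin = -(np.array(full) - 1.0) / 2.0 * voxel_size_mm
    return LabeledHeadVolume(labels, voxel_size_mm, origin)


def face_terminal_geometry(
    vol: LabeledHeadVolume, axis: int, end: str, role: str
) -> ElectrodeGeometry:
    """Synthetic electrode whose terminals cover one end face of a slab."""
    tissue = np.argwhere(vol.labels > 0)
    coord = tissue[:, axis]
    target = coord.max() if end == "high" else coord.min()
    face = tissue[coord == target]
    n = np.zeros(3)
    n[axis] = 1.0 if end == "high" else -1.0
    return ElectrodeGeometry(
        role=role,
        pad_voxels=face,
        gel_voxels=face,
        terminal_voxels=face,
        anchor_point=vol.voxel_to_world(face.mean(axis=0)),
        center=vol.voxel_to_world(face.mean(axis=0)),
        long_axis=np.roll(n, 1),
        width_axis=np.roll(n, 2),
        normal=n,
        short_edge_midpoints=np.zeros((2, 3)),
    )
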
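"""Electrode pad + gel placement and the electrode geometry metrics.

Two placement modes mirror the two modelling pipelines being compared:

* ``artificial`` -- the pad and gel are draped at the planned anchor exactly,
  the way an automated pipeline places an idealized electrode from a virtual
  10-20 measurement.
* ``real`` -- the anchor is shifted tangentially (a systematic outward
  component plus Gaussian scatter), the pad is rotated about its normal, and
  the gel footprint is eroded or dilated by a random area multiplier.  This
  emulates the as-placed electrodes segmented from structural scans, which
  show wider scatter in contact area, separation and location than the
  idealized ones.

The pad and gel conform to the local scalp: within an oriented rectangular
footprint, gel occupies the first ``gel_thickness`` of space above the head
surface and the pad the next ``pad_thickness``.  Draping reproduces the
intended 35 cm^2 pad-scalp interface on a flat surface and the projected
footprint on curved scalps, with no gap between gel and skin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import PlacementError, ValidationError, ZeroContactError
from .phantom import BACKGROUND, GEL, PAD, SKIN, LabeledHeadVolume

# Named scalp anchors as unit directions from the head center, using
# +x right, +y anterior, +z superior.  Polar angle is measured from +z,
# azimuth from +y toward +/-x.  The F3/F4 analogs are placed so that the
# short-edge separation of two draped 70 mm pads on the default scalp
# is close to the idealized-montage value of ~4.7 cm.
_POLAR_DEG = 50.0
_AZIMUTH_DEG = 48.0


def _direction(polar_deg: float, azimuth_deg: float) -> np.ndarray:
    th = np.radians(polar_deg)
    az = np.radians(azimuth_deg)
    return np.array([np.sin(th) * np.sin(az), np.sin(th) * np.cos(az), np.cos(th)])


NAMED_ANCHORS: dict[str, np.ndarray] = {
    "F3": _direction(_POLAR_DEG, -_AZIMUTH_DEG),  # left frontal (cathode in the montage)
    "F4": _direction(_POLAR_DEG, +_AZIMUTH_DEG),  # right frontal (anode)
}


@dataclass(frozen=True)
class PerturbationSpec:
    """Real-mode placement scatter.

    ``outward_shift_mm`` is a systematic tangential displacement away from
    the head midline (as-placed pads sit farther apart than planned);
    ``tangential_shift_sd_mm`` adds isotropic tangential scatter;
    ``rotation_sd_deg`` rotates the pad about its normal; the gel footprint
    area is multiplied by a uniform draw from ``area_multiplier_range``
    (erosion below 1, paste smear above 1).
    """

    outward_shift_mm: float = 13.0
    tangential_shift_sd_mm: float = 5.0
    rotation_sd_deg: float = 10.0
    area_multiplier_range: tuple[float, float] = (0.90, 1.40)

    def validate(self) -> None:
        lo, hi = self.area_multiplier_range
        if not (0.0 < lo <= hi):
            raise ValidationError("area_multiplier_range must be positive and ordered")
        if self.tangential_shift_sd_mm < 0 or self.rotation_sd_deg < 0:
            raise ValidationError("perturbation scales must be >= 0")


@dataclass(frozen=True)
class ElectrodeSpec:
    """One pad electrode to be placed on a head volume."""

    role: str  # "anode" | "cathode"
    anchor: object  # named position ("F3"/"F4"), unit direction, or world point
    pad_length_mm: float = 70.0
    pad_width_mm: float = 50.0
    pad_thickness_mm: float = 3.0
    gel_thickness_mm: float = 3.0
    mode: str = "artificial"  # "artificial" | "real"
    perturbation: PerturbationSpec = field(default_factory=PerturbationSpec)
    seed: int = 0

    def validate(self) -> None:
        if self.role not in ("anode", "cathode"):
            raise ValidationError(f"unknown electrode role {self.role!r}")
        if self.mode not in ("artificial", "real"):
            raise ValidationError(f"unknown electrode mode {self.mode!r}")
        if not (self.pad_length_mm >= self.pad_width_mm > 0):
            raise ValidationError("pad dimensions must satisfy length >= width > 0")
        if self.pad_thickness_mm <= 0 or self.gel_thickness_mm <= 0:
            raise ValidationError("pad and gel thicknesses must be positive")
        self.perturbation.validate()


@dataclass
class ElectrodeGeometry:
    """Placed pad + gel voxel sets and the oriented-box parameters."""

    role: str
    pad_voxels: np.ndarray  # (N, 3) int voxel indices
    gel_voxels: np.ndarray
    terminal_voxels: np.ndarray  # outer pad layer where current is applied
    anchor_point: np.ndarray  # world point on the scalp surface
    center: np.ndarray  # world centroid of the pad
    long_axis: np.ndarray
    width_axis: np.ndarray
    normal: np.ndarray
    short_edge_midpoints: np.ndarray  # (2, 3) world points on scalp-facing face


@dataclass
class ElectrodeProperties:
    """Per-pair geometric summary used by the comparison analysis."""

    contact_area_anode_cm2: float
    contact_area_cathode_cm2: float
    separation_distance_cm: float


def _tangent_basis(n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal tangent vectors at surface normal ``n``.

    The first vector is the azimuthal direction pointing toward the head
    midline plane (x = 0): pads are oriented with their long axis running
    toward the opposite electrode across the forehead.
    """
    z = np.array([0.0, 0.0, 1.0])
    east = np.cross(z, n)
    if np.linalg.norm(east) < 1e-9:
        east = np.array([1.0, 0.0, 0.0])
    east /= np.linalg.norm(east)
    # east = (-n_y, n_x, 0): for a right-side anchor (n_x > 0) it already
    # points toward the midline plane, for a left-side one flip it
    sign = np.sign(n[0]) if abs(n[0]) > 1e-12 else 1.0
    long_axis = sign * east
    width_axis = np.cross(n, long_axis)
    return long_axis, width_axis


def resolve_anchor_direction(vol: LabeledHeadVolume, anchor) -> np.ndarray:
    """Turn a named position, unit direction, or world point into a unit direction."""
    if isinstance(anchor, str):
        try:
            return NAMED_ANCHORS[anchor].copy()
        except KeyError as exc:
            raise ValidationError(f"unknown named anchor {anchor!r}") from exc
    v = np.asarray(anchor, dtype=float)
    if v.shape != (3,):
        raise ValidationError("anchor must be a name or a 3-vector")
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValidationError("anchor vector must be non-zero")
    if abs(norm - 1.0) < 0.5:  # already (close to) a unit direction
        return v / norm
    center = _head_center(vol)
    d = v - center
    if np.linalg.norm(d) == 0:
        raise ValidationError("anchor point coincides with head center")
    return d / np.linalg.norm(d)


def _head_center(vol: LabeledHeadVolume) -> np.ndarray:
    idx = np.argwhere(vol.head_mask)
    if idx.size == 0:
        raise ValidationError("volume contains no head tissue")
    return vol.voxel_to_world(idx.mean(axis=0))


def _surface_point(vol: LabeledHeadVolume, center: np.ndarray, direction: np.ndarray):
    """March inward along a ray to the outermost head voxel; returns world point."""
    h = vol.voxel_size_mm
    max_t = float(np.max(np.array(vol.shape) * h))
    labels = vol.labels
    for t in np.arange(max_t, 0.0, -h / 4.0):
        p = center + direction * t
        ijk = np.round((p - vol.origin) / h).astype(int)
        if np.any(ijk < 0) or np.any(ijk >= np.array(vol.shape)):
            continue
        lab = labels[tuple(ijk)]
        if lab in (GEL, PAD):
            raise PlacementError("anchor site already occupied by an electrode")
        if lab != BACKGROUND:
            if lab != SKIN:
                raise ValidationError(
                    f"anchor direction hits {lab} (not scalp) at {p}"
                )
            return vol.voxel_to_world(ijk)
    raise ValidationError("anchor ray does not intersect the head")


def place_electrode(
    vol: LabeledHeadVolume, spec: ElectrodeSpec
) -> tuple[LabeledHeadVolume, ElectrodeGeometry]:
    """Drape a pad + gel on the scalp and return the updated volume and geometry.

    The input volume is not modified; the returned copy carries gel (label 6)
    and pad (label 7) voxels.  Placement is deterministic given the spec and
    its seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h = vol.voxel_size_mm
    center = _head_center(vol)
    d = resolve_anchor_direction(vol, spec.anchor)

    area_mult = 1.0
    rotation = 0.0
    if spec.mode == "real":
        pert = spec.perturbation
        # tangential displacement: systematic outward (away from midline) + scatter
        l0, w0 = _tangent_basis(d)
        outward = -l0  # l0 points toward the midline
        sd = pert.tangential_shift_sd_mm
        u1, u2 = np.clip(rng.normal(0.0, sd, 2), -2 * sd, 2 * sd) if sd > 0 else (0.0, 0.0)
        disp = outward * pert.outward_shift_mm + l0 * u1 + w0 * u2
        r_anchor = np.linalg.norm(_surface_point(vol, center, d) - center)
        d = d * r_anchor + disp
        d /= np.linalg.norm(d)
        rot_sd = pert.rotation_sd_deg
        rotation = np.radians(
            np.clip(rng.normal(0.0, rot_sd), -2 * rot_sd, 2 * rot_sd) if rot_sd > 0 else 0.0
        )
        area_mult = rng.uniform(*pert.area_multiplier_range)

    p = _surface_point(vol, center, d)
    n = d / np.linalg.norm(d)  # outward normal = anchor ray direction
    long_axis, width_axis = _tangent_basis(n)
    if rotation != 0.0:
        c, s = np.cos(rotation), np.sin(rotation)
        long_axis, width_axis = (
            c * long_axis + s * width_axis,
            -s * long_axis + c * width_axis,
        )

    gel_t = spec.gel_thickness_mm
    pad_t = spec.pad_thickness_mm
    half_l, half_w = spec.pad_length_mm / 2.0, spec.pad_width_mm / 2.0
    scale = np.sqrt(area_mult)

    # local box around the anchor; distances to the head surface are local
    margin_mm = max(half_l, half_w) + gel_t + pad_t + 6 * h
    lo = np.floor((p - margin_mm - vol.origin) / h).astype(int)
    hi = np.ceil((p + margin_mm - vol.origin) / h).astype(int) + 1
    lo = np.clip(lo, 0, np.array(vol.shape))
    hi = np.clip(hi, 0, np.array(vol.shape))
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))

    sub_labels = vol.labels[sl]
    sub_head = (sub_labels >= 1) & (sub_labels <= 5)
    if not sub_head.any():
        raise PlacementError("no head tissue near the anchor")
    dist = ndimage.distance_transform_edt(~sub_head, sampling=h)

    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    pos = np.stack([ii, jj, kk], axis=-1) * h + vol.origin
    rel = pos - p
    a = rel @ long_axis
    b = rel @ width_axis
    c = rel @ n

    # stay on the anchor-side surface: allow the footprint to drop below the
    # tangent plane by the sagitta of a curved scalp, but never wrap to the
    # far side of a thin structure
    c_min = -(0.5 * max(half_l, half_w) + h)
    on_side = c > c_min

    in_pad_fp = (np.abs(a) <= half_l) & (np.abs(b) <= half_w) & on_side
    in_gel_fp = (np.abs(a) <= half_l * scale) & (np.abs(b) <= half_w * scale) & on_side
    eps = 1e-9
    # bands are clamped to at least one voxel layer on coarse grids
    gel_top = max(gel_t, h)
    pad_top = gel_top + max(pad_t, h)
    gel_sel = in_gel_fp & (dist > eps) & (dist <= gel_top + eps)
    pad_sel = in_pad_fp & (dist > gel_top + eps) & (dist <= pad_top + eps)

    occupied = np.isin(sub_labels, (GEL, PAD))
    if np.any((gel_sel | pad_sel) & occupied):
        raise PlacementError("pad/gel footprint overlaps an existing electrode")
    gel_sel &= sub_labels == BACKGROUND
    pad_sel &= sub_labels == BACKGROUND
    if not pad_sel.any() or not gel_sel.any():
        raise PlacementError("pad or gel footprint produced no voxels")

    # drop electrode voxels not face-connected to the head through gel/pad:
    # isolated staircase islands would be floating conductors in the solve
    elec = gel_sel | pad_sel
    comp, _ = ndimage.label(elec | sub_head)
    head_comp = np.unique(comp[sub_head])
    keep = np.isin(comp, head_comp) & elec
    gel_sel &= keep
    pad_sel &= keep
    if not pad_sel.any() or not gel_sel.any():
        raise PlacementError("pad/gel not connected to the scalp")

    out = vol.copy()
    sub_out = out.labels[sl]
    sub_out[gel_sel] = GEL
    sub_out[pad_sel] = PAD

    def _to_global(sel):
        loc = np.argwhere(sel)
        return loc + lo

    pad_voxels = _to_global(pad_sel)
    gel_voxels = _to_global(gel_sel)

    # terminal: outermost pad layer (current is applied on the pad's far face)
    pad_dist = dist[pad_sel]
    term_sel = pad_sel & (dist > pad_top - h + eps)
    if not term_sel.any():
        term_sel = pad_sel & (dist >= pad_dist.max() - eps)
    terminal_voxels = _to_global(term_sel)

    # short-edge midpoints on the scalp-facing pad face
    face_sel = pad_sel & (dist <= gel_top + h + eps)
    if not face_sel.any():
        face_sel = pad_sel
    face_pos = (np.argwhere(face_sel) + lo) * h + vol.origin
    face_a = (face_pos - p) @ long_axis
    midpoints = []
    for pick in (face_a >= face_a.max() - h / 2, face_a <= face_a.min() + h / 2):
        midpoints.append(face_pos[pick].mean(axis=0))
    pad_pos = pad_voxels * h + vol.origin

    geom = ElectrodeGeometry(
        role=spec.role,
        pad_voxels=pad_voxels,
        gel_voxels=gel_voxels,
        terminal_voxels=terminal_voxels,
        anchor_point=p,
        center=pad_pos.mean(axis=0),
        long_axis=long_axis,
        width_axis=width_axis,
        normal=n,
        short_edge_midpoints=np.array(midpoints),
    )
    return out, geom


_FACE_SHIFTS = [
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
]


def compute_contact_area(vol: LabeledHeadVolume, geom: ElectrodeGeometry) -> float:
    """Gel-skin interface area in cm^2, counted over 6-connected voxel faces."""
    if geom.gel_voxels.size == 0:
        raise ZeroContactError("electrode has no gel voxels")
    gel = np.zeros(vol.shape, dtype=bool)
    gel[geom.gel_voxels[:, 0], geom.gel_voxels[:, 1], geom.gel_voxels[:, 2]] = True
    skin = vol.labels == SKIN
    faces = 0
    for dx, dy, dz in _FACE_SHIFTS:
        shifted = np.roll(skin, (dx, dy, dz), axis=(0, 1, 2))
        # zero the wrapped border
        if dx:
            shifted[0 if dx == 1 else -1, :, :] = False
        if dy:
            shifted[:, 0 if dy == 1 else -1, :] = False
        if dz:
            shifted[:, :, 0 if dz == 1 else -1] = False
        faces += int(np.count_nonzero(gel & shifted))
    if faces == 0:
        raise ZeroContactError("gel does not touch the skin")
    return faces * vol.voxel_size_mm**2 / 100.0


def normalize_contact_areas(
    areas_artificial: np.ndarray, areas_real: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Normalize contact areas by the artificial-model mean area.

    ``areas_artificial`` and ``areas_real`` are (n_subjects, 2) arrays of
    anode/cathode contact areas.  Every area in both models is divided by the
    mean over all artificial areas; the per-subject value is the mean of the
    subject's normalized anode and cathode areas.  By construction the mean
    normalized artificial value is exactly 1.

    Returns (per-subject artificial values, per-subject real values,
    artificial mean area).
    """
    art = np.asarray(areas_artificial, dtype=float)
    real = np.asarray(areas_real, dtype=float)
    if art.size == 0:
        raise ValidationError("artificial area set is empty")
    if np.any(art <= 0) or np.any(real <= 0):
        raise ValidationError("contact areas must be positive")
    mean_art = art.mean()
    return art.mean(axis=-1) / mean_art, real.mean(axis=-1) / mean_art, float(mean_art)


def compute_separation_distance(
    geom_anode: ElectrodeGeometry, geom_cathode: ElectrodeGeometry
) -> float:
    """Euclidean distance (cm) between facing short-edge midpoints.

    For each electrode the short-edge midpoint nearest the other electrode's
    center is selected; ties break toward the more anterior (larger y)
    midpoint.
    """
    def _pick(geom: ElectrodeGeometry, other_center: np.ndarray) -> np.ndarray:
        mids = geom.short_edge_midpoints
        dist = np.linalg.norm(mids - other_center, axis=1)
        if abs(dist[0] - dist[1]) < 1e-9:
            return mids[np.argmax(mids[:, 1])]
        return mids[np.argmin(dist)]

    m_a = _pick(geom_anode, geom_cathode.center)
    m_c = _pick(geom_cathode, geom_anode.center)
    return float(np.linalg.norm(m_a - m_c)) / 10.0
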
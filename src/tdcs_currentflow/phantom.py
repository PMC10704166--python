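"""Voxelized multi-shell head phantoms with parameterized brain atrophy.

A phantom is a concentric (optionally ellipsoidal) set of tissue shells on a
regular isotropic grid: a white-matter core wrapped in a gray-matter shell,
surrounded by CSF, bone and skin.  Atrophy is modelled by shrinking the brain
(GM+WM) outer radius while the skull and scalp stay fixed, so the vacated
space fills with CSF -- the thickening CSF layer is what shunts injected
current away from the brain in older heads.  An optional central "ventricle"
ellipsoid of CSF inside the white matter grows as atrophy increases,
mimicking enlarged lateral ventricles.

Label codes follow a fixed convention shared across the package::

    0 background/air, 1 WM, 2 GM, 3 CSF, 4 bone, 5 skin, 6 gel, 7 pad
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GeometryError, ValidationError

BACKGROUND = 0
WM = 1
GM = 2
CSF = 3
BONE = 4
SKIN = 5
GEL = 6
PAD = 7

#: labels that are head tissue (electrode materials excluded)
TISSUE_LABELS = (WM, GM, CSF, BONE, SKIN)

LABEL_NAMES = {
    BACKGROUND: "background",
    WM: "white_matter",
    GM: "gray_matter",
    CSF: "csf",
    BONE: "bone",
    SKIN: "skin",
    GEL: "gel",
    PAD: "pad",
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic head.

    ``shell_radii_mm`` are the outer radii of (scalp, skull, inner-skull/CSF,
    brain), strictly decreasing.  ``atrophy_scale`` in (0, 1] multiplies the
    brain outer radius; CSF fills the vacated gap.  ``axis_scales`` stretch
    the whole geometry per axis to break spherical symmetry.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size_mm: float = 2.0
    shell_radii_mm: tuple[float, float, float, float] = (77.0, 70.0, 64.0, 58.0)
    atrophy_scale: float = 1.0
    gm_thickness_mm: float = 4.0
    ventricle_radius_mm: float = 12.0
    axis_scales: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def validate(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValidationError("voxel_size_mm must be positive")
        r = self.shell_radii_mm
        if len(r) != 4 or any(a <= b for a, b in zip(r, r[1:])):
            raise ValidationError(
                "shell_radii_mm must be strictly decreasing scalp > skull > CSF > brain"
            )
        if not (0.0 < self.atrophy_scale <= 1.0):
            raise ValidationError("atrophy_scale must lie in (0, 1]")
        if self.gm_thickness_mm <= 0:
            raise ValidationError("gm_thickness_mm must be positive")
        if self.ventricle_radius_mm < 0:
            raise ValidationError("ventricle_radius_mm must be >= 0")
        if any(s <= 0 for s in self.axis_scales):
            raise ValidationError("axis_scales must be positive")
        if len(self.grid_shape) != 3 or any(n < 8 for n in self.grid_shape):
            raise ValidationError("grid_shape must be three dimensions of at least 8")


@dataclass
class LabeledHeadVolume:
    """Integer tissue-label grid with isotropic voxel spacing.

    ``origin`` is the world coordinate (mm) of the center of voxel (0,0,0);
    world coordinates are ``origin + index * voxel_size_mm``.
    """

    labels: np.ndarray
    voxel_size_mm: float
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("labels must be an integer array")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag([self.voxel_size_mm] * 3)
        aff[:3, 3] = self.origin
        return aff

    @property
    def head_mask(self) -> np.ndarray:
        """Boolean mask of head tissue voxels (labels 1..5)."""
        return (self.labels >= WM) & (self.labels <= SKIN)

    def copy(self) -> "LabeledHeadVolume":
        return LabeledHeadVolume(self.labels.copy(), self.voxel_size_mm, self.origin.copy())

    def world_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates (mm) of voxel centers, broadcastable."""
        ax = [
            (self.origin[i] + self.voxel_size_mm * np.arange(self.shape[i]))
            for i in range(3)
        ]
        return (
            ax[0][:, None, None],
            ax[1][None, :, None],
            ax[2][None, None, :],
        )

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(ijk, dtype=float) * self.voxel_size_mm

    def counts(self) -> dict[int, int]:
        vals, cnt = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, cnt)}


@dataclass(frozen=True)
class RoiSectorConfig:
    """Angular sector bounds (degrees / direction cosines) for the ROI analogs.

    Sectors are measured from the inter-electrode midline direction; the four
    ROI analogs occupy disjoint angular bands, so the masks are disjoint by
    construction.
    """

    sfg_max_deg: float = 25.0
    mfg_max_deg: float = 45.0
    ifg_max_deg: float = 65.0
    ifg_z_max: float = 0.45
    temporal_min_deg: float = 75.0
    temporal_lateral_min: float = 0.45
    temporal_z_max: float = 0.30
    temporal_y_max: float = 0.25


@dataclass
class RoiMaskSet:
    """Named boolean masks on the phantom grid."""

    sfg_analog: np.ndarray
    mfg_analog: np.ndarray
    ifg_analog: np.ndarray
    temporal_analog: np.ndarray
    brain: np.ndarray
    gm: np.ndarray
    wm: np.ndarray
    whole_head: np.ndarray

    ROI_NAMES = ("sfg_analog", "mfg_analog", "ifg_analog", "temporal_analog")
    REGION_NAMES = ("whole_head", "brain", "gm", "wm") + ROI_NAMES

    def as_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in self.REGION_NAMES}


def _normalized_radius(vol_shape, origin, voxel_size, axis_scales):
    ax = [
        (origin[i] + voxel_size * np.arange(vol_shape[i])) / axis_scales[i]
        for i in range(3)
    ]
    return np.sqrt(
        ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2
    )


def generate_phantom(spec: PhantomSpec) -> LabeledHeadVolume:
    """Rasterize the concentric-shell head described by ``spec``.

    A voxel belongs to the innermost shell containing its center (center-in
    test), which makes the construction orientation-free and deterministic.
    """
    spec.validate()
    shape = tuple(spec.grid_shape)
    h = spec.voxel_size_mm
    origin = -(np.array(shape, dtype=float) - 1.0) / 2.0 * h

    half_extent = np.array(shape) * h / 2.0
    r_scalp = spec.shell_radii_mm[0]
    if any(r_scalp * s > e for s, e in zip(spec.axis_scales, half_extent)):
        raise GeometryError(
            f"scalp shell (radius {r_scalp} mm, axis_scales {spec.axis_scales}) "
            f"exceeds grid half-extent {tuple(half_extent)} mm"
        )

    rho = _normalized_radius(shape, origin, h, spec.axis_scales)
    r_scalp, r_skull, r_csf, r_brain = spec.shell_radii_mm
    brain_outer = r_brain * spec.atrophy_scale
    wm_outer = brain_outer - spec.gm_thickness_mm
    if wm_outer <= 0:
        raise ValidationError("gm_thickness_mm leaves no white-matter core")

    labels = np.zeros(shape, dtype=np.int16)
    labels[rho <= r_scalp] = SKIN
    labels[rho <= r_skull] = BONE
    labels[rho <= r_csf] = CSF
    labels[rho <= brain_outer] = GM
    labels[rho <= wm_outer] = WM

    if spec.ventricle_radius_mm > 0:
        # ventricle grows as atrophy deepens; kept strictly inside the WM core
        vr = min(spec.ventricle_radius_mm / spec.atrophy_scale, wm_outer - 2 * h)
        if vr > 0:
            labels[(rho <= vr) & (labels == WM)] = CSF

    return LabeledHeadVolume(labels, h, origin)


def generate_cohort(
    n: int,
    atrophy_range: tuple[float, float] = (0.86, 1.0),
    jitter: float = 0.02,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
) -> list[tuple[PhantomSpec, LabeledHeadVolume]]:
    """Generate ``n`` phantoms whose atrophy scales span ``atrophy_range``.

    Atrophy scales are evenly spaced across the range plus seeded jitter;
    head size (all shell radii) and per-axis ellipticity receive small
    multiplicative jitter to emulate inter-individual anatomy.  ``jitter`` is
    the fractional standard deviation of those multipliers (0 disables all
    randomness).
    """
    if n < 2:
        raise ValidationError("cohort size must be at least 2")
    lo, hi = atrophy_range
    if not (0.0 < lo < hi <= 1.0):
        raise ValidationError("atrophy_range must be a non-empty interval within (0, 1]")
    if jitter < 0:
        raise ValidationError("jitter must be >= 0")

    rng = np.random.default_rng(seed)
    base = np.linspace(lo, hi, n)
    spacing = (hi - lo) / (n - 1)
    # evenly spaced plus seeded jitter; |jitter shift| < spacing/2 keeps values distinct
    shift = rng.uniform(-0.45, 0.45, size=n) * spacing if jitter > 0 else np.zeros(n)
    atrophy = np.clip(base + shift, lo, hi)

    default = base_spec or PhantomSpec()
    cohort: list[tuple[PhantomSpec, LabeledHeadVolume]] = []
    for i in range(n):
        size_mult = 1.0 + rng.normal(0.0, jitter)
        axes = 1.0 + rng.normal(0.0, jitter / 2.0, size=3)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(
            default,
            shell_radii_mm=tuple(r * size_mult for r in default.shell_radii_mm),
            atrophy_scale=float(atrophy[i]),
            axis_scales=tuple(np.clip(axes, 0.9, 1.1)),
            seed=sub_seed,
        )
        cohort.append((spec, generate_phantom(spec)))
    return cohort


def compute_volume_ratio(vol: LabeledHeadVolume) -> float:
    """Brain volume ratio (GM+WM) / (GM+WM+CSF) from voxel counts.

    The ratio is the inverse proxy for atrophy: smaller values mean more CSF
    relative to brain parenchyma.
    """
    c = vol.counts()
    n_brain = c.get(GM, 0) + c.get(WM, 0)
    n_icv = n_brain + c.get(CSF, 0)
    if n_icv == 0:
        raise ValidationError("volume contains no intracranial voxels")
    return n_brain / n_icv


def _brain_directions(vol: LabeledHeadVolume, brain: np.ndarray):
    idx = np.argwhere(brain)
    pos = vol.voxel_to_world(idx)
    center = pos.mean(axis=0)
    u = pos - center
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    return idx, u, center


def define_roi_masks(
    vol: LabeledHeadVolume,
    anode_anchor: np.ndarray,
    cathode_anchor: np.ndarray,
    sectors: RoiSectorConfig | None = None,
) -> RoiMaskSet:
    """Angular-sector ROI analogs relative to the inter-electrode midline.

    ``anode_anchor`` / ``cathode_anchor`` are world points on the scalp.  The
    superior-frontal analog is the cap of brain tissue around the midline
    between the electrodes; middle- and inferior-frontal analogs are
    successively more lateral/inferior frontal bands; the temporal analog is
    the lateral sector posterior-inferior to the electrodes (a non-target
    control region).
    """
    sectors = sectors or RoiSectorConfig()
    labels = vol.labels
    gm = labels == GM
    wm = labels == WM
    brain = gm | wm
    whole_head = vol.head_mask
    if not brain.any():
        raise ValidationError("volume contains no brain voxels")

    idx, u, center = _brain_directions(vol, brain)
    a_dir = np.asarray(anode_anchor, dtype=float) - center
    c_dir = np.asarray(cathode_anchor, dtype=float) - center
    na, nc = np.linalg.norm(a_dir), np.linalg.norm(c_dir)
    if na == 0 or nc == 0 or np.linalg.norm(a_dir / na - c_dir / nc) < 1e-9:
        raise ValidationError("electrode anchors are coincident")
    m = a_dir / na + c_dir / nc
    m /= np.linalg.norm(m)

    ang = np.degrees(np.arccos(np.clip(u @ m, -1.0, 1.0)))
    ux, uy, uz = u[:, 0], u[:, 1], u[:, 2]
    frontal = uy > 0

    sel = {
        "sfg_analog": ang < sectors.sfg_max_deg,
        "mfg_analog": (ang >= sectors.sfg_max_deg) & (ang < sectors.mfg_max_deg) & frontal,
        "ifg_analog": (
            (ang >= sectors.mfg_max_deg)
            & (ang < sectors.ifg_max_deg)
            & frontal
            & (uz < sectors.ifg_z_max)
        ),
        "temporal_analog": (
            (ang >= sectors.temporal_min_deg)
            & (np.abs(ux) > sectors.temporal_lateral_min)
            & (uz < sectors.temporal_z_max)
            & (uy < sectors.temporal_y_max)
        ),
    }

    masks = {}
    for name, cond in sel.items():
        mask = np.zeros(vol.shape, dtype=bool)
        chosen = idx[cond]
        mask[chosen[:, 0], chosen[:, 1], chosen[:, 2]] = True
        masks[name] = mask

    return RoiMaskSet(
        sfg_analog=masks["sfg_analog"],
        mfg_analog=masks["mfg_analog"],
        ifg_analog=masks["ifg_analog"],
        temporal_analog=masks["temporal_analog"],
        brain=brain,
        gm=gm,
        wm=wm,
        whole_head=whole_head,
    )
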
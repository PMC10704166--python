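"""Electrode placement, contact areas, normalization and separation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdcs_currentflow.electrodes import (
    ElectrodeGeometry,
    ElectrodeSpec,
    NAMED_ANCHORS,
    PerturbationSpec,
    _tangent_basis,
    compute_contact_area,
    compute_separation_distance,
    normalize_contact_areas,
    place_electrode,
)
from tdcs_currentflow.errors import PlacementError, ValidationError, ZeroContactError
from tdcs_currentflow.phantom import GEL, PAD, SKIN, PhantomSpec, generate_phantom

from conftest import make_slab

ZERO_PERT = PerturbationSpec(0.0, 0.0, 0.0, (1.0, 1.0))


def flat_slab(axis=2, h=2.0):
    """Skin slab with outward surface normal along +axis."""
    shape = [60, 60, 60]
    shape[axis] = 12
    return make_slab(tuple(shape), h, label=SKIN, pad_background=6)


def axis_spec(axis, **kw):
    d = np.zeros(3)
    d[axis] = 1.0
    return ElectrodeSpec(kw.pop("role", "anode"), d, **kw)


class TestPlacement:
    def test_flat_slab_full_contact_is_35_cm2(self):
        vol = flat_slab()
        v2, geom = place_electrode(vol, axis_spec(2, seed=0))
        assert compute_contact_area(v2, geom) == pytest.approx(35.0, abs=1e-9)

    def test_contact_area_invariant_under_axis_rotation(self):
        areas = []
        for axis in (0, 1, 2):
            vol = flat_slab(axis=axis)
            v2, geom = place_electrode(vol, axis_spec(axis, seed=0))
            areas.append(compute_contact_area(v2, geom))
        assert areas[0] == areas[1] == areas[2]

    def test_determinism_same_seed_same_voxels(self, small_phantom):
        spec = ElectrodeSpec("anode", "F4", mode="real", seed=11)
        _, g1 = place_electrode(small_phantom, spec)
        _, g2 = place_electrode(small_phantom, spec)
        assert np.array_equal(g1.pad_voxels, g2.pad_voxels)
        assert np.array_equal(g1.gel_voxels, g2.gel_voxels)

    def test_real_mode_coverage_erosion_scales_area(self):
        vol = flat_slab()
        pert = PerturbationSpec(0.0, 0.0, 0.0, (0.8, 0.8))
        v2, geom = place_electrode(
            vol, axis_spec(2, mode="real", perturbation=pert, seed=3)
        )
        area = compute_contact_area(v2, geom)
        # 0.8 * 35 = 28 cm^2, up to one voxel layer of footprint rounding
        assert area == pytest.approx(28.0, abs=2.5)

    def test_gel_adjacent_to_skin_or_pad(self, small_phantom):
        v2, geom = place_electrode(small_phantom, ElectrodeSpec("anode", "F4", seed=5))
        gel = np.zeros(v2.shape, dtype=bool)
        gel[tuple(geom.gel_voxels.T)] = True
        near = np.zeros(v2.shape, dtype=bool)
        other = (v2.labels == SKIN) | (v2.labels == PAD)
        for axis in range(3):
            for step in (1, -1):
                near |= np.roll(other, step, axis=axis)
        assert np.all(near[gel])

    def test_overlapping_pads_raise(self, small_phantom):
        v1, _ = place_electrode(small_phantom, ElectrodeSpec("anode", "F4", seed=0))
        with pytest.raises(PlacementError):
            place_electrode(v1, ElectrodeSpec("cathode", "F4", seed=1))

    def test_anchor_not_on_scalp_raises(self):
        # a bare gray-matter block has no skin for the anchor ray to land on
        from tdcs_currentflow.phantom import GM

        vol = make_slab((20, 20, 10), 2.0, label=GM, pad_background=4)
        with pytest.raises(ValidationError):
            place_electrode(vol, axis_spec(2, seed=0))

    def test_electrode_labels_written(self, small_phantom):
        v2, geom = place_electrode(small_phantom, ElectrodeSpec("anode", "F4", seed=0))
        assert np.all(v2.labels[tuple(geom.pad_voxels.T)] == PAD)
        assert np.all(v2.labels[tuple(geom.gel_voxels.T)] == GEL)
        # original tissue untouched
        changed = v2.labels != small_phantom.labels
        assert set(np.unique(v2.labels[changed])) <= {GEL, PAD}


class TestContactArea:
    def test_no_gel_raises(self):
        vol = flat_slab()
        geom = ElectrodeGeometry(
            role="anode", pad_voxels=np.zeros((0, 3), int),
            gel_voxels=np.zeros((0, 3), int), terminal_voxels=np.zeros((0, 3), int),
            anchor_point=np.zeros(3), center=np.zeros(3),
            long_axis=np.eye(3)[0], width_axis=np.eye(3)[1], normal=np.eye(3)[2],
            short_edge_midpoints=np.zeros((2, 3)),
        )
        with pytest.raises(ZeroContactError):
            compute_contact_area(vol, geom)

    def test_curved_scalp_consistent_under_refinement(self):
        """Face-counted area on a sphere agrees between 2 mm and 1 mm grids."""
        areas = {}
        for h in (2.0, 1.0):
            n = int(np.ceil(170.0 / h))
            spec = PhantomSpec(grid_shape=(n, n, n), voxel_size_mm=h,
                               ventricle_radius_mm=0.0)
            vol = generate_phantom(spec)
            v2, geom = place_electrode(vol, ElectrodeSpec("anode", "F4", seed=0))
            areas[h] = compute_contact_area(v2, geom)
        assert areas[1.0] == pytest.approx(areas[2.0], rel=0.10)


class TestNormalizeAreas:
    def test_hand_arithmetic_example(self):
        art = np.array([[30.0, 40.0]])
        real = np.array([[42.0, 28.0]])
        norm_art, norm_real, mean_art = normalize_contact_areas(art, real)
        assert mean_art == 35.0
        assert norm_art[0] == pytest.approx(1.0)
        assert norm_real[0] == pytest.approx(1.0)  # mean of 1.2 and 0.8
        assert (real / mean_art).ravel() == pytest.approx([1.2, 0.8])

    def test_all_equal_areas_normalize_to_one(self):
        art = np.full((4, 2), 42.0)
        norm_art, norm_real, _ = normalize_contact_areas(art, art)
        assert np.allclose(norm_art, 1.0) and np.allclose(norm_real, 1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(5.0, 80.0), min_size=2, max_size=32).filter(
            lambda v: len(v) % 2 == 0
        )
    )
    def test_artificial_mean_is_identically_one(self, flat_areas):
        art = np.array(flat_areas).reshape(-1, 2)
        norm_art, _, _ = normalize_contact_areas(art, art * 1.1)
        assert np.mean(norm_art) == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_area_raises(self):
        with pytest.raises(ValidationError):
            normalize_contact_areas(np.array([[0.0, 1.0]]), np.array([[1.0, 1.0]]))


class TestSeparation:
    def _geom(self, midpoints, center):
        return ElectrodeGeometry(
            role="anode", pad_voxels=np.zeros((1, 3), int),
            gel_voxels=np.zeros((1, 3), int), terminal_voxels=np.zeros((1, 3), int),
            anchor_point=np.asarray(center, float), center=np.asarray(center, float),
            long_axis=np.eye(3)[0], width_axis=np.eye(3)[1], normal=np.eye(3)[2],
            short_edge_midpoints=np.asarray(midpoints, float),
        )

    def test_coincident_midpoints_give_zero(self):
        g1 = self._geom([[0, 0, 0], [10, 0, 0]], [5, 0, 0])
        g2 = self._geom([[0, 0, 0], [-10, 0, 0]], [-5, 0, 0])
        assert compute_separation_distance(g1, g2) == 0.0

    def test_three_four_five_triangle(self):
        g1 = self._geom([[0, 0, 0], [-50, 0, 0]], [-25, 0, 0])
        g2 = self._geom([[30, 40, 0], [80, 40, 0]], [55, 40, 0])
        assert compute_separation_distance(g1, g2) == pytest.approx(5.0)

    def test_sphere_montage_matches_chord_oracle(self, default_phantom):
        """Placed separation matches the analytic chord between edge midpoints."""
        v1, ga = place_electrode(default_phantom, ElectrodeSpec("anode", "F4", seed=1))
        v2, gc = place_electrode(v1, ElectrodeSpec("cathode", "F3", seed=2))
        sep = compute_separation_distance(ga, gc)

        h = default_phantom.voxel_size_mm
        r_face = 77.0 + 3.0 + h / 2.0  # scalp radius + gel band + half voxel
        arc = np.arcsin(35.0 / r_face)
        mids = []
        for name in ("F4", "F3"):
            d = NAMED_ANCHORS[name]
            l, _ = _tangent_basis(d)
            mids.append(r_face * (np.cos(arc) * d + np.sin(arc) * l))
        predicted = np.linalg.norm(mids[0] - mids[1]) / 10.0
        assert sep == pytest.approx(predicted, abs=2 * h / 10.0)


class TestCohortSpread:
    def test_real_mode_wider_than_artificial(self, small_phantom):
        """Idealized placement is tighter than as-placed placement."""
        rng = np.random.default_rng(0)
        seps = {"artificial": [], "real": []}
        areas = {"artificial": [], "real": []}
        for i in range(8):
            seeds = rng.integers(0, 2**31 - 1, 4)
            for mode, (s1, s2) in (("artificial", seeds[:2]), ("real", seeds[2:])):
                v1, ga = place_electrode(
                    small_phantom, ElectrodeSpec("anode", "F4", mode=mode, seed=int(s1))
                )
                v2, gc = place_electrode(
                    v1, ElectrodeSpec("cathode", "F3", mode=mode, seed=int(s2))
                )
                seps[mode].append(compute_separation_distance(ga, gc))
                areas[mode].append(
                    compute_contact_area(v2, ga) + compute_contact_area(v2, gc)
                )
        assert np.var(seps["artificial"]) < np.var(seps["real"])
        assert np.var(areas["artificial"]) < np.var(areas["real"])
        assert np.mean(seps["real"]) > np.mean(seps["artificial"])
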
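"""Voxel morphometrics: surface/volume, ECS correction, coverage, selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calfluct.geometry import (
    EmptySegmentError,
    LabelVolume,
    SynapseRecord,
    apply_ecs_correction,
    astro_surface_area_volume,
    compartment_fractions,
    select_synapses,
    synaptic_coverage,
)
from calfluct.synthetic import make_slab_fixture


def brute_force_surface_area(vol: LabelVolume, role: str) -> float:
    """Independent oracle: loop over every voxel and its 6 faces."""
    m = vol.mask(role)
    dx, dy, dz = vol.pitch_nm
    face = {0: dy * dz, 1: dx * dz, 2: dx * dy}
    nx, ny, nz = m.shape
    area = 0.0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not m[x, y, z]:
                    continue
                for axis, (ox, oy, oz) in enumerate(
                    [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
                ):
                    for s in (+1, -1):
                        nxx, nyy, nzz = x + s * ox, y + s * oy, z + s * oz
                        if 0 <= nxx < nx and 0 <= nyy < ny and 0 <= nzz < nz:
                            if not m[nxx, nyy, nzz]:
                                area += face[axis]
                        # sample-boundary faces are not surface
    return area * 1e-6  # um^2


class TestSurfaceVolume:
    @pytest.mark.parametrize("thickness,expected_svr", [(60, 2000 / 60), (90, 2000 / 90), (600, 2000 / 600)])
    def test_slab_closed_form(self, thickness, expected_svr):
        vol = make_slab_fixture(thickness)
        _, _, svr = astro_surface_area_volume(vol)
        assert svr == pytest.approx(expected_svr, rel=1e-12)

    def test_single_voxel_closed_form(self):
        labels = np.zeros((5, 5, 5), dtype=np.int16)
        labels[2, 2, 2] = 1
        vol = LabelVolume(labels, (6, 6, 30), {0: "ecs", 1: "astro"})
        area, volume, svr = astro_surface_area_volume(vol)
        # 2*(6*6) + 4*(6*30) = 792 nm^2; 6*6*30 = 1080 nm^3
        assert area == pytest.approx(792e-6)
        assert volume == pytest.approx(1080e-9)
        assert svr == pytest.approx(792 / 1080 * 1000)

    def test_random_blob_matches_brute_force(self, two_phase_volume):
        area, volume, svr = astro_surface_area_volume(two_phase_volume)
        oracle = brute_force_surface_area(two_phase_volume, "astro")
        assert area == pytest.approx(oracle, rel=1e-12)
        n = int(two_phase_volume.mask("astro").sum())
        assert volume == pytest.approx(n * 1080e-9)

    def test_sphere_svr_converges_to_staircase_limit(self):
        # Face counting overestimates a smooth surface by the staircase
        # factor 3/2 (mean of |nx|+|ny|+|nz| over the sphere), so the
        # voxel estimator converges to (3/2) * 3/r, not 3/r.  Axis-aligned
        # sheets (the leaflet case) are exact; see the slab tests.
        pitch = 6.0
        for r_vox in (10, 14):
            r = r_vox * pitch
            n = 2 * r_vox + 5
            x = (np.arange(n) - n // 2) * pitch
            X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
            labels = ((X**2 + Y**2 + Z**2) <= r**2).astype(np.int16)
            vol = LabelVolume(labels, (pitch,) * 3, {0: "ecs", 1: "astro"})
            _, _, svr = astro_surface_area_volume(vol)
            assert svr == pytest.approx(1.5 * 3.0 / r * 1000, rel=0.15)

    def test_empty_astro_raises(self):
        vol = LabelVolume(np.zeros((4, 4, 4), dtype=np.int16), (6, 6, 30), {0: "ecs", 1: "astro"})
        with pytest.raises(EmptySegmentError):
            astro_surface_area_volume(vol)


class TestEcsCorrection:
    def test_pure_ecs_unchanged(self):
        vol = LabelVolume(np.zeros((8, 8, 4), dtype=np.int16), (6, 6, 30), {0: "ecs", 1: "astro"})
        out = apply_ecs_correction(vol)
        assert np.array_equal(out.labels, vol.labels)

    def test_slab_erodes_by_one_voxel_each_side(self):
        # 5-voxel-wide slab (in x) spanning y/z -> 3 voxels after 6 nm shrink
        labels = np.zeros((11, 9, 4), dtype=np.int16)
        labels[3:8, :, :] = 1
        vol = LabelVolume(labels, (6, 6, 30), {0: "ecs", 1: "astro"})
        before_ecs = int((vol.labels == 0).sum())
        out = apply_ecs_correction(vol, shrink_nm=6)
        assert out.labels[4:7, :, :].all()
        assert not out.labels[3, :, :].any() and not out.labels[7, :, :].any()
        # ECS gain equals the eroded shell: 2 faces * 9 * 4 voxels
        after_ecs = int((out.labels == 0).sum())
        assert after_ecs - before_ecs == 2 * 9 * 4

    def test_brute_force_neighborhood_oracle(self, two_phase_volume):
        out = apply_ecs_correction(two_phase_volume, shrink_nm=6)
        m = two_phase_volume.mask("astro")
        # oracle: astro voxel survives iff all in-plane 4-neighbors are
        # astro (or lie on the sample boundary)
        nx, ny, nz = m.shape
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    if not m[x, y, z]:
                        continue
                    keep = True
                    for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        xx, yy = x + dx, y + dy
                        if 0 <= xx < nx and 0 <= yy < ny and not m[xx, yy, z]:
                            keep = False
                    assert bool(out.labels[x, y, z] == 1) == keep

    def test_no_relabel_between_cells_and_monotone_ecs(self):
        labels = np.zeros((12, 12, 3), dtype=np.int16)
        labels[2:6, 2:10, :] = 1
        labels[6:10, 2:10, :] = 2  # face-adjacent distinct segment
        vol = LabelVolume(labels, (6, 6, 30), {0: "ecs", 1: "astro", 2: "bouton"})
        out = apply_ecs_correction(vol)
        ecs_before = compartment_fractions(vol)["ecs"]
        ecs_after = compartment_fractions(out)["ecs"]
        assert ecs_after > ecs_before  # strict: two segments touched
        changed = vol.labels != out.labels
        assert np.all(out.labels[changed] == 0)  # only relabelled to ECS

    def test_incommensurate_shrink_rejected(self):
        vol = LabelVolume(np.zeros((4, 4, 4), dtype=np.int16), (6, 6, 30), {0: "ecs"})
        with pytest.raises(ValueError, match="multiple of the in-plane"):
            apply_ecs_correction(vol, shrink_nm=7)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_ecs_fraction_never_decreases(self, seed):
        gen = np.random.default_rng(seed)
        labels = gen.integers(0, 4, size=(9, 9, 4)).astype(np.int16)
        vol = LabelVolume(
            labels, (6, 6, 30), {0: "ecs", 1: "astro", 2: "bouton", 3: "spine"}
        )
        out = apply_ecs_correction(vol)
        assert compartment_fractions(out)["ecs"] >= compartment_fractions(vol)["ecs"]


class TestFractions:
    def test_half_ecs(self):
        labels = np.zeros((4, 4, 4), dtype=np.int16)
        labels[:2] = 1
        vol = LabelVolume(labels, (6, 6, 30), {0: "ecs", 1: "astro"})
        assert compartment_fractions(vol)["ecs"] == pytest.approx(0.5)

    def test_uniform_astro(self):
        labels = np.ones((4, 4, 4), dtype=np.int16)
        vol = LabelVolume(labels, (6, 6, 30), {0: "ecs", 1: "astro"})
        f = compartment_fractions(vol)
        assert f["astro"] == 1.0 and f["ecs"] == 0.0

    def test_fractions_sum_to_one_and_match_counts(self, rng):
        labels = rng.integers(0, 5, size=(10, 10, 5)).astype(np.int16)
        label_map = {0: "ecs", 1: "astro", 2: "bouton", 3: "spine", 4: "other"}
        vol = LabelVolume(labels, (6, 6, 30), label_map)
        f = compartment_fractions(vol)
        assert sum(f.values()) == pytest.approx(1.0)
        for i, role in label_map.items():
            assert f[role] == pytest.approx((labels == i).mean())


class TestCoverage:
    def test_fully_wrapped_bouton(self, wrapped_bouton_volume):
        cov = synaptic_coverage(wrapped_bouton_volume, "bouton", contact_dist_nm=20)
        assert cov == 1.0

    def test_no_astro_gives_zero(self):
        labels = np.zeros((8, 8, 8), dtype=np.int16)
        labels[3:5, 3:5, 3:5] = 2
        vol = LabelVolume(labels, (10, 10, 10), {0: "ecs", 1: "astro", 2: "bouton"})
        assert synaptic_coverage(vol, "bouton") == 0.0

    def test_missing_target_raises(self, two_phase_volume):
        with pytest.raises(EmptySegmentError):
            synaptic_coverage(two_phase_volume, "bouton")

    def test_hemispheric_wrap_is_about_half(self):
        from scipy import ndimage

        n, pitch = 41, 10.0
        labels = np.zeros((n, n, n), dtype=np.int16)
        c = (n // 2 + 0.5) * pitch
        x = (np.arange(n) + 0.5) * pitch
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        r = np.sqrt((X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2)
        bouton = r <= 80
        cross = ndimage.generate_binary_structure(3, 1)
        d1 = ndimage.binary_dilation(bouton, cross)
        d3 = ndimage.binary_dilation(bouton, cross, iterations=3)
        labels[d3 & ~d1 & (Z > c)] = 1  # upper hemisphere wrap
        labels[bouton] = 2
        vol = LabelVolume(labels, (pitch,) * 3, {0: "ecs", 1: "astro", 2: "bouton"})
        cov = synaptic_coverage(vol, "bouton", contact_dist_nm=20)
        assert cov == pytest.approx(0.5, abs=0.1)

    def test_monotone_in_contact_distance(self, wrapped_bouton_volume):
        covs = [
            synaptic_coverage(wrapped_bouton_volume, "bouton", d)
            for d in (6.0, 12.0, 25.0, 60.0)
        ]
        assert all(0.0 <= c <= 1.0 for c in covs)
        assert covs == sorted(covs)


class TestSelection:
    def _record(self, astro_vox: int, **flags):
        labels = np.zeros((10, 10, 10), dtype=np.int16)
        labels.flat[:astro_vox] = 1
        vol = LabelVolume(labels, (6, 6, 6), {0: "ecs", 1: "astro"})
        defaults = dict(
            axon_type="excitatory",
            has_terminal=True,
            is_multisynaptic=False,
            target_is_spine=True,
        )
        defaults.update(flags)
        return SynapseRecord(volume=vol, centroid_nm=(30, 30, 30), **defaults)

    def test_boundary_astro_fraction(self):
        # 1000 voxels total: 19 voxels = 1.9% -> excluded; 20 = 2.0% -> included
        excluded = self._record(19)
        included = self._record(20)
        assert select_synapses([excluded, included]) == [included]

    @pytest.mark.parametrize(
        "flags",
        [
            {"axon_type": "inhibitory"},
            {"has_terminal": False},
            {"is_multisynaptic": True},
            {"target_is_spine": False},
        ],
    )
    def test_each_criterion_excludes(self, flags):
        assert select_synapses([self._record(50, **flags)]) == []

    def test_missing_attribute_names_record(self):
        rec = self._record(50)
        rec.axon_type = None
        rec.synapse_id = "synX"
        with pytest.raises(ValueError, match="synX"):
            select_synapses([rec])

    def test_random_population_matches_brute_force(self, rng):
        records = []
        for _ in range(40):
            records.append(
                self._record(
                    int(rng.integers(0, 60)),
                    axon_type=str(rng.choice(["excitatory", "inhibitory"])),
                    has_terminal=bool(rng.integers(2)),
                    is_multisynaptic=bool(rng.integers(2)),
                    target_is_spine=bool(rng.integers(2)),
                )
            )
        got = select_synapses(records)
        expected = [
            r
            for r in records
            if r.axon_type == "excitatory"
            and r.has_terminal
            and not r.is_multisynaptic
            and r.target_is_spine
            and r.volume.mask("astro").mean() >= 0.02
        ]
        assert got == expected


class TestIO:
    def test_hdf5_roundtrip(self, two_phase_volume, tmp_path):
        p = tmp_path / "vol.h5"
        two_phase_volume.to_hdf5(p)
        back = LabelVolume.from_hdf5(p)
        assert np.array_equal(back.labels, two_phase_volume.labels)
        assert back.pitch_nm == two_phase_volume.pitch_nm
        assert back.label_map == two_phase_volume.label_map

    def test_tiff_roundtrip(self, two_phase_volume, tmp_path):
        p = tmp_path / "vol.tif"
        two_phase_volume.to_tiff(p)
        back = LabelVolume.from_tiff(p)
        assert np.array_equal(back.labels, two_phase_volume.labels)
        assert back.pitch_nm == two_phase_volume.pitch_nm
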
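"""Geometry tests: solids vs closed forms, shells, lattice, voxelization."""

import math

import numpy as np
import pytest

from spsd.fixtures import load_fixture, media_basic, small_phantom_specs
from spsd.phantom_geometry import (
    CORTICAL_BONE,
    MARROW,
    OUTSIDE,
    TRABECULAR_BONE,
    Media,
    add_cortical_shell,
    build_solid,
    derive_geometry,
    generate_trabecular_lattice,
    voxelize,
    VoxelBudgetError,
)
from spsd.segment_model import MicroSpec, ShapeKind, ShapeSpec


@pytest.fixture(scope="module")
def media():
    return media_basic()


def mc_volume(solid, n=200_000, seed=0):
    """Monte Carlo volume from the membership predicate (independent check)."""
    rng = np.random.default_rng(seed)
    lo, hi = solid.bbox_bounds
    pts = rng.uniform(lo, hi, size=(n, 3))
    box_vol = float(np.prod(hi - lo))
    return box_vol * float(np.mean(solid.contains(pts)))


class TestSolids:
    @pytest.mark.parametrize("kind,dims,expected", [
        (ShapeKind.BOX, (1.1, 0.6, 3.0), 1.98),
        (ShapeKind.ELLIPTIC_CYLINDER, (1.0, 1.0, 2.0), math.pi / 4 * 2.0),
        (ShapeKind.ELLIPSOID, (1.0, 1.0, 1.0), math.pi / 6),
        (ShapeKind.TRIANGULAR_PYRAMID, (1.2, 0.9, 2.0), 1.2 * 0.9 * 2.0 / 6),
        (ShapeKind.TUBE, (0.5, 1.0, 2.0), math.pi * 0.75 * 2.0),
        # truncated cone as the degenerate deformed cylinder
        (ShapeKind.DEFORMED_CYLINDER, (2.0, 2.0, 1.0, 1.0, 3.0),
         math.pi * 3.0 / 3.0 * (1.0 ** 2 + 1.0 * 0.5 + 0.5 ** 2)),
    ])
    def test_analytic_volume(self, kind, dims, expected):
        assert build_solid(ShapeSpec(kind, dims)).volume == pytest.approx(expected)

    @pytest.mark.parametrize("kind,dims", [
        (ShapeKind.BOX, (1.1, 0.6, 3.0)),
        (ShapeKind.ELLIPTIC_CYLINDER, (1.4, 0.8, 2.0)),
        (ShapeKind.DEFORMED_CYLINDER, (1.72, 0.6, 0.6, 0.6, 1.34)),
        (ShapeKind.ELLIPSOID, (0.78, 0.78, 1.22)),
        (ShapeKind.TRIANGULAR_PYRAMID, (1.5, 1.0, 2.0)),
        (ShapeKind.TUBE, (0.4, 0.9, 1.5)),
    ])
    def test_membership_consistent_with_volume(self, kind, dims):
        solid = build_solid(ShapeSpec(kind, dims))
        assert mc_volume(solid) == pytest.approx(solid.volume, rel=0.01)

    def test_sphere_surface_area(self):
        solid = build_solid(ShapeSpec(ShapeKind.ELLIPSOID, (2.0, 2.0, 2.0)))
        assert solid.surface_area == pytest.approx(4 * math.pi, rel=1e-6)


class TestCorticalShell:
    def test_cube_shell_closed_form(self):
        cube = build_solid(ShapeSpec(ShapeKind.BOX, (2.1, 2.1, 2.1)))
        part = add_cortical_shell(cube, 0.035)
        expected = 2.1 ** 3 - (2.1 - 2 * 0.035) ** 3
        assert part.cortex_volume == pytest.approx(expected, rel=1e-12)

    def test_zero_thickness_gives_all_spongiosa(self):
        cube = build_solid(ShapeSpec(ShapeKind.BOX, (1.0, 1.0, 1.0)))
        part = add_cortical_shell(cube, 0.0)
        assert part.cortex_volume == 0.0
        assert part.spongiosa.volume == pytest.approx(1.0)

    def test_partial_coverage_leaves_faces_open(self):
        cube = build_solid(ShapeSpec(ShapeKind.BOX, (1.0, 1.0, 1.0)))
        # cover only the two z faces
        part = add_cortical_shell(cube, 0.1,
                                  coverage=(False,) * 4 + (True,) * 2)
        assert part.spongiosa.volume == pytest.approx(1.0 * 1.0 * 0.8)

    def test_per_face_thickness_renormalization(self):
        # the face-randomization protocol: random per-face thicknesses are
        # rescaled so their mean equals the uniform-model thickness
        row7 = load_fixture("cortical_randomization").iloc[6]
        faces = np.array([row7[f"f{i}"] for i in range(1, 7)]) * 1e-2
        assert faces.mean() == pytest.approx(3.5e-2)
        cube = build_solid(ShapeSpec(ShapeKind.BOX, (2.1, 2.1, 2.1)))
        part = add_cortical_shell(cube, faces, target_mean=0.035)
        assert np.mean(part.thicknesses) == pytest.approx(0.035)

    def test_overthick_shell_fails(self):
        cube = build_solid(ShapeSpec(ShapeKind.BOX, (1.0, 1.0, 1.0)))
        with pytest.raises(ValueError, match="no spongiosa"):
            add_cortical_shell(cube, 0.6)


class TestTrabecularLattice:
    def test_zero_bvtv_gives_all_marrow(self):
        cube = build_solid(ShapeSpec(ShapeKind.BOX, (1.0, 1.0, 1.0)))
        micro = MicroSpec(0.01, 0.0, 0.05, 0.0, 0.0, (0.0, 0.0))
        lat = generate_trabecular_lattice(cube, micro, seed=0)
        assert lat.realized_bvtv() == 0.0

    def test_reference_micro_lands_in_range(self):
        # Tb.Th 0.01, Tb.Sp 0.036, BV/TV 0.28 with a +/-10% admissible band
        cube = build_solid(ShapeSpec(ShapeKind.BOX, (0.5, 0.5, 0.5)))
        micro = MicroSpec(0.01, 0.001, 0.036, 0.002, 0.28, (0.252, 0.308))
        lat = generate_trabecular_lattice(cube, micro, seed=1)
        got = lat.realized_bvtv(seed=99)  # fresh points, not the calibration set
        assert 0.24 <= got <= 0.32

    def test_rod_thickness_mean_matches_tbth(self):
        cube = build_solid(ShapeSpec(ShapeKind.BOX, (1.0, 1.0, 1.0)))
        micro = MicroSpec(0.02, 0.004, 0.08, 0.004, 0.10, (0.0, 1.0))
        lat = generate_trabecular_lattice(cube, micro, seed=2)
        rods = np.concatenate([lat._th_z.ravel(), lat._th_x.ravel(),
                               lat._th_y.ravel()])
        assert rods.size >= 100
        se = micro.tb_th_sd / math.sqrt(rods.size)
        assert abs(rods.mean() - micro.tb_th) < 2 * se + 1e-9


class TestVoxelize:
    def test_aligned_box_is_exact(self):
        box = build_solid(ShapeSpec(ShapeKind.BOX, (1.0, 0.5, 2.0)))
        part = add_cortical_shell(box, 0.0)
        ph = voxelize(part, 0.05)
        counts = ph.counts()
        assert counts[MARROW] * ph.voxel_volume == pytest.approx(1.0 * 0.5 * 2.0)
        assert counts[OUTSIDE] == counts[CORTICAL_BONE] == counts[TRABECULAR_BONE] == 0

    def test_label_counts_conserve_grid(self):
        cyl = build_solid(ShapeSpec(ShapeKind.ELLIPTIC_CYLINDER, (1.0, 0.8, 1.2)))
        part = add_cortical_shell(cyl, 0.05)
        ph = voxelize(part, 0.02)
        assert sum(ph.counts().values()) == ph.grid.size

    def test_shell_volume_error_shrinks_with_resolution(self):
        # thickness chosen off the voxel grid so center-point sampling
        # actually has to converge rather than landing exactly
        cube = build_solid(ShapeSpec(ShapeKind.BOX, (1.0, 1.0, 1.0)))
        part = add_cortical_shell(cube, 0.083)
        expected = 1.0 - (1.0 - 2 * 0.083) ** 3
        errors = []
        for res in (0.05, 0.0125):
            ph = voxelize(part, res)
            got = ph.counts()[CORTICAL_BONE] * ph.voxel_volume
            errors.append(abs(got - expected))
        assert errors[1] < errors[0]

    def test_voxel_rule_warning(self):
        # 200 um trabeculae: 150 um (= 0.75 Tb.Th) passes, 200 um warns
        cube = build_solid(ShapeSpec(ShapeKind.BOX, (0.5, 0.5, 0.5)))
        micro = MicroSpec(0.02, 0.002, 0.078, 0.004, 0.17, (0.0, 1.0))
        lat = generate_trabecular_lattice(cube, micro, seed=3)
        part = add_cortical_shell(cube, 0.0)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("error")
            voxelize(part, 0.015, lat)  # no warning
        with pytest.warns(UserWarning, match="0.75 x Tb.Th"):
            voxelize(part, 0.02, lat)

    def test_voxel_budget(self):
        cube = build_solid(ShapeSpec(ShapeKind.BOX, (1.0, 1.0, 1.0)))
        part = add_cortical_shell(cube, 0.0)
        with pytest.raises(VoxelBudgetError):
            voxelize(part, 0.01, max_voxels=1000)


class TestDerivedGeometry:
    def test_unit_cube_spongiosa(self, media):
        bone, marrow = media
        cube = build_solid(ShapeSpec(ShapeKind.BOX, (1.0, 1.0, 1.0)))
        part = add_cortical_shell(cube, 0.0)
        geom = derive_geometry(part, bone, marrow, bvtv=0.0)
        assert geom.v_s == pytest.approx(1.0)
        assert geom.ss == pytest.approx(6.0)
        assert geom.m_bmv == pytest.approx(0.98)

    def test_reference_phantoms_reproduce_printed_volumes(self, media):
        """The six printed small phantoms: V_s, V_CBV within 5%."""
        bone, marrow = media
        table = load_fixture("small_phantoms")
        for spec, (_, row) in zip(small_phantom_specs(), table.iterrows()):
            part = add_cortical_shell(build_solid(spec.shape), spec.ct_th,
                                      spec.cortical_coverage)
            geom = derive_geometry(part, bone, marrow, bvtv=spec.micro.bvtv)
            v_s_printed = row["v_tbv"] + row["v_bmv"]
            assert geom.v_s == pytest.approx(v_s_printed, rel=0.05), spec.segment_id
            assert geom.v_cbv == pytest.approx(row["v_cbv"], rel=0.05), spec.segment_id

    def test_mass_volume_consistency(self, media):
        bone, marrow = media
        cyl = build_solid(ShapeSpec(ShapeKind.ELLIPTIC_CYLINDER, (1.0, 1.0, 2.0)))
        part = add_cortical_shell(cyl, 0.1)
        geom = derive_geometry(part, bone, marrow, bvtv=0.2)
        assert geom.v_s == pytest.approx(geom.v_tbv + geom.v_bmv)
        assert geom.m_tbv == pytest.approx(geom.v_tbv * bone.density)
        assert geom.m_cbv == pytest.approx(geom.v_cbv * bone.density)

    def test_sphere_voxel_surface_close_to_closed_form(self, media):
        bone, marrow = media
        d = 1.0
        sphere = build_solid(ShapeSpec(ShapeKind.ELLIPSOID, (d, d, d)))
        part = add_cortical_shell(sphere, 0.0)
        ph = voxelize(part, d / 50)
        geom = derive_geometry(ph, bone, marrow)
        # voxel faces overestimate a curved surface by up to ~pi/2 x; the
        # comparison is on the voxel estimate scaled by the staircase factor
        staircase = geom.ss / (math.pi * d ** 2)
        assert 1.0 < staircase < 1.6

    def test_voxel_volumes_match_analytic(self, media):
        bone, marrow = media
        cyl = build_solid(ShapeSpec(ShapeKind.ELLIPTIC_CYLINDER, (1.0, 0.8, 1.5)))
        part = add_cortical_shell(cyl, 0.08)
        ph = voxelize(part, 0.01)
        geom_v = derive_geometry(ph, bone, marrow)
        geom_a = derive_geometry(part, bone, marrow, bvtv=0.0)
        assert geom_v.v_s == pytest.approx(geom_a.v_s, rel=0.02)
        assert geom_v.v_cbv == pytest.approx(geom_a.v_cbv, rel=0.05)


class TestMedia:
    def test_fraction_sum_enforced(self):
        with pytest.raises(ValueError, match="sum"):
            Media("bad", 1.0, {"H": 0.5, "O": 0.4})

    def test_basic_media_densities(self):
        bone, marrow = media_basic()
        assert bone.density == 1.9
        assert marrow.density == 0.98
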
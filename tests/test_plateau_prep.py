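"""Template construction, alignment, and standardized plateau cuts."""

import numpy as np
import pytest

import menisize as mz
from menisize.errors import ValidationError
from menisize.geometry import RigidTransform, rotation_about_axis
from menisize.plateau_prep import CuttingPlaneSet


class TestDefaultTemplate:
    def test_deterministic_and_bit_identical(self):
        a = mz.build_default_template()
        b = mz.build_default_template()
        assert np.array_equal(a.mesh.vertices, b.mesh.vertices)
        assert np.array_equal(a.mesh.faces, b.mesh.faces)

    def test_length_is_35_mm(self, template):
        z = template.mesh.vertices[:, 2]
        assert (z.max() - z.min()) == pytest.approx(35.0, abs=1e-6)

    def test_landmark_ordering(self, template):
        assert (
            template.medial_tubercle[1]
            > template.plateau_center[1]
            > template.lateral_tubercle[1]
        )

    def test_axial_plane_10_mm_below_plateau_level(self, template):
        point, normal = template.planes.axial_plane
        assert np.allclose(normal, [0, 0, 1])
        assert point[2] == pytest.approx(
            template.plateau_level_z - mz.AXIAL_OFFSET_MM, abs=1e-9
        )

    def test_sagittal_normals_perpendicular_to_axial(self, template):
        axial_n = template.planes.axial_plane[1]
        for plane in (
            template.planes.central_sagittal_plane,
            template.planes.medial_tubercle_plane,
            template.planes.lateral_tubercle_plane,
        ):
            assert abs(axial_n @ plane[1]) < 1e-9

    def test_save_load_round_trip(self, template, tmp_path):
        mz.save_template(template, tmp_path)
        back = mz.load_template(tmp_path)
        assert back.plateau_level_z == pytest.approx(template.plateau_level_z)
        assert np.allclose(back.medial_tubercle, template.medial_tubercle)

    def test_nonperpendicular_planes_rejected(self, template):
        with pytest.raises(ValidationError):
            CuttingPlaneSet(
                axial_plane=(np.zeros(3), np.array([0, 0, 1.0])),
                central_sagittal_plane=(np.zeros(3), np.array([0, 1.0, 0.1])),
                medial_tubercle_plane=(np.zeros(3), np.array([0, 1.0, 0])),
                lateral_tubercle_plane=(np.zeros(3), np.array([0, 1.0, 0])),
            )


class TestAlignToTemplate:
    def test_template_aligns_to_itself_as_identity(self, template, fast_icp):
        res = mz.align_to_template(template.mesh, template, fast_icp)
        assert np.abs(res.transform.rotation - np.eye(3)).max() < 1e-6
        assert np.abs(res.transform.translation).max() < 1e-6
        assert res.residual_mesd < 1e-6

    def test_scaled_displaced_template_recovers_centroid(self, template, fast_icp):
        scaled = mz.SurfaceMesh(
            template.mesh.vertices * 1.05 + np.array([6.0, -4.0, 3.0]),
            template.mesh.faces,
            "scaled",
        )
        res = mz.align_to_template(scaled, template, fast_icp)
        moved_centroid = res.transform.apply(scaled.centroid())
        # uniform scaling is unbiased: the aligned centroid lands close to
        # the scaled template centroid
        assert (
            np.linalg.norm(moved_centroid - template.mesh.centroid() * 1.05) < 1.5
        )

    def test_random_pose_recovers_plateau_level(self, template, fast_icp):
        """A template-sized tibia under a random pose aligns back so its
        plateau level is within 1 mm of the template's."""
        rng = np.random.default_rng(7)
        pose = RigidTransform(
            rotation_about_axis(rng.normal(size=3), rng.uniform(5, 25)),
            rng.uniform(-20, 20, 3),
        )
        apex = template.mesh.vertices[
            int(np.argmax(template.mesh.vertices[:, 2]))
        ]
        moved = template.mesh.transformed(pose)
        res = mz.align_to_template(moved, template, fast_icp)
        recovered_apex = res.transform.apply(pose.apply(apex))
        assert abs(recovered_apex[2] - template.plateau_level_z) < 1.0

    def test_generated_specimens_align_with_small_residual(self, prepared6):
        specimens, truths = prepared6
        for s, t in zip(specimens, truths):
            apex_posed = t.plateau_apex_posed
            if s.side is mz.Side.LEFT:  # ingestion mirrored the posed meshes
                apex_posed = apex_posed * [1, -1, 1]
            apex = s.alignment.transform.apply(apex_posed)
            # size and eminence variation leave a residual offset
            assert abs(apex[2] - t.plateau_level_z) < 2.0
            assert s.alignment.residual_mesd < 2.0


class TestCutPlateau:
    def test_axial_cut_of_template_keeps_proximal_10_mm(self, template):
        cut = mz.cut_plateau(
            template.mesh, template.planes, mz.PlateauConfig.ENTIRE
        )
        z = cut.vertices[:, 2]
        axial_z = template.planes.axial_plane[0][2]
        assert z.min() >= axial_z - 1e-9
        assert z.max() - axial_z <= mz.AXIAL_OFFSET_MM + 1e-6

    def test_aligned_specimen_cut_stays_near_10_mm(self, prepared6, template):
        specimens, _ = prepared6
        cut = specimens[0].plateau_cuts[(mz.PlateauConfig.ENTIRE, None)]
        extent = cut.vertices[:, 2].max() - template.planes.axial_plane[0][2]
        # alignment residual plus eminence-height variation adds slack
        assert extent <= mz.AXIAL_OFFSET_MM + 2.0

    def test_halves_partition_the_entire_cut(self, prepared6):
        specimens, _ = prepared6
        s = specimens[0]
        entire = s.plateau_cuts[(mz.PlateauConfig.ENTIRE, None)]
        med = s.plateau_cuts[
            (mz.PlateauConfig.HALF_WITH_EMINENCE, mz.Compartment.MEDIAL)
        ]
        lat = s.plateau_cuts[
            (mz.PlateauConfig.HALF_WITH_EMINENCE, mz.Compartment.LATERAL)
        ]
        assert med.area() + lat.area() == pytest.approx(
            entire.area(), rel=1e-6
        )
        pts = mz.sample_surface_points(entire, 300, seed=0)
        d_med, _, _ = med.nearest.query(pts)
        d_lat, _, _ = lat.nearest.query(pts)
        assert np.minimum(d_med, d_lat).max() < 1e-9

    def test_half_without_eminence_is_strictly_smaller(self, prepared6):
        specimens, _ = prepared6
        s = specimens[1]
        for comp in mz.Compartment:
            with_em = s.plateau_cuts[(mz.PlateauConfig.HALF_WITH_EMINENCE, comp)]
            without = s.plateau_cuts[
                (mz.PlateauConfig.HALF_WITHOUT_EMINENCE, comp)
            ]
            assert without.area() < with_em.area()

    def test_cuts_are_nested_subsets(self, prepared6):
        specimens, _ = prepared6
        s = specimens[2]
        entire = s.plateau_cuts[(mz.PlateauConfig.ENTIRE, None)]
        half = s.plateau_cuts[
            (mz.PlateauConfig.HALF_WITH_EMINENCE, mz.Compartment.MEDIAL)
        ]
        without = s.plateau_cuts[
            (mz.PlateauConfig.HALF_WITHOUT_EMINENCE, mz.Compartment.MEDIAL)
        ]
        for inner, outer in ((without, half), (half, entire)):
            pts = mz.sample_surface_points(inner, 200, seed=1)
            d, _, _ = outer.nearest.query(pts)
            assert d.max() < 1e-9

    def test_cut_result_lies_on_input_surface(self, prepared6):
        specimens, _ = prepared6
        s = specimens[3]
        cut = s.plateau_cuts[
            (mz.PlateauConfig.HALF_WITHOUT_EMINENCE, mz.Compartment.LATERAL)
        ]
        pts = mz.sample_surface_points(cut, 300, seed=2)
        d, _, _ = s.tibia.nearest.query(pts)
        assert d.max() < 1e-9
        assert cut.is_closed is False

    def test_cut_commutes_with_rigid_motion(self, template):
        T = RigidTransform(
            rotation_about_axis([1, 0.5, 2], 21.0), np.array([3.0, 8.0, -5.0])
        )
        cut_then_move = mz.cut_plateau(
            template.mesh, template.planes, mz.PlateauConfig.ENTIRE
        ).transformed(T)
        moved_planes = CuttingPlaneSet(
            axial_plane=(
                T.apply(template.planes.axial_plane[0]),
                T.rotation @ template.planes.axial_plane[1],
            ),
            central_sagittal_plane=(
                T.apply(template.planes.central_sagittal_plane[0]),
                T.rotation @ template.planes.central_sagittal_plane[1],
            ),
            medial_tubercle_plane=(
                T.apply(template.planes.medial_tubercle_plane[0]),
                T.rotation @ template.planes.medial_tubercle_plane[1],
            ),
            lateral_tubercle_plane=(
                T.apply(template.planes.lateral_tubercle_plane[0]),
                T.rotation @ template.planes.lateral_tubercle_plane[1],
            ),
        )
        move_then_cut = mz.cut_plateau(
            template.mesh.transformed(T), moved_planes, mz.PlateauConfig.ENTIRE
        )
        d, _, _ = move_then_cut.nearest.query(cut_then_move.vertices)
        assert d.max() < 1e-9

    def test_missing_compartment_rejected(self, template):
        with pytest.raises(ValidationError):
            mz.cut_plateau(
                template.mesh, template.planes,
                mz.PlateauConfig.HALF_WITH_EMINENCE,
            )

    def test_planes_missing_the_mesh_raise(self, template):
        planes = CuttingPlaneSet(
            axial_plane=(np.array([0.0, 0.0, 100.0]), np.array([0, 0, 1.0])),
            central_sagittal_plane=(np.zeros(3), np.array([0, 1.0, 0])),
            medial_tubercle_plane=(np.zeros(3), np.array([0, 1.0, 0])),
            lateral_tubercle_plane=(np.zeros(3), np.array([0, 1.0, 0])),
        )
        with pytest.raises(ValidationError):
            mz.cut_plateau(template.mesh, planes, mz.PlateauConfig.ENTIRE)
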
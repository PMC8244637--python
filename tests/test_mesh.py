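"""Mesh, landmark, reflection and rigid-alignment contracts."""

import numpy as np
import pytest

from facesym.errors import AlignmentError, InputError
from facesym.mesh import (CANONICAL_LANDMARKS, CohortRecord, FaceSurface,
                          LandmarkSet, build_pairing, landmark_distance,
                          procrustes_align, read_face, read_landmarks,
                          reflect_surface, rigid_transform, write_face,
                          write_landmarks)


def _face_from_template(template, subject_id="t"):
    return FaceSurface(
        subject_id=subject_id,
        vertices=template.vertices.copy(),
        triangles=template.triangles.copy(),
        landmarks=LandmarkSet(list(template.landmarks.names),
                              template.landmarks.points.copy()),
    )


# ---------------------------------------------------------------------------
# landmark sets


def test_pairing_is_involution_covering_all_names():
    pairing = build_pairing(CANONICAL_LANDMARKS)
    assert set(pairing) == set(CANONICAL_LANDMARKS)
    for name, partner in pairing.items():
        assert pairing[partner] == name
    assert pairing["exocanthion_l"] == "exocanthion_r"
    assert pairing["nasion"] == "nasion"


def test_sided_landmark_without_partner_rejected():
    with pytest.raises(InputError, match="exocanthion_r"):
        build_pairing(["nasion", "exocanthion_l"])


def test_duplicate_landmark_names_rejected():
    with pytest.raises(InputError, match="duplicate"):
        LandmarkSet(names=["nasion", "nasion"], points=np.zeros((2, 3)))


def test_reflected_landmarks_negate_x_and_relabel():
    lms = LandmarkSet(
        names=["nasion", "exocanthion_l", "exocanthion_r"],
        points=np.array([[0.0, 50.0, 5.0], [-45.0, 40.0, 2.0], [45.0, 40.0, 2.0]]),
    )
    ref = lms.reflected()
    # the entry that was the left exocanthion is now named right, at (−x, y, z)
    i = lms.index("exocanthion_l")
    assert ref.names[i] == "exocanthion_r"
    np.testing.assert_array_equal(ref.points[i], [45.0, 40.0, 2.0])
    assert ref.names[lms.index("nasion")] == "nasion"


def test_landmark_distance_three_four_five():
    lms = LandmarkSet(names=["nasion", "pronasale"],
                      points=np.array([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]]))
    assert landmark_distance(lms, "nasion", "pronasale") == pytest.approx(5.0)
    assert landmark_distance(lms, "nasion", "nasion") == 0.0
    with pytest.raises(InputError):
        landmark_distance(lms, "nasion", "gnathion")


# ---------------------------------------------------------------------------
# reflection


def test_reflection_negates_x(template):
    face = _face_from_template(template)
    mirrored = reflect_surface(face)
    np.testing.assert_array_equal(mirrored.vertices[:, 0], -face.vertices[:, 0])
    np.testing.assert_array_equal(mirrored.vertices[:, 1:], face.vertices[:, 1:])


def test_double_reflection_is_identity(template):
    face = _face_from_template(template)
    back = reflect_surface(reflect_surface(face))
    np.testing.assert_array_equal(back.vertices, face.vertices)
    np.testing.assert_array_equal(back.triangles, face.triangles)
    assert back.landmarks.names == face.landmarks.names
    np.testing.assert_array_equal(back.landmarks.points, face.landmarks.points)


def test_reflection_flips_triangle_winding(template):
    face = _face_from_template(template)
    mirrored = reflect_surface(face)
    np.testing.assert_array_equal(mirrored.triangles, face.triangles[:, ::-1])


# ---------------------------------------------------------------------------
# rigid alignment


def _rotation_y(angle):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def test_alignment_of_face_at_reference_is_identity(template):
    face = _face_from_template(template)
    aligned, residuals = procrustes_align([face], template.landmarks)
    assert residuals[0] < 1e-9
    np.testing.assert_allclose(aligned[0].vertices, face.vertices, atol=1e-9)


def test_alignment_recovers_known_rotation(template):
    face = _face_from_template(template)
    r = _rotation_y(np.deg2rad(30.0))
    t = np.array([5.0, -3.0, 2.0])
    moved = face.copy()
    moved.vertices = face.vertices @ r.T + t
    moved.landmarks = LandmarkSet(list(face.landmarks.names),
                                  face.landmarks.points @ r.T + t)
    aligned, residuals = procrustes_align([moved], template.landmarks)
    assert residuals[0] < 1e-8
    np.testing.assert_allclose(aligned[0].vertices, face.vertices, atol=1e-8)


def test_alignment_preserves_landmark_distances(template):
    face = _face_from_template(template)
    r = _rotation_y(0.7)
    moved = face.copy()
    moved.vertices = face.vertices @ r.T + 10.0
    moved.landmarks = LandmarkSet(list(face.landmarks.names),
                                  face.landmarks.points @ r.T + 10.0)
    aligned, _ = procrustes_align([moved], template.landmarks)
    before = moved.landmarks.points
    after = aligned[0].landmarks.points
    d_before = np.linalg.norm(before[:, None] - before[None], axis=2)
    d_after = np.linalg.norm(after[:, None] - after[None], axis=2)
    np.testing.assert_allclose(d_after, d_before, atol=1e-9)


def test_degenerate_landmark_configuration_raises():
    # collinear points have rank < 3
    src = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(AlignmentError):
        rigid_transform(src, src)


def test_symmetric_face_reflection_realigns_onto_itself(template):
    """A surface symmetric about x = 0 with mirrored landmark pairs maps
    onto itself (up to vertex reordering) after reflection + alignment."""
    face = _face_from_template(template)
    mirrored = reflect_surface(face)
    aligned, residuals = procrustes_align([mirrored], face.landmarks)
    assert residuals[0] < 1e-6
    perm = template.mirror_permutation
    np.testing.assert_allclose(aligned[0].vertices[perm], face.vertices, atol=1e-6)


# ---------------------------------------------------------------------------
# I/O


def test_obj_round_trip_preserves_vertices(template, tmp_path):
    face = _face_from_template(template)
    write_face(face, tmp_path / "t.obj", tmp_path / "t.lmk")
    back = read_face(tmp_path / "t.obj", tmp_path / "t.lmk", subject_id="t")
    assert np.abs(back.vertices - face.vertices).max() < 1e-6
    np.testing.assert_array_equal(back.triangles, face.triangles)
    assert back.landmarks.names == face.landmarks.names


def test_landmark_file_missing_name_rejected(template, tmp_path):
    lms = template.landmarks
    short = LandmarkSet(names=lms.names[1:], points=lms.points[1:],
                        pairing={n: lms.pairing[n] for n in lms.names[1:]})
    write_landmarks(short, tmp_path / "short.lmk")
    with pytest.raises(InputError, match=lms.names[0]):
        read_landmarks(tmp_path / "short.lmk")


def test_landmark_reader_reorders_to_canonical_scheme(template, tmp_path):
    lms = template.landmarks
    shuffled = lms.reordered(list(reversed(lms.names)))
    write_landmarks(shuffled, tmp_path / "s.lmk")
    back = read_landmarks(tmp_path / "s.lmk")
    assert back.names == list(CANONICAL_LANDMARKS)
    for n in lms.names:
        np.testing.assert_allclose(back.point(n), lms.point(n), atol=1e-6)


# ---------------------------------------------------------------------------
# validation


def test_face_surface_rejects_tiny_meshes():
    with pytest.raises(InputError, match="100"):
        FaceSurface("x", np.zeros((10, 3)), np.zeros((1, 3), int),
                    LandmarkSet(["nasion"], np.zeros((1, 3))))


def test_face_surface_rejects_bad_triangle_indices(template):
    tri = template.triangles.copy()
    tri[0, 0] = len(template.vertices)  # out of range
    with pytest.raises(InputError, match="triangle"):
        FaceSurface("x", template.vertices, tri, template.landmarks)


def test_face_surface_rejects_landmarks_outside_bbox(template):
    pts = template.landmarks.points.copy()
    pts[0] = [1e4, 1e4, 1e4]
    with pytest.raises(InputError, match="bounding box"):
        FaceSurface("x", template.vertices, template.triangles,
                    LandmarkSet(list(template.landmarks.names), pts))


def test_cohort_record_validation():
    with pytest.raises(InputError, match="duration"):
        CohortRecord("s", age=30.0, gender="F", group="FS", duration=40.0)
    with pytest.raises(InputError, match="gender"):
        CohortRecord("s", age=30.0, gender="x", group="FS")
    with pytest.raises(InputError, match="group"):
        CohortRecord("s", age=30.0, gender="F", group="XYZ")
    rec = CohortRecord("s", age=30.0, gender="F", group="FS", duration=10.0,
                       lesion_side="left")
    assert rec.lesion_side == "left"
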
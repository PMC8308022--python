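"""Half-face compositing: fixed points, reflection oracle, streaming."""

import numpy as np
import pytest
from scipy.ndimage import map_coordinates

from mirrorface.compositor import (
    CompositeOptions,
    composite,
    composite_stream,
    electrode_occlusion_check,
)
from mirrorface.errors import AxisOutOfFrameError
from mirrorface.symmetry import SymmetryAxis, estimate_axis, reflect_point
from mirrorface.synthetic import FaceParams, OracleProvider, generate_face, generate_sequence


def seam_mask(axis, shape, seam_width=11.0):
    h, w = shape
    xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    s = axis.signed_distance(np.stack([xs, ys], -1).reshape(-1, 2)).reshape(h, w)
    return np.abs(s) > seam_width / 2.0, s


class TestComposite:
    def test_symmetric_face_is_fixed_point(self, upright_face):
        image, lms, _ = upright_face
        axis = estimate_axis(lms)
        frame = composite(image, lms, axis, "right")
        outside, _ = seam_mask(axis, image.shape)
        diff = np.abs(frame.image.astype(int) - image.astype(int))
        assert diff[outside].max() <= 2

    def test_affected_pixels_sample_reflected_input(self, drooped_face):
        image, lms, _ = drooped_face
        axis = estimate_axis(lms)
        frame = composite(image, lms, axis, "right")
        outside, s = seam_mask(axis, image.shape)
        affected = outside & (s < 0)  # image-left side of an up axis
        ys, xs = np.nonzero(affected)
        pick = slice(0, len(ys), max(1, len(ys) // 500))
        pts = np.stack([xs[pick], ys[pick]], -1).astype(float)
        refl = reflect_point(pts, axis)
        expected = map_coordinates(
            image.astype(float), [refl[:, 1], refl[:, 0]], order=1, mode="nearest"
        )
        got = frame.image[ys[pick], xs[pick]].astype(float)
        assert np.abs(got - np.rint(expected)).max() <= 1

    def test_unaffected_side_bit_identical(self, drooped_face):
        image, lms, _ = drooped_face
        axis = estimate_axis(lms)
        frame = composite(image, lms, axis, "right")
        outside, s = seam_mask(axis, image.shape)
        keep = outside & (s > 0)
        assert np.array_equal(frame.image[keep], image[keep])

    def test_idempotent_outside_seam(self, drooped_face):
        image, lms, _ = drooped_face
        axis = estimate_axis(lms)
        once = composite(image, lms, axis, "right").image
        twice = composite(once, lms, axis, "right").image
        outside, _ = seam_mask(axis, image.shape)
        diff = np.abs(twice.astype(int) - once.astype(int))
        assert diff[outside].max() <= 2

    def test_output_bilateral_symmetry(self, drooped_face):
        image, lms, _ = drooped_face
        axis = estimate_axis(lms)
        out = composite(image, lms, axis, "right").image.astype(float)
        outside, s = seam_mask(axis, image.shape)
        # compare output at p vs output at reflect(p), in the face region
        hull_lo, hull_hi = lms.points.min(0) + 5, lms.points.max(0) - 5
        ys, xs = np.nonzero(outside)
        pts = np.stack([xs, ys], -1).astype(float)
        inside_face = np.all((pts > hull_lo) & (pts < hull_hi), axis=1)
        pts = pts[inside_face][::37]
        refl = reflect_point(pts, axis)
        a = out[pts[:, 1].astype(int), pts[:, 0].astype(int)]
        b = map_coordinates(out, [refl[:, 1], refl[:, 0]], order=1, mode="nearest")
        assert np.abs(a - b).max() <= 2

    def test_deterministic(self, drooped_face):
        image, lms, _ = drooped_face
        axis = estimate_axis(lms)
        a = composite(image, lms, axis, "left").image
        b = composite(image, lms, axis, "left").image
        assert np.array_equal(a, b)

    def test_rgb_image_supported(self, drooped_face):
        image, lms, _ = drooped_face
        rgb = np.stack([image] * 3, axis=-1)
        axis = estimate_axis(lms)
        frame = composite(rgb, lms, axis, "right")
        assert frame.image.shape == rgb.shape
        gray = composite(image, lms, axis, "right").image
        assert np.array_equal(frame.image[..., 0], gray)

    def test_axis_outside_image_is_error(self, upright_face):
        image, lms, _ = upright_face
        axis = SymmetryAxis((10000.0, 0.0), (0.0, -1.0))
        with pytest.raises(AxisOutOfFrameError):
            composite(image, lms, axis, "right")

    def test_mesh_warp_mode_preserves_unaffected_side(self, drooped_face):
        image, lms, _ = drooped_face
        axis = estimate_axis(lms)
        frame = composite(
            image, lms, axis, "right", CompositeOptions(warp_mode="mesh_warp")
        )
        outside, s = seam_mask(axis, image.shape)
        keep = outside & (s > 0)
        assert np.array_equal(frame.image[keep], image[keep])

    def test_face_only_restricts_replacement(self, drooped_face):
        image, lms, _ = drooped_face
        axis = estimate_axis(lms)
        frame = composite(
            image, lms, axis, "right", CompositeOptions(face_only=True)
        )
        # far corner (outside the landmark hull, affected side) is untouched
        assert frame.image[5, 5] == image[5, 5]


class TestStream:
    def test_constant_sequence_all_found(self, upright_face):
        image, lms, _ = upright_face
        frames = [image] * 10
        out = list(composite_stream(frames, OracleProvider(lms), "right"))
        assert len(out) == 10
        assert all(f.face_found for f in out)
        assert [f.source_frame_index for f in out] == list(range(10))

    def test_blank_frame_passes_through_flagged(self, upright_face):
        image, lms, _ = upright_face
        blank = np.zeros_like(image)
        out = list(composite_stream([image, blank, image], OracleProvider(lms), "right"))
        assert [f.face_found for f in out] == [True, False, True]
        assert np.array_equal(out[1].image, blank)
        assert out[1].axis is None

    def test_translating_face_moves_axis(self):
        params = FaceParams()
        motion = (5.0, 0.0)
        seq = list(generate_sequence(params, 6, motion))
        frames = [f[0] for f in seq]
        provider = OracleProvider([f[1] for f in seq])
        out = list(composite_stream(frames, provider, "right"))
        anchors = np.array([f.axis.anchor for f in out])
        steps = np.diff(anchors[:, 0])
        assert np.all(np.abs(steps - 5.0) <= 0.5)


class TestOcclusion:
    def _setup(self, upright_face):
        _, lms, _ = upright_face
        axis = estimate_axis(lms)
        return lms, axis

    def test_region_fully_on_affected_side_hidden(self, upright_face):
        lms, axis = self._setup(upright_face)
        # unaffected = right; a box well on the image-left side is replaced
        report = electrode_occlusion_check(lms, axis, [(10, 100, 50, 30)], "right")
        assert report[0]["hidden"] == "full"
        assert report[0]["hidden_bool"] is True

    def test_region_straddling_axis_partial(self, upright_face):
        lms, axis = self._setup(upright_face)
        cx = axis.anchor[0]
        report = electrode_occlusion_check(lms, axis, [(cx - 20, 50, 40, 20)], "right")
        assert report[0]["hidden"] == "partial"

    def test_forehead_electrode_reaching_past_midline_stays_visible(self, upright_face):
        # an electrode on the frontalis that crosses onto the unaffected side
        # is only partially hidden by the mirrored composite
        lms, axis = self._setup(upright_face)
        brow_y = lms.points[17:27, 1].min() - 10
        cx = axis.anchor[0]
        report = electrode_occlusion_check(
            lms, axis, [(cx - 35, brow_y, 50, 15)], "right"
        )
        assert report[0]["hidden"] == "partial"
        assert report[0]["hidden_bool"] is False

    def test_region_on_unaffected_side_not_hidden(self, upright_face):
        lms, axis = self._setup(upright_face)
        report = electrode_occlusion_check(lms, axis, [(600, 100, 30, 30)], "right")
        assert report[0]["hidden"] == "none"
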
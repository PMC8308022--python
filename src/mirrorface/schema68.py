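"""The packaged 68-point facial landmark layout.

The layout follows the de-facto interchange convention for face landmark
files: 17 jaw points (0-16), 10 brow points (17-26), 9 nose points (27-35),
12 eye points (36-47), 20 mouth points (48-67).  ``left``/``right`` in the
bilateral-pair table refer to the *image* side for an upright face seen by
an observer (image left = subject's anatomical right).
"""

from __future__ import annotations

# (image-left index, image-right index) for every anatomically mirrored pair
BILATERAL_PAIRS_68: tuple[tuple[int, int], ...] = (
    # jaw line
    (0, 16), (1, 15), (2, 14), (3, 13), (4, 12), (5, 11), (6, 10), (7, 9),
    # eyebrows
    (17, 26), (18, 25), (19, 24), (20, 23), (21, 22),
    # nostrils / alae
    (31, 35), (32, 34),
    # eyes (outer corner, upper lid x2, inner corner, lower lid x2)
    (36, 45), (37, 44), (38, 43), (39, 42), (40, 47), (41, 46),
    # outer lip contour
    (48, 54), (49, 53), (50, 52), (55, 59), (56, 58),
    # inner lip contour
    (60, 64), (61, 63), (65, 67),
)

# chin tip, nose bridge (4), columella base, mid upper/lower lip (outer and inner)
MIDLINE_INDICES_68: tuple[int, ...] = (8, 27, 28, 29, 30, 33, 51, 57, 62, 66)

#: index of the chin tip (inferior midline anchor, used to orient the axis)
CHIN_INDEX_68 = 8
#: index of the top of the nose bridge (superior midline anchor)
NOSE_BRIDGE_INDEX_68 = 27

POINT_NAMES_68: tuple[str, ...] = tuple(
    [f"jaw_{i}" for i in range(17)]
    + [f"brow_l_{i}" for i in range(5)]
    + [f"brow_r_{i}" for i in range(5)]
    + [f"nose_bridge_{i}" for i in range(4)]
    + [f"nose_base_{i}" for i in range(5)]
    + [f"eye_l_{i}" for i in range(6)]
    + [f"eye_r_{i}" for i in range(6)]
    + [f"mouth_outer_{i}" for i in range(12)]
    + [f"mouth_inner_{i}" for i in range(8)]
)

#: landmark indices for the left/right eye rings (used for interocular distance)
LEFT_EYE_68 = tuple(range(36, 42))
RIGHT_EYE_68 = tuple(range(42, 48))
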
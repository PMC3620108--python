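import math

import numpy as np
import pytest

from nucshell import (
    BACKGROUND,
    NUCLEUS,
    PROBE,
    ClassGrid,
    DegenerateNucleusError,
    GeometryError,
    NoNucleusError,
    PixelGrid,
    bounding_box,
    classify_grid,
    estimate_geometry,
    find_contour,
    initial_midpoint,
    major_axis,
    minor_axis,
    refine_midpoint,
)
from nucshell.contour_axes import SENTINEL, BoundingBox, Contour

from conftest import angle_diff_deg, classgrid_of, random_ellipse_specs
from nucshell.synthetic import make_nucleus_image


def single_pixel_grid(x=7, y=4, w=12, h=9):
    lab = np.full((h, w), BACKGROUND, dtype=np.uint8)
    lab[y, x] = NUCLEUS
    return ClassGrid(lab)


class TestFindContour:
    def test_no_nucleus_raises(self):
        lab = np.full((6, 6), BACKGROUND, dtype=np.uint8)
        with pytest.raises(NoNucleusError):
            find_contour(ClassGrid(lab))

    def test_ellipse_row_through_center(self, ellipse_100_50, palette):
        _, grid, _ = ellipse_100_50
        contour = find_contour(classgrid_of(grid))
        assert abs(contour.left[150] - 100) <= 1
        assert abs(contour.right[150] - 300) <= 1

    def test_single_pixel(self):
        contour = find_contour(single_pixel_grid())
        assert contour.left[4] == contour.right[4] == 7
        mask = np.arange(9) != 4
        assert (contour.left[mask] == SENTINEL).all()

    def test_probe_touching_rim_counts_as_boundary(self):
        lab = np.full((7, 9), BACKGROUND, dtype=np.uint8)
        lab[3, 3:6] = NUCLEUS
        lab[3, 2] = PROBE  # probe outside the counterstain, on the rim
        contour = find_contour(ClassGrid(lab))
        assert contour.left[3] == 2 and contour.right[3] == 5

    def test_extremes_are_nucleus_or_probe(self, suite):
        for name in ("axis_aligned_ellipse", "rotated_ellipse_30deg", "interior_blob"):
            cls = classgrid_of(suite[name].grid)
            contour = find_contour(cls)
            for y in contour.rows():
                assert cls.labels[y, contour.left[y]] in (NUCLEUS, PROBE)
                assert cls.labels[y, contour.right[y]] in (NUCLEUS, PROBE)


class TestBoundingBoxMidpoint:
    def test_ellipse_extremes(self, ellipse_100_50):
        _, grid, _ = ellipse_100_50
        box = bounding_box(find_contour(classgrid_of(grid)))
        assert box.left[0] == pytest.approx(100, abs=1)
        assert box.left[1] == pytest.approx(150, abs=1)
        assert box.right[0] == pytest.approx(300, abs=1)
        assert box.top[1] == pytest.approx(100, abs=1)
        assert box.bottom[1] == pytest.approx(200, abs=1)

    def test_single_pixel_degenerate_box(self):
        box = bounding_box(find_contour(single_pixel_grid()))
        assert box.left == box.right == (7.0, 4.0)

    def test_two_pixel_extremes(self):
        lab = np.full((8, 12), BACKGROUND, dtype=np.uint8)
        lab[2, 3] = NUCLEUS
        lab[6, 9] = NUCLEUS
        box = bounding_box(find_contour(ClassGrid(lab)))
        assert box.left[0] == 3 and box.right[0] == 9
        assert box.top[1] == 2 and box.bottom[1] == 6

    @pytest.mark.parametrize(
        "left,right,top,bottom,expected",
        [
            ((100, 150), (300, 150), (200, 100), (200, 200), (200.0, 150.0)),
            ((7, 4), (7, 4), (7, 4), (7, 4), (7.0, 4.0)),
            ((0, 2), (5, 2), (2, 0), (2, 5), (2.5, 2.5)),
        ],
    )
    def test_initial_midpoint_formula(self, left, right, top, bottom, expected):
        box = BoundingBox(top=top, bottom=bottom, left=left, right=right)
        assert initial_midpoint(box) == expected


class TestAxes:
    def test_major_axis_length_of_ellipse(self, ellipse_100_50):
        _, grid, _ = ellipse_100_50
        contour = find_contour(classgrid_of(grid))
        mpt = initial_midpoint(bounding_box(contour))
        p1, p2 = major_axis(contour, mpt)
        assert math.dist(p1, p2) == pytest.approx(200, abs=2)
        assert p1 in ((300.0, 150.0), (100.0, 150.0))

    def test_circle_diameter(self, suite):
        cls = classgrid_of(suite["circle"].grid)
        contour = find_contour(cls)
        mpt = initial_midpoint(bounding_box(contour))
        p1, p2 = major_axis(contour, mpt)
        assert math.dist(p1, p2) == pytest.approx(140, abs=2)

    def test_rotated_axis_orientation(self, rotated_30):
        contour = find_contour(classgrid_of(rotated_30.grid))
        mpt = initial_midpoint(bounding_box(contour))
        p1, p2 = major_axis(contour, mpt)
        theta = math.atan2(p2[1] - p1[1], p2[0] - p1[0])
        assert angle_diff_deg(theta, math.radians(30)) <= 2

    def test_degenerate_contour_raises(self):
        with pytest.raises(DegenerateNucleusError):
            contour = find_contour(single_pixel_grid())
            major_axis(contour, (7.0, 4.0))

    @pytest.mark.parametrize(
        "p1,p2,expected",
        [((300, 150), (100, 150), (200, 150)), ((0, 0), (10, 20), (5, 10))],
    )
    def test_refine_midpoint(self, p1, p2, expected):
        assert refine_midpoint(p1, p2) == expected

    def test_refine_midpoint_coincident_raises(self):
        with pytest.raises(DegenerateNucleusError):
            refine_midpoint((3, 3), (3, 3))

    def test_rotated_center_recovery(self, rotated_30):
        contour = find_contour(classgrid_of(rotated_30.grid))
        mpt0 = initial_midpoint(bounding_box(contour))
        mpt = refine_midpoint(*major_axis(contour, mpt0))
        assert mpt[0] == pytest.approx(rotated_30.spec.center[0], abs=1)
        assert mpt[1] == pytest.approx(rotated_30.spec.center[1], abs=1)

    def test_minor_axis_of_ellipse(self, ellipse_100_50):
        _, grid, _ = ellipse_100_50
        contour = find_contour(classgrid_of(grid))
        q1, q2 = minor_axis(contour, (200.0, 150.0), 0.0)
        assert math.dist(q1, q2) / 2 == pytest.approx(50, abs=1)
        ys = sorted([q1[1], q2[1]])
        assert ys[0] == pytest.approx(100, abs=1)
        assert ys[1] == pytest.approx(200, abs=1)

    def test_minor_axis_outside_midpoint_raises(self, ellipse_100_50):
        _, grid, _ = ellipse_100_50
        contour = find_contour(classgrid_of(grid))
        with pytest.raises(GeometryError):
            minor_axis(contour, (5.0, 5.0), 0.0)


class TestEstimateGeometry:
    def test_known_rotated_ellipse_recovery(self):
        spec_kwargs = dict(width=300, height=300, center=(150.0, 150.0))
        from nucshell.synthetic import NucleusSpec

        spec = NucleusSpec(a=120, b=60, theta=math.radians(40), seed=0, **spec_kwargs)
        grid, _ = make_nucleus_image(spec)
        geom = estimate_geometry(classgrid_of(grid))
        assert geom.a == pytest.approx(120, abs=2)
        assert geom.b == pytest.approx(60, abs=2)
        assert angle_diff_deg(geom.theta, math.radians(40)) <= 2

    def test_circle_axis_ratio_near_one(self, suite):
        geom = estimate_geometry(classgrid_of(suite["circle"].grid))
        assert 0.98 <= geom.a / geom.b <= 1.02

    def test_two_to_one_ellipse_ratio(self, ellipse_100_50):
        _, grid, _ = ellipse_100_50
        geom = estimate_geometry(classgrid_of(grid))
        assert 1.9 <= geom.a / geom.b <= 2.1

    def test_axes_perpendicular_and_consistent(self, rotated_30):
        geom = estimate_geometry(classgrid_of(rotated_30.grid))
        major_dir = math.atan2(geom.majpt2[1] - geom.majpt1[1], geom.majpt2[0] - geom.majpt1[0])
        minor_dir = math.atan2(geom.minpt2[1] - geom.minpt1[1], geom.minpt2[0] - geom.minpt1[0])
        assert angle_diff_deg(major_dir, minor_dir) == pytest.approx(90, abs=1e-6)
        assert math.dist(geom.majpt1, geom.majpt2) == pytest.approx(2 * geom.a, abs=1e-9)
        assert math.dist(geom.minpt1, geom.minpt2) == pytest.approx(2 * geom.b, abs=1e-9)

    def test_parameter_recovery_over_random_ellipses(self):
        """Semi-axes recover to 2% + 2 px over a random orientation/size sweep."""
        rng = np.random.default_rng(0)
        specs = random_ellipse_specs(rng, 20, a_range=(60, 150), aspect_range=(1.5, 3))
        for spec in specs:
            grid, _ = make_nucleus_image(spec)
            geom = estimate_geometry(classgrid_of(grid))
            assert abs(geom.a - spec.a) <= 0.02 * spec.a + 2
            assert abs(geom.b - spec.b) <= 0.02 * spec.b + 2
            # Orientation noise grows as eccentricity falls; 5 deg is a
            # loose sanity bound here, the precision study lives with the
            # acceptance checks.
            assert angle_diff_deg(geom.theta, spec.theta) <= 5

    def test_rotation_equivariance(self, rotated_30):
        cls = classgrid_of(rotated_30.grid)
        geom = estimate_geometry(cls)
        rot = ClassGrid(np.rot90(cls.labels, k=1))  # 90 deg counterclockwise
        geom_rot = estimate_geometry(rot)
        assert angle_diff_deg(geom_rot.theta, geom.theta + math.pi / 2) <= 2
        assert geom_rot.a == pytest.approx(geom.a, abs=1)
        assert geom_rot.b == pytest.approx(geom.b, abs=1)
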
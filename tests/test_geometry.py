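"""Domain discretization: masks, faces, catalytic region, relocation."""

import numpy as np
import pytest

import nucactin as na
from nucactin.geometry import CYTOPLASM, EXTERIOR, NUCLEUS


def brute_force_counts(geom, nx, ny, extent=((-1, 1), (-1, 1))):
    """Independent cell-centre enumeration oracle."""
    (x0, x1), (y0, y1) = extent
    h = (x1 - x0) / nx
    counts = {NUCLEUS: 0, CYTOPLASM: 0, EXTERIOR: 0}
    for j in range(ny):
        for i in range(nx):
            x = x0 + (i + 0.5) * h
            y = y0 + (j + 0.5) * h
            if (x - geom.p1[0]) ** 2 + (y - geom.p1[1]) ** 2 < geom.r1 ** 2:
                counts[NUCLEUS] += 1
            elif (x - geom.p2[0]) ** 2 + (y - geom.p2[1]) ** 2 < geom.r2 ** 2:
                counts[CYTOPLASM] += 1
            else:
                counts[EXTERIOR] += 1
    return counts


class TestBuildDomain:
    def test_labels_match_brute_force_enumeration(self, geometry):
        domain = na.build_domain(geometry, 41, 41)
        expected = brute_force_counts(geometry, 41, 41)
        for label in (NUCLEUS, CYTOPLASM, EXTERIOR):
            assert len(domain.indices(label)) == expected[label]

    def test_probe_points_get_expected_labels(self, geometry, toy_domain):
        # the centre of the nucleus and the mid-annulus point
        mask = toy_domain.mask
        i = np.argmin(np.abs(toy_domain.xc - geometry.p1[0]))
        j = np.argmin(np.abs(toy_domain.yc - geometry.p1[1]))
        assert mask[j, i] == NUCLEUS
        r_mid = (geometry.r1 + geometry.r2) / 2
        i = np.argmin(np.abs(toy_domain.xc - r_mid))
        assert mask[j, i] == CYTOPLASM

    def test_label_partition_covers_grid(self, toy_domain):
        n = sum(len(toy_domain.indices(lab)) for lab in (NUCLEUS, CYTOPLASM, EXTERIOR))
        assert n == toy_domain.nx * toy_domain.ny

    def test_nucleus_area_converges_under_refinement(self, geometry):
        errors = []
        for nx in (41, 82, 164, 328):
            dom = na.build_domain(geometry, nx, nx)
            area = len(dom.indices(NUCLEUS)) * dom.cell_area
            errors.append(abs(area - np.pi * geometry.r1 ** 2) / (np.pi * geometry.r1 ** 2))
        assert errors == sorted(errors, reverse=True)
        assert errors[-1] < errors[0]

    def test_faces_join_distinct_compartments_once(self, toy_domain):
        mask = toy_domain.mask.ravel()
        faces = toy_domain.nuclear_faces
        assert np.all(mask[faces[:, 0]] == CYTOPLASM)
        assert np.all(mask[faces[:, 1]] == NUCLEUS)
        keys = {tuple(sorted(f)) for f in faces.tolist()}
        assert len(keys) == len(faces)
        outer = toy_domain.outer_faces
        assert np.all(mask[outer[:, 0]] == CYTOPLASM)
        assert np.all(mask[outer[:, 1]] == EXTERIOR)

    def test_non_nested_geometry_rejected(self):
        with pytest.raises(na.GeometryError):
            na.CellGeometry(p1=(0.8, 0), r1=0.3, p2=(0, 0), r2=0.9,
                            p3=(0.3, 0), r3=0.05, Ec_init=1.0)

    def test_too_coarse_grid_rejected(self):
        tiny = na.CellGeometry(p1=(0, 0), r1=0.01, p2=(0, 0), r2=0.9,
                               p3=(0.05, 0), r3=0.01, Ec_init=1.0)
        with pytest.raises(na.GeometryError):
            na.build_domain(tiny, 8, 8)


class TestCatalyticField:
    def test_field_restricted_to_cytoplasmic_ball(self, geometry, toy_domain):
        # region deliberately overlapping the nucleus: nuclear cells stay zero
        geom = geometry.replace(p3=(0.3, 0.0), r3=0.15)
        field = na.initialize_catalytic_field(toy_domain, geom)
        X, Y = np.meshgrid(toy_domain.xc, toy_domain.yc)
        dist = np.hypot(X - 0.3, Y)
        assert np.any((dist < 0.15) & (toy_domain.mask == NUCLEUS))
        assert np.all(field[toy_domain.mask == NUCLEUS] == 0.0)
        # cells that cannot intersect the ball carry nothing
        assert np.all(field[dist > 0.15 + toy_domain.h] == 0.0)
        assert np.all(field >= 0.0)
        assert field.max() > 0.0

    def test_total_mass_matches_continuum_region_area_exactly(self, geometry, toy_domain):
        # tangent default placement: the region is the full ball
        field = na.initialize_catalytic_field(toy_domain, geometry)
        total = field.sum() * toy_domain.cell_area
        assert total == pytest.approx(
            geometry.Ec_init * np.pi * geometry.r3 ** 2, rel=1e-12)

    def test_total_mass_excludes_nuclear_overlap(self, geometry, toy_domain):
        # ball centred on the nuclear surface: exactly half its area overlaps
        geom = geometry.replace(p3=(0.3, 0.0), r3=0.05)
        field = na.initialize_catalytic_field(toy_domain, geom)
        total = field.sum() * toy_domain.cell_area
        half_moon = np.pi * 0.05 ** 2 - na.geometry._circle_overlap_area(0.3, 0.05, 0.3)
        assert total == pytest.approx(geom.Ec_init * half_moon, rel=1e-12)
        assert half_moon < np.pi * 0.05 ** 2

    def test_mass_is_grid_independent(self, geometry):
        totals = []
        for nx in (41, 82, 164):
            dom = na.build_domain(geometry, nx, nx)
            totals.append(na.initialize_catalytic_field(dom, geometry).sum()
                          * dom.cell_area)
        np.testing.assert_allclose(totals, totals[0], rtol=1e-12)

    def test_zero_initial_value_gives_zero_field(self, geometry, toy_domain):
        field = na.initialize_catalytic_field(
            toy_domain, geometry.replace(Ec_init=0.0))
        assert np.all(field == 0.0)


class TestRelocation:
    def test_tangent_placement_identity(self, geometry):
        g0 = na.place_region_at_distance(geometry, 0.0)
        dist = np.hypot(g0.p3[0] - g0.p1[0], g0.p3[1] - g0.p1[1])
        assert dist == pytest.approx(geometry.r1 + geometry.r3)

    def test_protruding_placement_rejected(self, geometry):
        with pytest.raises(na.GeometryError):
            na.place_region_at_distance(geometry, 10.0)

    def test_max_distance_is_admissible_boundary(self, geometry):
        dmax = na.max_region_distance(geometry)
        na.place_region_at_distance(geometry, dmax)  # does not raise
        with pytest.raises(na.GeometryError):
            na.place_region_at_distance(geometry, dmax + 0.01)

    def test_relocation_preserves_catalytic_mass_exactly(self, geometry):
        domain = na.build_domain(geometry, 164, 164)
        dmax = na.max_region_distance(geometry)
        m0 = na.initialize_catalytic_field(domain, geometry).sum() * domain.cell_area
        g1 = na.place_region_at_distance(geometry, dmax)
        m1 = na.initialize_catalytic_field(domain, g1).sum() * domain.cell_area
        assert m1 == pytest.approx(m0, rel=1e-12)
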
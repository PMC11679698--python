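"""Projection, IDW interpolation, percentile classes, crowns, quadrants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from biomon.spatial import (crown_profile, idw, idw_interpolate,
                            percentile_classes, project_local, quadrant_compare)
from biomon.survey import Site

from conftest import build_survey


def _haversine_m(lon1, lat1, lon2, lat2, R=6_371_000.0):
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi, dlmb = p2 - p1, np.radians(lon2 - lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    return 2 * R * np.arcsin(np.sqrt(a))


class TestProjection:
    def test_matches_haversine_on_meridian(self):
        lon = np.array([-9.0, -9.0])
        lat = np.array([38.6, 38.609])
        x, y = project_local(lon, lat)
        d = np.hypot(x[1] - x[0], y[1] - y[0])
        expect = _haversine_m(-9.0, 38.6, -9.0, 38.609)
        assert d == pytest.approx(expect, abs=0.5)
        assert expect == pytest.approx(1000.6, abs=1.0)

    def test_zero_distance_and_symmetry(self):
        x, y = project_local(np.array([-9.0, -9.02]), np.array([38.6, 38.61]))
        assert np.hypot(x[0] - x[0], y[0] - y[0]) == 0.0
        d_ab = np.hypot(x[1] - x[0], y[1] - y[0])
        d_ba = np.hypot(x[0] - x[1], y[0] - y[1])
        assert d_ab == d_ba


class TestIdw:
    def test_hand_evaluated_weighting(self):
        # values 0 and 3 at distances 1 m and 2 m, k=2 -> (0*1 + 3*0.25)/1.25
        pts = np.array([[1.0, 0.0], [2.0, 0.0]])
        out = idw(pts, np.array([0.0, 3.0]), np.array([[0.0, 0.0]]), k=2)
        assert out[0] == pytest.approx(0.6)

    def test_single_sample_constant_surface(self):
        out = idw(np.array([[5.0, 5.0]]), np.array([7.0]),
                  np.array([[0.0, 0.0], [100.0, -3.0]]))
        assert np.allclose(out, 7.0)

    def test_equidistant_mean(self):
        pts = np.array([[-1.0, 0.0], [1.0, 0.0]])
        out = idw(pts, np.array([2.0, 10.0]), np.array([[0.0, 0.0]]))
        assert out[0] == pytest.approx(6.0)

    def test_exact_at_samples_and_bounded(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 1000, (20, 2))
        vals = rng.uniform(5, 50, 20)
        at_samples = idw(pts, vals, pts)
        assert np.allclose(at_samples, vals)
        queries = rng.uniform(0, 1000, (200, 2))
        est = idw(pts, vals, queries)
        assert est.min() >= vals.min() - 1e-12
        assert est.max() <= vals.max() + 1e-12

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.floats(-100, 100))
    def test_constant_shift_invariance(self, c):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 100, (8, 2))
        vals = rng.uniform(1, 9, 8)
        q = rng.uniform(0, 100, (30, 2))
        assert np.allclose(idw(pts, vals + c, q), idw(pts, vals, q) + c,
                           atol=1e-9)

    def test_surface_classes_use_sample_percentiles(self, leaf_survey):
        surf = idw_interpolate(leaf_survey, "Fe", cell_size=(300.0, 300.0))
        expect = np.percentile(leaf_survey.exposure["Fe"], [20, 40, 60, 80])
        assert np.allclose(surf.class_edges, expect)
        assert surf.values.min() >= leaf_survey.exposure["Fe"].min() - 1e-9
        assert surf.values.max() <= leaf_survey.exposure["Fe"].max() + 1e-9

    def test_ascii_grid_round_trip(self, leaf_survey, tmp_path):
        surf = idw_interpolate(leaf_survey, "Fe", cell_size=(500.0, 500.0))
        path = tmp_path / "fe.asc"
        surf.to_ascii_grid(path)
        lines = path.read_text().splitlines()
        assert lines[0].split() == ["ncols", str(surf.values.shape[1])]
        body = np.loadtxt(lines[6:])
        assert np.allclose(body[::-1], surf.values, rtol=1e-5)


class TestPercentileClasses:
    def test_edges_for_1_to_10(self):
        classes, edges = percentile_classes(np.arange(1.0, 11.0))
        assert np.allclose(edges, [2.8, 4.6, 6.4, 8.2])
        assert classes.min() == 0 and classes.max() == 4

    def test_constant_vector_single_class_with_warning(self):
        with pytest.warns(UserWarning, match="distinct"):
            classes, _ = percentile_classes(np.full(6, 3.0))
        assert len(set(classes.tolist())) == 1

    def test_uniform_sample_balanced_classes(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(size=1000)
        classes, _ = percentile_classes(v)
        counts = np.bincount(classes, minlength=5)
        assert counts.min() > 150 and counts.max() < 250

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            percentile_classes(np.array([1.0, 2.0, 3.0]))


def _survey_at(points, values, center=(-9.0, 38.6)):
    """Survey with 4-element panel, Fe set per site, sites at given local offsets."""
    lon0, lat0 = center
    sites = []
    rows = []
    for i, ((dx, dy), v) in enumerate(zip(points, values)):
        lon = lon0 + dx / (111_195.0 * np.cos(np.radians(lat0)))
        lat = lat0 + dy / 111_195.0
        sites.append(Site(f"S{i}", lon, lat, "exposure"))
        rows.append([100.0, v, 10.0, 30.0])
    sites.append(Site("BG", lon0 - 0.2, lat0, "background"))
    rows.append([120.0, 400.0, 6.0, 25.0])
    return build_survey(rows, sites=sites)


class TestCrowns:
    def test_exact_exponential_recovered(self):
        d = np.array([500.0, 1500.0, 2500.0, 3500.0, 4500.0])  # ring midpoints, m
        vals = 10.0 * np.exp(-0.5 * d / 1000.0)
        survey = _survey_at([(x, 0.0) for x in d], vals)
        prof = crown_profile(survey, "Fe", (-9.0, 38.6))
        assert prof.fit_a == pytest.approx(10.0, rel=1e-3)
        assert prof.fit_b == pytest.approx(0.5, rel=1e-3)
        assert prof.r2 == pytest.approx(1.0, abs=1e-6)

    def test_refit_of_fitted_model_is_perfect(self):
        d = np.array([500.0, 1500.0, 2500.0, 3500.0, 4500.0])
        vals = 7.3 * np.exp(-0.31 * d / 1000.0)
        survey = _survey_at([(x, 0.0) for x in d], vals)
        prof = crown_profile(survey, "Fe", (-9.0, 38.6))
        refit_vals = prof.predict(d / 1000.0)
        survey2 = _survey_at([(x, 0.0) for x in d], refit_vals)
        prof2 = crown_profile(survey2, "Fe", (-9.0, 38.6))
        assert prof2.r2 == pytest.approx(1.0, abs=1e-9)

    def test_single_ring_reports_mean_without_fit(self):
        survey = _survey_at([(300.0, 0.0), (0.0, 400.0)], [5.0, 7.0])
        with pytest.warns(UserWarning, match="empty ring"):
            prof = crown_profile(survey, "Fe", (-9.0, 38.6))
        assert prof.fit_b is None
        assert prof.ring_means[0] == pytest.approx(6.0)

    def test_ring_assignment_right_closed(self):
        survey = _survey_at([(1000.0, 0.0), (1000.5, 0.0)], [5.0, 9.0])
        prof = crown_profile(survey, "Fe", (-9.0, 38.6), ring_edges=(1.0, 2.0))
        # d = 1.000 km goes to the first ring; 1.0005 km to the second
        assert prof.ring_counts.tolist() == [1, 1]


class TestQuadrants:
    def test_hand_computed_kruskal_wallis(self):
        # three quadrants holding 1-3, 4-6, 7-9: rank sums 6/15/24 -> H = 7.2
        pts = [(100, 100), (200, 150), (150, 250),        # NE
               (100, -100), (200, -150), (150, -250),     # SE
               (-100, -100), (-200, -150), (-150, -250)]  # SW
        vals = [1, 2, 3, 4, 5, 6, 7, 8, 9]
        survey = _survey_at(pts, vals)
        q = quadrant_compare(survey, "Fe", (-9.0, 38.6))
        assert q.h == pytest.approx(7.2)
        assert set(q.labels.unique()) == {"NE", "SE", "SW"}

    def test_rotation_permutes_labels_cyclically(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(-900, 900, (12, 2))
        vals = rng.uniform(1, 9, 12)
        survey = _survey_at([tuple(p) for p in pts], vals, center=(0.0, 0.0))
        q1 = quadrant_compare(survey, "Fe", (0.0, 0.0))
        rot = [(p[1], -p[0]) for p in pts]          # rotate 90° clockwise
        survey2 = _survey_at(rot, vals, center=(0.0, 0.0))
        q2 = quadrant_compare(survey2, "Fe", (0.0, 0.0))
        nxt = {"NE": "SE", "SE": "SW", "SW": "NW", "NW": "NE"}
        for sid in q1.labels.index:
            assert q2.labels[sid] == nxt[q1.labels[sid]]

    def test_shifted_quadrant_detected(self):
        rng = np.random.default_rng(6)
        pts, vals = [], []
        for qx, qy, shift in [(1, 1, 0.0), (1, -1, 0.0), (-1, -1, 0.0), (-1, 1, 10.0)]:
            for _ in range(15):
                pts.append((qx * rng.uniform(50, 900), qy * rng.uniform(50, 900)))
                vals.append(50.0 + shift * 1.0 + rng.normal(0, 1))
        survey = _survey_at(pts, vals, center=(0.0, 0.0))
        q = quadrant_compare(survey, "Fe", (0.0, 0.0))
        assert q.p < 0.001
        row = q.pairwise[(q.pairwise.quadrant_a == "NE") & (q.pairwise.quadrant_b == "NW")]
        assert float(row["p"].iloc[0]) < 0.001

    def test_single_quadrant_rejected(self):
        survey = _survey_at([(100, 100), (200, 150), (150, 250)], [1, 2, 3])
        with pytest.raises(ValueError):
            quadrant_compare(survey, "Fe", (-9.0, 38.6))
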
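"""Geographic analyses: IDW interpolation, crown (ring) decay profiles, quadrants.

Coordinates are projected from WGS84 lon/lat onto a local plane with an
equirectangular projection about the mean latitude (x = R·Δλ·cos φ̄,
y = R·Δφ, R = 6 371 000 m); over the few-kilometre extent of a biomonitoring
grid the distance error versus great-circle distances is negligible.

The inverse-distance-weighted (IDW) estimate at a grid cell is

    v0 = Σ vᵢ·dᵢ⁻ᵏ / Σ dᵢ⁻ᵏ

over all S samples (global IDW, power k = 2 by default). Surfaces are classed
into quintiles of the *sampled* values, the usual percentile-class rendering
of biomonitoring maps.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .survey import ElementalSurvey, Site

__all__ = [
    "EARTH_RADIUS_M",
    "IdwSurface",
    "CrownProfile",
    "QuadrantSplit",
    "project_local",
    "idw",
    "idw_interpolate",
    "percentile_classes",
    "crown_profile",
    "quadrant_compare",
]

EARTH_RADIUS_M = 6_371_000.0


def project_local(lon: np.ndarray, lat: np.ndarray,
                  lon0: float | None = None, lat0: float | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Equirectangular projection to metres about (lon0, lat0) (defaults: mean)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lon0 = float(np.mean(lon)) if lon0 is None else lon0
    lat0 = float(np.mean(lat)) if lat0 is None else lat0
    x = EARTH_RADIUS_M * np.radians(lon - lon0) * np.cos(np.radians(lat0))
    y = EARTH_RADIUS_M * np.radians(lat - lat0)
    if x.size and (np.ptp(x) > 100_000 or np.ptp(y) > 100_000):
        warnings.warn("extent exceeds 100 km; equirectangular approximation degrades")
    return x, y


def _survey_xy(survey: ElementalSurvey, extra: Site | tuple[float, float] | None = None):
    """Project exposure sites (plus an optional extra point) to a shared plane."""
    coords = survey.coords(roles=("exposure",))
    lons = list(coords["lon"])
    lats = list(coords["lat"])
    if extra is not None:
        elon, elat = (extra.lon, extra.lat) if isinstance(extra, Site) else extra
        lons.append(elon)
        lats.append(elat)
    x, y = project_local(np.array(lons), np.array(lats))
    if extra is not None:
        return x[:-1], y[:-1], (x[-1], y[-1]), list(coords.index)
    return x, y, None, list(coords.index)


# ---------------------------------------------------------------------------
# IDW
# ---------------------------------------------------------------------------

def idw(points_xy: np.ndarray, values: np.ndarray, query_xy: np.ndarray,
        k: float = 2.0, eps: float = 1e-6) -> np.ndarray:
    """Global inverse-distance-weighted estimate at each query point.

    Every sample contributes with weight d⁻ᵏ; a query within ``eps`` metres of
    a sample takes that sample's value exactly. Being a convex combination,
    estimates are bounded by the sample min/max.
    """
    points_xy = np.atleast_2d(np.asarray(points_xy, dtype=float))
    values = np.asarray(values, dtype=float)
    if points_xy.shape[0] == 0:
        raise ValueError("no sample points")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite sample values")
    d = cdist(np.atleast_2d(query_xy), points_xy)
    out = np.empty(d.shape[0])
    exact = d < eps
    with np.errstate(divide="ignore"):
        w = d ** (-k)
    for i in range(d.shape[0]):
        if exact[i].any():
            out[i] = values[np.argmin(d[i])]
        else:
            wi = w[i]
            out[i] = float((wi * values).sum() / wi.sum())
    return out


@dataclass
class IdwSurface:
    x_centers: np.ndarray            # metres, cell centres (ascending)
    y_centers: np.ndarray
    values: np.ndarray               # (ny, nx), row 0 = southernmost row
    classes: np.ndarray              # quintile class indices 0–4
    class_edges: np.ndarray          # 20/40/60/80th percentile cuts
    k: float
    n_samples: int
    cell_size: tuple[float, float]
    element: str = ""

    def to_ascii_grid(self, path) -> None:
        """ESRI ASCII raster (requires square cells)."""
        cx, cy = self.cell_size
        if abs(cx - cy) > 1e-9:
            raise ValueError("ESRI ASCII export requires square cells")
        ny, nx = self.values.shape
        header = (
            f"ncols {nx}\nnrows {ny}\n"
            f"xllcorner {self.x_centers[0] - cx / 2:.3f}\n"
            f"yllcorner {self.y_centers[0] - cy / 2:.3f}\n"
            f"cellsize {cx:.3f}\nNODATA_value -9999\n"
        )
        body = "\n".join(
            " ".join(f"{v:.6g}" for v in row) for row in self.values[::-1]
        )
        with open(path, "w") as fh:
            fh.write(header + body + "\n")

    def to_geojson(self, path) -> None:
        """Cell polygons with value and quintile class attributes (local metres)."""
        cx, cy = self.cell_size
        feats = []
        for iy, yc in enumerate(self.y_centers):
            for ix, xc in enumerate(self.x_centers):
                ring = [
                    [xc - cx / 2, yc - cy / 2], [xc + cx / 2, yc - cy / 2],
                    [xc + cx / 2, yc + cy / 2], [xc - cx / 2, yc + cy / 2],
                    [xc - cx / 2, yc - cy / 2],
                ]
                feats.append({
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                    "properties": {"value": float(self.values[iy, ix]),
                                   "class": int(self.classes[iy, ix])},
                })
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)


def percentile_classes(values: np.ndarray, sample_values: np.ndarray | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Quintile classes with edges at the 20/40/60/80th sample percentiles.

    Edges come from ``sample_values`` (the measured stations) when given,
    otherwise from ``values`` itself; linear-interpolation quantiles,
    right-closed intervals (value ≤ edge falls in the lower class).
    """
    values = np.asarray(values, dtype=float)
    ref = values if sample_values is None else np.asarray(sample_values, dtype=float)
    ref = ref[np.isfinite(ref)]
    if ref.size < 5:
        raise ValueError("need at least 5 finite values for quintile classes")
    if np.unique(ref).size < 5:
        warnings.warn("fewer than 5 distinct values; degenerate class edges")
    edges = np.percentile(ref, [20, 40, 60, 80], method="linear")
    classes = np.searchsorted(edges, values, side="left")
    return classes, edges


def idw_interpolate(survey: ElementalSurvey, element: str,
                    cell_size: tuple[float, float] = (65.0, 65.0),
                    k: float = 2.0, pad_m: float = 0.0) -> IdwSurface:
    """Interpolate one element over a regular grid spanning the exposure sites."""
    if element not in survey.panel.elements:
        raise KeyError(element)
    x, y, _, ids = _survey_xy(survey)
    vals = survey.exposure[element].to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("impute censored cells before interpolation")
    cx, cy = cell_size
    x0, x1 = x.min() - pad_m, x.max() + pad_m
    y0, y1 = y.min() - pad_m, y.max() + pad_m
    nx = max(int(np.ceil((x1 - x0) / cx)), 1)
    ny = max(int(np.ceil((y1 - y0) / cy)), 1)
    xc = x0 + (np.arange(nx) + 0.5) * cx
    yc = y0 + (np.arange(ny) + 0.5) * cy
    gx, gy = np.meshgrid(xc, yc)
    grid = idw(np.column_stack([x, y]), vals,
               np.column_stack([gx.ravel(), gy.ravel()]), k=k).reshape(ny, nx)
    classes, edges = percentile_classes(grid, sample_values=vals)
    return IdwSurface(xc, yc, grid, classes, edges, k, len(vals), (cx, cy), element)


# ---------------------------------------------------------------------------
# crown profiles
# ---------------------------------------------------------------------------

@dataclass
class CrownProfile:
    element: str
    center: tuple[float, float]          # lon, lat
    ring_edges: np.ndarray               # km, outer edges
    ring_mids: np.ndarray                # km, midpoints of non-empty rings
    ring_means: np.ndarray               # mean concentration per non-empty ring
    ring_counts: np.ndarray
    fit_a: float | None
    fit_b: float | None                  # decay rate, km⁻¹
    r2: float | None                     # on the fitted (log) scale

    def predict(self, d_km: np.ndarray) -> np.ndarray:
        if self.fit_a is None:
            raise ValueError("no fitted decay model")
        return self.fit_a * np.exp(-self.fit_b * np.asarray(d_km, dtype=float))


def crown_profile(survey: ElementalSurvey, element: str,
                  center: Site | tuple[float, float],
                  ring_edges: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
                  ) -> CrownProfile:
    """Mean concentration in concentric rings about a source, with an
    exponential decay fit c = a·e^(−b·d).

    Rings are right-closed, (edge_{i−1}, edge_i] in km; sites beyond the outer
    edge are excluded. The fit is ordinary least squares of ln(ring mean) on
    the ring midpoint distance; r² is reported on that log scale. With fewer
    than two non-empty rings the means are still reported but no model is fit.
    """
    edges = np.asarray(ring_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 1 or np.any(np.diff(edges) <= 0):
        raise ValueError("ring edges must be strictly increasing")
    x, y, c_xy, ids = _survey_xy(survey, extra=center)
    d_km = np.hypot(x - c_xy[0], y - c_xy[1]) / 1000.0
    vals = survey.exposure[element].to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("impute censored cells before the crown profile")
    idx = np.searchsorted(edges, d_km, side="left")   # ring i: (e_{i-1}, e_i]
    lows = np.concatenate([[0.0], edges[:-1]])
    mids, means, counts = [], [], []
    for i in range(len(edges)):
        sel = idx == i
        if d_km[sel].size == 0:
            warnings.warn(f"empty ring ({lows[i]:g}, {edges[i]:g}] km skipped")
            continue
        mids.append((lows[i] + edges[i]) / 2.0)
        means.append(float(vals[sel].mean()))
        counts.append(int(sel.sum()))
    mids_a, means_a = np.array(mids), np.array(means)
    fit_a = fit_b = r2 = None
    if len(means_a) >= 2:
        if np.any(means_a <= 0):
            raise ValueError("non-positive ring mean; cannot fit exponential decay")
        logm = np.log(means_a)
        slope, intercept = np.polyfit(mids_a, logm, 1)
        fit_a, fit_b = float(np.exp(intercept)), float(-slope)
        resid = logm - (intercept + slope * mids_a)
        ss_tot = float(((logm - logm.mean()) ** 2).sum())
        r2 = 1.0 if ss_tot == 0 else float(1.0 - (resid**2).sum() / ss_tot)
    center_ll = (center.lon, center.lat) if isinstance(center, Site) else tuple(center)
    return CrownProfile(element, center_ll, edges, mids_a, means_a,
                        np.array(counts), fit_a, fit_b, r2)


# ---------------------------------------------------------------------------
# quadrants
# ---------------------------------------------------------------------------

_QUADRANTS = ("NE", "SE", "SW", "NW")


@dataclass
class QuadrantSplit:
    element: str
    labels: pd.Series                    # site_id -> quadrant
    h: float
    p: float
    pairwise: pd.DataFrame               # quadrant_a, quadrant_b, h, p, p_bonferroni


def quadrant_compare(survey: ElementalSurvey, element: str,
                     center: Site | tuple[float, float],
                     bonferroni: bool = False) -> QuadrantSplit:
    """Kruskal–Wallis comparison of an element across compass quadrants.

    Quadrant labels use the bearing from the center: NE = [0°, 90°),
    SE = [90°, 180°), SW = [180°, 270°), NW = [270°, 360°). Pairwise
    follow-ups are two-group Kruskal–Wallis tests, unadjusted by default.
    """
    x, y, c_xy, ids = _survey_xy(survey, extra=center)
    bearing = np.degrees(np.arctan2(x - c_xy[0], y - c_xy[1])) % 360.0
    labels = pd.Series([_QUADRANTS[int(b // 90.0)] for b in bearing], index=ids)
    vals = survey.exposure[element]
    if vals.isna().any():
        raise ValueError("impute censored cells before the quadrant comparison")
    groups = {q: vals[labels[labels == q].index].to_numpy(dtype=float)
              for q in _QUADRANTS if (labels == q).sum() > 0}
    usable = {q: g for q, g in groups.items() if g.size >= 2}
    if len(usable) < 2:
        raise ValueError("need at least 2 quadrants with at least 2 sites")
    h, p = stats.kruskal(*usable.values())
    pairs = []
    names = list(usable)
    n_pairs = len(names) * (len(names) - 1) // 2
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            hp, pp = stats.kruskal(usable[a], usable[b])
            pairs.append((a, b, float(hp), float(pp), min(1.0, float(pp) * n_pairs)))
    pairwise = pd.DataFrame(pairs, columns=["quadrant_a", "quadrant_b", "h", "p",
                                            "p_bonferroni"])
    if not bonferroni:
        pairwise = pairwise.drop(columns="p_bonferroni")
    return QuadrantSplit(element, labels, float(h), float(p), pairwise)
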
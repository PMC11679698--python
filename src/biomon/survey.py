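"""Data model for elemental biomonitoring surveys.

A survey is a site-by-element concentration matrix (mg·kg⁻¹ dry weight) with
site coordinates, a single designated background site, a left-censoring mask
for below-detection-limit cells, and per-element detection limits. All
downstream stages (enrichment, source apportionment, mapping, biomonitor
comparison) consume this container.

Censored cells hold NaN until :func:`impute_censored` substitutes DL/2, the
standard single-value substitution for left-censored concentration data in
mapping workflows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Site",
    "ElementPanel",
    "ElementalSurvey",
    "CrustalReference",
    "DEFAULT_PANEL",
    "default_crustal_reference",
    "read_survey",
    "write_survey",
    "impute_censored",
    "summarize",
]

SITE_ROLES = ("exposure", "background", "source", "control")

#: The default 22-element XRF analyte panel, grouped as macro elements
#: (structural elements and plant macronutrients), micro elements
#: (micronutrients plus Cl/Al), and non-essential trace elements.
_PANEL_GROUPS: dict[str, tuple[str, ...]] = {
    "macro": ("K", "Ca", "Mg", "Si", "P", "S"),
    "micro": ("Cl", "Fe", "Al", "Mn", "Zn", "Cu"),
    "trace": ("Sr", "Ba", "As", "Ti", "Br", "Rb", "Zr", "Se", "Cr", "Pb"),
}


@dataclass(frozen=True)
class Site:
    """A georeferenced sampling location (WGS84 decimal degrees)."""

    site_id: str
    lon: float
    lat: float
    role: str = "exposure"

    def __post_init__(self) -> None:
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"site {self.site_id!r}: lon {self.lon} outside [-180, 180]")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"site {self.site_id!r}: lat {self.lat} outside [-90, 90]")
        if self.role not in SITE_ROLES:
            raise ValueError(f"site {self.site_id!r}: unknown role {self.role!r}")


@dataclass(frozen=True)
class ElementPanel:
    """Ordered analyte list with a macro/micro/trace category per element."""

    elements: tuple[str, ...]
    category: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.elements)) != len(self.elements):
            raise ValueError("element symbols must be unique")

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)


def _default_panel() -> ElementPanel:
    elements: list[str] = []
    category: dict[str, str] = {}
    for cat, syms in _PANEL_GROUPS.items():
        for s in syms:
            elements.append(s)
            category[s] = cat
    return ElementPanel(tuple(elements), category)


DEFAULT_PANEL: ElementPanel = _default_panel()


@dataclass
class ElementalSurvey:
    """Site×element concentration matrix with censoring metadata.

    ``concentrations`` is indexed by site_id with one column per panel
    element; cells flagged in ``censored`` are below the element's detection
    limit and hold NaN until imputation (then DL/2).
    """

    sites: tuple[Site, ...]
    panel: ElementPanel
    concentrations: pd.DataFrame
    censored: pd.DataFrame
    detection_limits: dict[str, float] = field(default_factory=dict)
    biomonitor_label: str = "strawberry_leaf"
    imputed: bool = False

    def __post_init__(self) -> None:
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate site ids: {dupes}")
        n_bg = sum(1 for s in self.sites if s.role == "background")
        if n_bg != 1:
            raise ValueError(
                "no background site" if n_bg == 0 else f"{n_bg} background sites; exactly one required"
            )
        if list(self.concentrations.index) != ids:
            raise ValueError("concentration matrix index must match site order")
        if list(self.concentrations.columns) != list(self.panel.elements):
            raise ValueError("concentration matrix columns must match the panel")
        if self.censored.shape != self.concentrations.shape:
            raise ValueError("censoring mask shape mismatch")
        vals = self.concentrations.to_numpy(dtype=float)
        mask = self.censored.to_numpy(dtype=bool)
        if np.any(vals[~mask] <= 0) or np.any(~np.isfinite(vals[~mask])):
            raise ValueError("uncensored concentrations must be strictly positive and finite")

    # -- convenience accessors -------------------------------------------------

    @property
    def background_id(self) -> str:
        return next(s.site_id for s in self.sites if s.role == "background")

    @property
    def exposure_ids(self) -> list[str]:
        return [s.site_id for s in self.sites if s.role == "exposure"]

    @property
    def exposure(self) -> pd.DataFrame:
        """Concentrations at exposure sites only (background excluded)."""
        return self.concentrations.loc[self.exposure_ids]

    @property
    def background(self) -> pd.Series:
        return self.concentrations.loc[self.background_id]

    def site(self, site_id: str) -> Site:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(site_id)

    def coords(self, roles: Iterable[str] = ("exposure",)) -> pd.DataFrame:
        rs = set(roles)
        rows = [(s.site_id, s.lon, s.lat) for s in self.sites if s.role in rs]
        return pd.DataFrame(rows, columns=["site_id", "lon", "lat"]).set_index("site_id")


@dataclass(frozen=True)
class CrustalReference:
    """Average crustal composition used as the enrichment-factor denominator."""

    abundances: Mapping[str, float]
    normalizing_element: str = "Al"
    provenance_label: str = "unspecified"

    def __post_init__(self) -> None:
        if self.normalizing_element not in self.abundances:
            raise ValueError(f"normalizing element {self.normalizing_element!r} missing from table")
        for el, v in self.abundances.items():
            if not v > 0:
                raise ValueError(f"non-positive crustal abundance for {el!r}")

    def ratio_to_normalizer(self, element: str) -> float:
        if element not in self.abundances:
            raise KeyError(f"element {element!r} absent from crustal reference")
        return self.abundances[element] / self.abundances[self.normalizing_element]


def default_crustal_reference(normalizing_element: str = "Al") -> CrustalReference:
    """Upper continental crust average (Rudnick & Gao 2003), mg·kg⁻¹."""
    with resources.files("biomon.data").joinpath("ucc_rudnick_gao_2003.csv").open() as fh:
        tab = pd.read_csv(fh)
    ab = dict(zip(tab["element"], tab["mg_per_kg"].astype(float)))
    return CrustalReference(ab, normalizing_element, "UCC (Rudnick & Gao 2003)")


def load_crustal_reference(path: str | Path, normalizing_element: str = "Al",
                           provenance_label: str | None = None) -> CrustalReference:
    tab = pd.read_csv(path)
    ab = dict(zip(tab["element"], tab["mg_per_kg"].astype(float)))
    return CrustalReference(ab, normalizing_element, provenance_label or str(path))


# -- readers / writers ---------------------------------------------------------

_META_COLS = ("site_id", "lon", "lat", "role")


def _parse_cell(raw: object, strict_empty: bool) -> tuple[float, bool]:
    """Return (value, censored). '<...' tokens and empty cells mean below-DL."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        if strict_empty:
            raise ValueError("empty concentration cell in strict mode")
        return np.nan, True
    text = str(raw).strip()
    if text == "":
        if strict_empty:
            raise ValueError("empty concentration cell in strict mode")
        return np.nan, True
    if text.startswith("<"):
        return np.nan, True
    return float(text), False


def read_survey(
    path: str | Path,
    panel: ElementPanel = DEFAULT_PANEL,
    dl_table: Mapping[str, float] | None = None,
    biomonitor_label: str = "strawberry_leaf",
    strict_empty: bool = False,
    units: Mapping[str, str] | None = None,
) -> ElementalSurvey:
    """Read a survey CSV (site_id, lon, lat, role, then one column per element).

    Below-DL entries are encoded as ``<DL`` (any ``<``-prefixed token) or, unless
    ``strict_empty``, an empty cell. ``units`` maps elements reported in g·kg⁻¹
    to ``"g_per_kg"``; those columns are converted to mg·kg⁻¹ on ingest.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    element_cols = [c for c in df.columns if c not in _META_COLS]
    unknown = [c for c in element_cols if c not in panel.elements]
    if unknown:
        raise ValueError(f"unknown element columns: {unknown}")
    absent = [e for e in panel.elements if e not in element_cols]
    if absent:
        raise ValueError(f"panel elements missing from file: {absent}")

    sites = tuple(
        Site(str(r.site_id), float(r.lon), float(r.lat), str(r.role))
        for r in df.itertuples()
    )
    vals = np.empty((len(df), len(panel)), dtype=float)
    mask = np.zeros_like(vals, dtype=bool)
    for j, el in enumerate(panel.elements):
        scale = 1000.0 if units and units.get(el) == "g_per_kg" else 1.0
        for i, raw in enumerate(df[el]):
            v, c = _parse_cell(raw, strict_empty)
            vals[i, j] = v * scale if not c else np.nan
            mask[i, j] = c
    ids = [s.site_id for s in sites]
    conc = pd.DataFrame(vals, index=ids, columns=list(panel.elements))
    cens = pd.DataFrame(mask, index=ids, columns=list(panel.elements))
    return ElementalSurvey(sites, panel, conc, cens,
                           dict(dl_table or {}), biomonitor_label)


def write_survey(survey: ElementalSurvey, path: str | Path, sidecar: bool = True) -> None:
    """Write a survey CSV plus a JSON metadata sidecar (units, DLs, provenance).

    Censored cells are written as ``<DL`` regardless of any imputed value, so
    the censoring mask round-trips exactly.
    """
    path = Path(path)
    rows = []
    for s in survey.sites:
        row: dict[str, object] = {"site_id": s.site_id, "lon": s.lon, "lat": s.lat, "role": s.role}
        for el in survey.panel.elements:
            if bool(survey.censored.loc[s.site_id, el]):
                row[el] = "<DL"
            else:
                row[el] = float(f"{survey.concentrations.loc[s.site_id, el]:.6g}")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    if sidecar:
        meta = {
            "units": "mg_per_kg_dry_weight",
            "biomonitor_label": survey.biomonitor_label,
            "detection_limits": survey.detection_limits,
            "imputation": "DL/2" if survey.imputed else "none",
            "censoring_encoding": "<DL",
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))


# -- censoring -----------------------------------------------------------------

def impute_censored(survey: ElementalSurvey) -> ElementalSurvey:
    """Substitute DL/2 for every censored cell; returns a new survey.

    Idempotent: imputing an already imputed survey changes nothing.
    """
    conc = survey.concentrations.copy()
    mask = survey.censored.to_numpy(dtype=bool)
    if mask.any():
        censored_elements = [
            el for j, el in enumerate(survey.panel.elements) if mask[:, j].any()
        ]
        no_dl = [el for el in censored_elements if el not in survey.detection_limits]
        if no_dl:
            raise ValueError(f"censored cells but no detection limit for: {no_dl}")
        for el in censored_elements:
            col = conc[el].to_numpy(dtype=float)
            col[survey.censored[el].to_numpy(dtype=bool)] = survey.detection_limits[el] / 2.0
            conc[el] = col
    return replace(survey, concentrations=conc, imputed=True)


# -- descriptive statistics ----------------------------------------------------

def summarize(survey: ElementalSurvey) -> pd.DataFrame:
    """Per-element descriptive statistics over exposure sites.

    ``n_above_dl`` counts uncensored cells; mean/sd/median/min/max are computed
    over uncensored values only, mirroring the convention of reporting
    detection-limited elements from their quantified samples.
    """
    ids = survey.exposure_ids
    if not ids:
        raise ValueError("survey has no exposure sites")
    out = {}
    for el in survey.panel.elements:
        cens = survey.censored.loc[ids, el].to_numpy(dtype=bool)
        vals = survey.concentrations.loc[ids, el].to_numpy(dtype=float)[~cens]
        if vals.size == 0:
            out[el] = dict(n_above_dl=0, mean=np.nan, sd=np.nan,
                           median=np.nan, min=np.nan, max=np.nan)
            continue
        out[el] = dict(
            n_above_dl=int(vals.size),
            mean=float(np.mean(vals)),
            sd=float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
            median=float(np.median(vals)),
            min=float(np.min(vals)),
            max=float(np.max(vals)),
        )
    tab = pd.DataFrame(out).T
    tab["n_above_dl"] = tab["n_above_dl"].astype(int)
    tab.index.name = "element"
    return tab
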
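"""Accumulation and enrichment factors for biomonitoring surveys.

The Accumulation Factor (AF) of element X at a site is the Al-normalized
concentration ratio between that site and the background site:

    AF_X = (C_X / C_ref)_site / (C_X / C_ref)_background

The Enrichment Factor (EF) replaces the background with an average crustal
composition:

    EF_X = (C_X / C_ref)_sample / (C_X / C_ref)_crust

Both are computed per sample; the reference element (Al by default, taken as
purely geogenic) has AF = EF = 1 identically. AF category thresholds at
1 / 2 / 5 / 20 / 40 grade the accumulation; EF mean < 10 indicates a
predominantly crustal origin, and an element counts as enriched when its mean
EF exceeds 3 with at least 30% of samples above 3.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survey import CrustalReference, ElementalSurvey

__all__ = [
    "AfCategory",
    "AccumulationResult",
    "EnrichmentResult",
    "accumulation_factor",
    "classify_af",
    "enrichment_factor",
    "modified_cv",
]


class AfCategory(enum.IntEnum):
    """Ordered accumulation grades; the order supports monotone comparison."""

    none = 0
    minimal = 1
    moderate = 2
    significant = 3
    very_high = 4
    extremely_high = 5


_AF_EDGES = np.array([1.0, 2.0, 5.0, 20.0, 40.0])


def classify_af(af: float) -> AfCategory:
    """Grade an accumulation factor.

    ≤1 none; (1,2) minimal; [2,5] moderate; (5,20] significant;
    (20,40] very high; >40 extremely high. The boundary AF=2 falls in the
    moderate class, matching the conventional "2–5" interval label.
    """
    if not af > 0:
        raise ValueError(f"AF must be positive, got {af}")
    if af <= 1.0:
        return AfCategory.none
    if af < 2.0:
        return AfCategory.minimal
    if af <= 5.0:
        return AfCategory.moderate
    if af <= 20.0:
        return AfCategory.significant
    if af <= 40.0:
        return AfCategory.very_high
    return AfCategory.extremely_high


def _classify_af_frame(af: pd.DataFrame) -> pd.DataFrame:
    return af.map(lambda v: classify_af(float(v)).name)


@dataclass
class AccumulationResult:
    af: pd.DataFrame                 # site×element, dimensionless
    category: pd.DataFrame           # site×element, category names
    mean_af: pd.Series
    sd_af: pd.Series
    from_imputed: pd.DataFrame       # True where the AF used a DL/2 cell
    reference_element: str

    def to_tidy(self) -> pd.DataFrame:
        long = self.af.stack().rename("af").reset_index()
        long.columns = ["site_id", "element", "af"]
        long["af_category"] = self.category.stack().to_numpy()
        long["from_imputed"] = self.from_imputed.stack().to_numpy()
        return long


@dataclass
class EnrichmentResult:
    ef: pd.DataFrame                 # site×element, dimensionless
    mean_ef: pd.Series
    sd_ef: pd.Series
    frac_above_3: pd.Series
    origin: pd.Series                # 'crustal' | 'anthropogenic'
    enriched_flag: pd.Series
    from_imputed: pd.DataFrame
    reference_element: str
    crust_provenance: str

    def to_tidy(self) -> pd.DataFrame:
        return pd.DataFrame({
            "element": self.mean_ef.index,
            "mean_ef": self.mean_ef.to_numpy(),
            "sd_ef": self.sd_ef.to_numpy(),
            "frac_above_3": self.frac_above_3.to_numpy(),
            "origin": self.origin.to_numpy(),
            "enriched": self.enriched_flag.to_numpy(),
        })


def _require_imputed(survey: ElementalSurvey) -> None:
    if survey.concentrations.isna().to_numpy().any():
        raise ValueError("survey contains unimputed censored cells; run impute_censored first")


def _normalized_ratios(conc: pd.DataFrame, reference_element: str) -> pd.DataFrame:
    if reference_element not in conc.columns:
        raise KeyError(f"reference element {reference_element!r} not in panel")
    return conc.div(conc[reference_element], axis=0)


def accumulation_factor(survey: ElementalSurvey,
                        reference_element: str = "Al") -> AccumulationResult:
    """Per-sample accumulation factors relative to the background site."""
    _require_imputed(survey)
    bg = survey.background
    zero_bg = [el for el in survey.panel.elements if not bg[el] > 0]
    if zero_bg:
        raise ValueError(f"non-positive background concentration for: {zero_bg}")
    ratios = _normalized_ratios(survey.exposure, reference_element)
    bg_ratio = bg / bg[reference_element]
    af = ratios.div(bg_ratio, axis=1)
    cens = survey.censored
    from_imp = (
        cens.loc[survey.exposure_ids]
        | cens.loc[survey.exposure_ids, [reference_element]].to_numpy()
        | cens.loc[survey.background_id]
    )
    return AccumulationResult(
        af=af,
        category=_classify_af_frame(af),
        mean_af=af.mean(axis=0),
        sd_af=af.std(axis=0, ddof=1),
        from_imputed=from_imp,
        reference_element=reference_element,
    )


def enrichment_factor(survey: ElementalSurvey,
                      crust: CrustalReference) -> EnrichmentResult:
    """Per-sample enrichment factors against an average crustal composition."""
    _require_imputed(survey)
    ref = crust.normalizing_element
    missing = [el for el in survey.panel.elements if el not in crust.abundances]
    if missing:
        raise KeyError(f"elements absent from crustal reference: {missing}")
    ratios = _normalized_ratios(survey.exposure, ref)
    crust_ratio = pd.Series(
        {el: crust.ratio_to_normalizer(el) for el in survey.panel.elements}
    )
    ef = ratios.div(crust_ratio, axis=1)
    mean_ef = ef.mean(axis=0)
    frac = (ef > 3.0).mean(axis=0)
    cens = survey.censored
    from_imp = (
        cens.loc[survey.exposure_ids]
        | cens.loc[survey.exposure_ids, [ref]].to_numpy()
    )
    return EnrichmentResult(
        ef=ef,
        mean_ef=mean_ef,
        sd_ef=ef.std(axis=0, ddof=1),
        frac_above_3=frac,
        origin=pd.Series(np.where(mean_ef < 10.0, "crustal", "anthropogenic"),
                         index=mean_ef.index),
        enriched_flag=(mean_ef > 3.0) & (frac >= 0.30),
        from_imputed=from_imp,
        reference_element=ref,
        crust_provenance=crust.provenance_label,
    )


def modified_cv(survey: ElementalSurvey) -> pd.Series:
    """Modified coefficient of variation: sd / median, per element.

    Computed over exposure-site concentrations (DL/2-imputed). High values flag
    spatially heterogeneous, anthropogenically influenced elements; scale
    invariant, so unit changes do not affect it.
    """
    _require_imputed(survey)
    mat = survey.exposure
    med = mat.median(axis=0)
    zero = [el for el in med.index if not med[el] > 0]
    if zero:
        raise ValueError(f"zero median concentration for: {zero}")
    return mat.std(axis=0, ddof=1) / med
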
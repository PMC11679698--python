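"""End-to-end pipeline: impute → descriptives → AF/EF/CV → background tests →
correlations → PCA → spatial → biomonitor comparison, driven by a YAML config.

Every stage writes tidy CSV outputs into the run directory and the whole run
is summarized in a JSON report. All randomness flows from the single seed in
the config, so re-running an identical config reproduces identical numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .apportionment import apportion, spearman_screen
from .comparison import compare_biomonitors
from .enrichment import accumulation_factor, enrichment_factor, modified_cv
from .spatial import crown_profile, idw_interpolate, quadrant_compare
from .survey import (ElementalSurvey, default_crustal_reference, impute_censored,
                     load_crustal_reference, read_survey, summarize, write_survey)
from .synth import SyntheticConfig, generate

log = logging.getLogger("biomon.pipeline")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "compare_to_background"]

_KNOWN_KEYS = {
    "synth", "inputs", "output_dir", "stages", "params",
}
_KNOWN_STAGES = {"summary", "enrichment", "background", "correlation",
                 "pca", "spatial", "comparison"}
_KNOWN_PARAMS = {"msa_threshold", "eigen_cut", "loading_threshold", "keep",
                 "max_sweeps", "idw_k", "cell_size", "idw_elements",
                 "ring_edges", "crown_elements", "crown_center",
                 "quadrant_element", "n_perm", "seed", "alpha",
                 "reference_element"}


@dataclass
class PipelineConfig:
    output_dir: str = "biomon_run"
    synth: dict | None = None              # SyntheticConfig overrides, or None
    inputs: dict = field(default_factory=dict)
    stages: dict[str, bool] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        stages = raw.get("stages") or {}
        bad = set(stages) - _KNOWN_STAGES
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        params = raw.get("params") or {}
        badp = set(params) - _KNOWN_PARAMS
        if badp:
            raise ValueError(f"unknown params: {sorted(badp)}")
        return cls(output_dir=raw.get("output_dir", "biomon_run"),
                   synth=raw.get("synth"), inputs=raw.get("inputs") or {},
                   stages=dict(stages), params=dict(params))

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    output_dir: str
    config_hash: str
    version: str
    stages_run: list[str]
    outputs: dict[str, str]
    notes: list[str]
    tables: dict[str, pd.DataFrame] = field(default_factory=dict, repr=False)

    def to_json(self, path: str | Path) -> None:
        payload = {k: v for k, v in dataclasses.asdict(self).items() if k != "tables"}
        Path(path).write_text(json.dumps(payload, indent=2))


def compare_to_background(survey: ElementalSurvey, alpha: float = 0.05
                          ) -> pd.DataFrame:
    """Per-element test of exposure-site concentrations against the background value.

    The single-background design makes this a one-sample problem on the
    differences (site − background): Shapiro–Wilk routes to a one-sample
    t-test or a Wilcoxon signed-rank test. Direction is by median difference.
    """
    bg = survey.background
    rows = []
    for el in survey.panel.elements:
        x = survey.exposure[el].to_numpy(dtype=float)
        if np.isnan(x).any() or not np.isfinite(bg[el]):
            raise ValueError(f"{el}: impute censored cells before background tests")
        d = x - float(bg[el])
        med = float(np.median(d))
        direction = "none" if med == 0 else ("higher" if med > 0 else "lower")
        if np.ptp(d) == 0:
            p, route, stat = (1.0, "degenerate", 0.0)
            if d[0] != 0:        # constant but nonzero offset: sign is exact
                p = 2.0 ** (1 - len(d))
        elif stats.shapiro(d).pvalue >= alpha:
            res = stats.ttest_1samp(d, 0.0)
            p, route, stat = float(res.pvalue), "t_test", float(res.statistic)
        else:
            res = stats.wilcoxon(d, zero_method="pratt")
            p, route, stat = float(res.pvalue), "wilcoxon", float(res.statistic)
        rows.append({"element": el, "route": route, "statistic": stat,
                     "p": p, "direction": direction,
                     "significant": bool(p < alpha)})
    return pd.DataFrame(rows)


def _load_inputs(cfg: PipelineConfig):
    p = cfg.params
    if cfg.synth is not None:
        synth_cfg = SyntheticConfig(**cfg.synth)
        survey_a, survey_b, truth = generate(synth_cfg)
        crust = default_crustal_reference(p.get("reference_element", "Al"))
        return survey_a, survey_b, crust, truth
    inputs = cfg.inputs
    if "survey_a" not in inputs:
        raise ValueError("config needs either a synth block or inputs.survey_a")
    dl = {}
    if inputs.get("dl_table"):
        tab = pd.read_csv(inputs["dl_table"])
        dl = dict(zip(tab["element"], tab["dl_mg_per_kg"].astype(float)))
    survey_a = read_survey(inputs["survey_a"], dl_table=dl)
    survey_b = (read_survey(inputs["survey_b"], dl_table=dl,
                            biomonitor_label="lichen")
                if inputs.get("survey_b") else None)
    crust = (load_crustal_reference(inputs["crust"])
             if inputs.get("crust")
             else default_crustal_reference(p.get("reference_element", "Al")))
    return survey_a, survey_b, crust, None


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all enabled stages; any stage failure aborts with a named error."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = config.params
    seed = int(p.get("seed", 0))
    alpha = float(p.get("alpha", 0.05))
    ref_el = p.get("reference_element", "Al")
    outputs: dict[str, str] = {}
    tables: dict[str, pd.DataFrame] = {}
    notes: list[str] = []
    stages_run: list[str] = []

    def _save(name: str, frame: pd.DataFrame, index: bool = False) -> None:
        path = out / f"{name}.csv"
        frame.to_csv(path, index=index)
        outputs[name] = str(path)
        tables[name] = frame

    def _stage(name: str):
        log.info("stage=%s seed=%d", name, seed)
        stages_run.append(name)

    survey_a, survey_b, crust, truth = _load_inputs(config)
    leaf = impute_censored(survey_a)
    lichen = impute_censored(survey_b) if survey_b is not None else None
    write_survey(survey_a, out / "survey_a.csv")
    outputs["survey_a"] = str(out / "survey_a.csv")

    try:
        if config.enabled("summary"):
            _stage("summary")
            _save("descriptives", summarize(survey_a), index=True)

        ef_a = ef_b = None
        if config.enabled("enrichment"):
            _stage("enrichment")
            af = accumulation_factor(leaf, reference_element=ref_el)
            ef = enrichment_factor(leaf, crust)
            ef_a = ef.ef
            _save("accumulation_factors", af.to_tidy())
            _save("enrichment_factors", ef.to_tidy())
            cv = modified_cv(leaf).rename("modified_cv")
            cv.index.name = "element"
            _save("modified_cv", cv.reset_index())
            if lichen is not None:
                ef_b = enrichment_factor(lichen, crust).ef

        if config.enabled("background"):
            _stage("background")
            _save("background_tests", compare_to_background(leaf, alpha=alpha))

        if config.enabled("correlation"):
            _stage("correlation")
            screen = spearman_screen(leaf, alpha=alpha)
            _save("spearman_rho", screen.rho, index=True)
            _save("spearman_significant", screen.significant_pairs())

        if config.enabled("pca"):
            _stage("pca")
            sol = apportion(leaf,
                            msa_threshold=float(p.get("msa_threshold", 0.5)),
                            keep=tuple(p.get("keep", ())),
                            eigen_cut=float(p.get("eigen_cut", 1.0)),
                            loading_threshold=float(p.get("loading_threshold", 0.5)),
                            max_sweeps=int(p.get("max_sweeps", 1000)))
            _save("pca_loadings", sol.to_table(), index=True)
            adequacy = {
                "kmo": sol.kmo, "bartlett_chi2": sol.bartlett_chi2,
                "bartlett_df": sol.bartlett_df, "bartlett_p": sol.bartlett_p,
                "n_components": sol.n_components,
                "explained_variance_pct": sol.explained_variance_pct,
                "total_variance_pct": sol.total_variance_pct,
                "dropped": sol.dropped_variables,
                "assignments": sol.assignments,
            }
            (out / "pca_adequacy.json").write_text(
                json.dumps(adequacy, indent=2, default=float))
            outputs["pca_adequacy"] = str(out / "pca_adequacy.json")

        if config.enabled("spatial"):
            _stage("spatial")
            cell = p.get("cell_size", [65.0, 65.0])
            for el in p.get("idw_elements", ["Fe"]):
                surf = idw_interpolate(leaf, el, cell_size=tuple(cell),
                                       k=float(p.get("idw_k", 2.0)))
                surf.to_ascii_grid(out / f"idw_{el}.asc")
                outputs[f"idw_{el}"] = str(out / f"idw_{el}.asc")
            center = p.get("crown_center")
            if center is None and truth is not None and truth.source_locations:
                center = next(iter(truth.source_locations.values()))
            if center is not None:
                edges = tuple(p.get("ring_edges", (1.0, 2.0, 3.0, 4.0, 5.0)))
                rows = []
                for el in p.get("crown_elements", ["Fe", "Cr"]):
                    prof = crown_profile(leaf, el, tuple(center), edges)
                    rows.append({"element": el, "fit_a": prof.fit_a,
                                 "fit_b": prof.fit_b, "r2": prof.r2})
                _save("crown_fits", pd.DataFrame(rows))
                q = quadrant_compare(leaf, p.get("quadrant_element", "Fe"),
                                     tuple(center))
                _save("quadrant_pairwise", q.pairwise)
                notes.append(f"quadrant KW H={q.h:.3f} p={q.p:.4f}")
            else:
                notes.append("spatial: no crown center available; crowns skipped")

        if config.enabled("comparison"):
            if lichen is None or ef_a is None or ef_b is None:
                notes.append("comparison skipped: second survey or EFs unavailable")
            else:
                _stage("comparison")
                comp = compare_biomonitors(ef_a, ef_b,
                                           n_perm=int(p.get("n_perm", 999)),
                                           seed=seed, alpha=alpha)
                _save("biomonitor_comparison", comp)
    except Exception as exc:
        raise RuntimeError(f"stage {stages_run[-1] if stages_run else 'input'} "
                           f"failed: {exc}") from exc

    report = RunReport(str(out), config.hash(), __version__, stages_run,
                       outputs, notes, tables)
    report.to_json(out / "report.json")
    return report
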
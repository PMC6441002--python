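"""The four candidate abiotic models and the end-to-end analysis.

Candidates differ only in which abiotic drivers of web structure they
admit — temperature, latitude, both, or none — with the aquatic/terrestrial
indicator always present.  The structural core is a fully recursive causal
chain over the seven web descriptors

    S -> p_basal -> p_top -> L -> omnivory -> C -> maxTL

(each regressed on all earlier descriptors and the variant's abiotic
variables) minus the three paths aquatic -> {omnivory, C, maxTL}: the
unique "fully recursive minus a named path set" structure consistent with
all four candidate degrees of freedom (3, 3, 3, 4) simultaneously.  In the
"both" variant latitude drives temperature (temperature ~ latitude) and
latitude/aquatic are exogenous with a free covariance.

``run_study`` chains the whole pipeline: inclusion filter, optional
trophospecies aggregation, descriptor computation, covariate join with
listwise deletion of webs lacking temperature, collinearity screen,
z-standardization, ML fit of all four candidates, AIC ranking, and
effect decomposition with bootstrap significance for the AIC-best model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import aggregate as agg
from . import metrics as met
from . import pathsem, webio

logger = logging.getLogger(__name__)

VARIANTS = ("temperature", "latitude", "both", "none")

ENDO_ORDER = ("S", "p_basal", "p_top", "L", "omnivory", "C", "maxTL")
# aquatic predicts the biotic block only, not the network-structural one
_NO_AQUATIC = frozenset({"omnivory", "C", "maxTL"})

STUDY_COLUMNS = (
    "latitude", "temperature", "aquatic",
    "S", "p_basal", "p_top", "L", "omnivory", "C", "maxTL",
)


@dataclass(frozen=True)
class CandidateVariant:
    name: str
    spec: pathsem.PathModelSpec


def candidate_model(variant: str) -> CandidateVariant:
    """Build the candidate path model for one variant.

    Degrees of freedom are structural: 3 for "temperature", "latitude"
    and "none", 4 for "both".
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    equations: list[tuple[str, tuple[str, ...]]] = []
    if variant == "temperature":
        exogenous = ("temperature", "aquatic")
        abiotic = ("temperature", "aquatic")
    elif variant == "latitude":
        exogenous = ("latitude", "aquatic")
        abiotic = ("latitude", "aquatic")
    elif variant == "none":
        exogenous = ("aquatic",)
        abiotic = ("aquatic",)
    else:  # both: latitude drives temperature
        exogenous = ("latitude", "aquatic")
        abiotic = ("temperature", "latitude", "aquatic")
        equations.append(("temperature", ("latitude",)))

    for i, v in enumerate(ENDO_ORDER):
        preds = tuple(a for a in abiotic if not (a == "aquatic" and v in _NO_AQUATIC))
        preds += tuple(ENDO_ORDER[:i])
        equations.append((v, preds))

    variables = tuple(exogenous) + (
        ("temperature",) if variant == "both" else ()
    ) + ENDO_ORDER
    spec = pathsem.PathModelSpec(
        variables=variables,
        equations=tuple(equations),
        exogenous=exogenous,
        covariates=frozenset({"temperature", "latitude", "aquatic"} & set(variables)),
    )
    return CandidateVariant(name=variant, spec=spec)


@dataclass
class StudyReport:
    """Everything the analysis produces for one input collection."""

    n_input: int
    n_analyzed: int
    aggregated: bool
    seed: int
    metrics: pd.DataFrame
    screen: list[dict]
    comparison: pd.DataFrame
    best_model: str
    effects: dict[str, pd.DataFrame]
    r2: dict[str, dict[str, float]]
    exclusions: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "n_input": self.n_input,
            "n_analyzed": self.n_analyzed,
            "aggregated": self.aggregated,
            "seed": self.seed,
            "best_model": self.best_model,
            "comparison": self.comparison.to_dict(orient="records"),
            "screen": self.screen,
            "r2": self.r2,
            "exclusions": self.exclusions,
            "effects": {
                name: tab.to_dict(orient="records")
                for name, tab in self.effects.items()
            },
            "metrics": self.metrics.to_dict(orient="records"),
        }
        return json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(outdir / "metrics.csv", index=False)
        self.comparison.to_csv(outdir / "comparison.csv", index=False)
        for name, tab in self.effects.items():
            tab.to_csv(outdir / f"effects_{name}.csv", index=False)
        (outdir / "report.json").write_text(self.to_json(), encoding="utf-8")


def build_study_table(
    webs: Sequence[webio.FoodWeb],
    meta: Sequence[webio.WebMetadata],
    aggregate: bool = False,
    exclude_ids: Sequence[str] | None = None,
    min_species: int = 25,
    min_links: int = 50,
    use_abs_latitude: bool = True,
) -> tuple[pd.DataFrame, list[dict]]:
    """Filter, optionally aggregate, compute descriptors and join
    covariates; returns the per-web analysis table and the exclusion log."""
    exclusions: list[dict] = []
    excluded = set(exclude_ids or ())
    meta_by_id = {m.web_id: m for m in meta}

    kept: list[webio.FoodWeb] = []
    for w in webs:
        if w.web_id in excluded:
            exclusions.append({"web_id": w.web_id, "stage": "exclude_ids",
                               "reason": "explicitly excluded"})
        elif w.n_species < min_species or w.n_links < min_links:
            exclusions.append(
                {"web_id": w.web_id, "stage": "filter",
                 "reason": f"S={w.n_species}, L={w.n_links} below "
                           f"({min_species}, {min_links})"})
        elif w.web_id not in meta_by_id:
            exclusions.append({"web_id": w.web_id, "stage": "join",
                               "reason": "no metadata record"})
        else:
            kept.append(w)

    rows = []
    for w in kept:
        m = meta_by_id[w.web_id]
        if m.temperature_missing:
            exclusions.append({"web_id": w.web_id, "stage": "join",
                               "reason": "missing temperature (listwise deletion)"})
            continue
        target = agg.aggregate_web(w) if aggregate else w
        try:
            row = met.metrics_row(target)
        except met.TrophicLevelError as exc:
            exclusions.append({"web_id": w.web_id, "stage": "metrics",
                               "reason": str(exc)})
            continue
        d = row.to_dict()
        d["latitude"] = abs(m.latitude) if use_abs_latitude else m.latitude
        d["temperature"] = m.temperature_C
        d["aquatic"] = m.aquatic
        rows.append(d)
    table = pd.DataFrame(rows)
    return table, exclusions


def fit_candidates(
    data: pathsem.StandardizedMatrix,
) -> tuple[dict[str, pathsem.SemFit], pd.DataFrame]:
    """Fit all four candidate models to a standardized analysis matrix
    and rank them by AIC."""
    fits = {name: pathsem.fit_ml(candidate_model(name).spec, data)
            for name in VARIANTS}
    return fits, pathsem.compare_models(fits)


def run_study(
    webs: Sequence[webio.FoodWeb],
    meta: Sequence[webio.WebMetadata],
    aggregate: bool = False,
    exclude_ids: Sequence[str] | None = None,
    seed: int = 0,
    min_species: int = 25,
    min_links: int = 50,
    bootstrap: int = 1000,
    all_effects: bool = False,
) -> StudyReport:
    """Run the full analysis and bundle the results.

    Deterministic given identical inputs and ``seed`` (which drives only
    the bootstrap).
    """
    table, exclusions = build_study_table(
        webs, meta, aggregate=aggregate, exclude_ids=exclude_ids,
        min_species=min_species, min_links=min_links,
    )
    if len(table) < 10:
        raise pathsem.FitError(
            f"only {len(table)} webs analyzable after filtering/deletion; need >= 10"
        )
    logger.info("analyzing %d of %d webs (%d excluded)",
                len(table), len(webs), len(exclusions))

    metric_rows = [met.MetricsRow(**{k: r[k] for k in (
        "web_id", "S", "L", "C", "p_basal", "p_intermediate", "p_top",
        "omnivory", "maxTL", "meanTL")}) for r in table.to_dict(orient="records")]
    screen = met.correlation_screen(metric_rows)

    data = pathsem.standardize(table, columns=list(STUDY_COLUMNS))

    fits, comparison = fit_candidates(data)
    best = str(comparison.iloc[0]["model"])

    effects: dict[str, pd.DataFrame] = {}
    targets = list(VARIANTS) if all_effects else [best]
    for i, name in enumerate(targets):
        effects[name] = pathsem.bootstrap_se(
            fits[name].spec, data, B=bootstrap, seed=seed + i
        )
    r2 = {name: {k: float(v) for k, v in fits[name].R2.items()} for name in VARIANTS}

    return StudyReport(
        n_input=len(webs),
        n_analyzed=len(table),
        aggregated=aggregate,
        seed=seed,
        metrics=table,
        screen=screen,
        comparison=comparison,
        best_model=best,
        effects=effects,
        r2=r2,
        exclusions=exclusions,
    )
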
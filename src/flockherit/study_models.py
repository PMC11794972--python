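"""The study's model ladders and variance-proportion tables.

Three ladders of animal models are orchestrated here, each fitted per
winter and pooled across winters with year as a fixed effect:

* group size (one observation per flocking-event membership):
  Model 1  V_P = V_ID + V_R
  Model 2  V_P = V_ID + V_A + V_R
  Model 3  V_P = V_LOG + V_R
  Model 4  V_P = V_ID + V_LOG + V_R
  Model 5  V_P = V_ID + V_LOG + V_A + V_R

* weekend-level network traits (mean group size, degree, strength,
  eigenvector centrality, weighted eigenvector centrality, betweenness):
  Models 1-2 only — birds are observed over multiple locations, so no
  logger term is fitted;

* natal ladder on the locally-born subset (known natal section and brood):
  a  ID            b  ID+A          c  ID+SECT       d  ID+BI
  e  ID+SECT+BI    f  ID+A+SECT+BI (+LOG for group size only)
  g  ID+A+SPATIAL  h  ID+A+ENVSIM   i  ID+A+SPATIAL+ENVSIM

Repeatability is reported as (V_ID + V_A)/V_P (V_ID/V_P when no genetic
term is fitted) and narrow-sense heritability as h2 = V_A/V_P.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import (
    RESIDUAL,
    FitResult,
    ModelSpec,
    RandomTerm,
    RatioEstimate,
    lrt,
    reml_fit,
    variance_ratios,
)
from .pedigree import AMatrix, Pedigree, additive_relationship
from .similarity import SimilarityMatrix

__all__ = [
    "ModelLadderResult",
    "GROUP_SIZE_MODELS",
    "NETWORK_MODELS",
    "NATAL_MODELS",
    "NETWORK_TRAITS",
    "run_group_size_ladder",
    "run_network_trait_ladder",
    "run_natal_ladder",
    "variance_table",
]

GROUP_SIZE_MODELS = {
    "1": ("ID",),
    "2": ("ID", "A"),
    "3": ("LOG",),
    "4": ("ID", "LOG"),
    "5": ("ID", "LOG", "A"),
}
NETWORK_MODELS = {"1": ("ID",), "2": ("ID", "A")}
NATAL_MODELS = {
    "a": ("ID",),
    "b": ("ID", "A"),
    "c": ("ID", "SECT"),
    "d": ("ID", "BI"),
    "e": ("ID", "SECT", "BI"),
    "f": ("ID", "A", "SECT", "BI", "LOG"),  # LOG dropped for network traits
    "g": ("ID", "A", "SPATIAL"),
    "h": ("ID", "A", "ENVSIM"),
    "i": ("ID", "A", "SPATIAL", "ENVSIM"),
}
#: reduced-model comparison used for the likelihood-ratio test of each model's
#: distinguishing random term, where one exists within the same ladder
_LRT_PARTNERS = {
    "2": "1", "4": "1", "5": "4",
    "b": "a", "c": "a", "d": "a", "e": "c", "g": "b", "h": "b", "i": "g",
}

NETWORK_TRAITS = (
    "mean_group_size",
    "degree",
    "strength",
    "eigen_centrality",
    "weighted_eigen_centrality",
    "betweenness",
)

_TERM_COLUMNS = {
    "ID": "individual",
    "A": "individual",
    "LOG": "logger",
    "SECT": "natal_section",
    "BI": "brood_id",
    "SPATIAL": "individual",
    "ENVSIM": "individual",
}


@dataclass
class ModelLadderResult:
    model_id: str
    trait: str
    scope: str  # winter label or "pooled"
    fit: FitResult
    proportions: dict[str, float]
    ratios: dict[str, RatioEstimate]
    lrt_vs: dict[str, tuple[float, float]] = field(default_factory=dict)


def _amatrix_for(
    obs_individuals: pd.Series, ped: Pedigree, unpedigreed: str = "founders"
) -> tuple[AMatrix, pd.Index]:
    """Relatedness matrix covering the observed individuals.

    Birds without pedigree records are either added as unknown-parent
    founders (``"founders"``, the default: they contribute phenotype but
    carry no genetic links) or excluded from the genetic models
    (``"drop"``).
    """
    inds = pd.Index(obs_individuals.unique())
    known = set(ped.ids)
    extra = [i for i in inds if i not in known]
    if unpedigreed == "founders":
        if extra:
            recs = [
                (
                    ped.ids[k],
                    ped.ids[ped.sire[k]] if ped.sire[k] >= 0 else None,
                    ped.ids[ped.dam[k]] if ped.dam[k] >= 0 else None,
                )
                for k in range(len(ped))
            ] + [(e, None, None) for e in extra]
            ped = Pedigree.from_records(recs)
        keep = inds
    elif unpedigreed == "drop":
        if extra:
            warnings.warn(
                f"dropping {len(extra)} individuals without pedigree records",
                stacklevel=3,
            )
        keep = inds[~inds.isin(extra)]
    else:
        raise ValueError(f"unknown unpedigreed policy {unpedigreed!r}")
    return additive_relationship(ped), keep


def _make_terms(
    names: tuple[str, ...],
    amatrix: AMatrix | None,
    spatial: SimilarityMatrix | None = None,
    envsim: SimilarityMatrix | None = None,
) -> list[RandomTerm]:
    cov = {"A": amatrix, "SPATIAL": spatial, "ENVSIM": envsim}
    terms = []
    for nm in names:
        c = cov.get(nm)
        if nm in cov and c is None:
            raise ValueError(f"model requires a covariance structure for term {nm}")
        terms.append(RandomTerm(nm, _TERM_COLUMNS[nm], covariance=c))
    return terms


def _ratios(fit: FitResult, names: tuple[str, ...]) -> dict[str, RatioEstimate]:
    out: dict[str, RatioEstimate] = {}
    if "ID" in names:
        num = ("ID", "A") if "A" in names else ("ID",)
        out["repeatability"] = variance_ratios(fit, num, "repeatability")
    if "A" in names:
        out["heritability"] = variance_ratios(fit, ("A",), "heritability")
    return out


def _run_ladder(
    data: pd.DataFrame,
    response: str,
    models: dict[str, tuple[str, ...]],
    scopes: list[str],
    trait: str,
    amatrix: AMatrix | None,
    spatial: SimilarityMatrix | None = None,
    envsim: SimilarityMatrix | None = None,
    options=None,
) -> list[ModelLadderResult]:
    results: list[ModelLadderResult] = []
    for scope in scopes:
        if scope == "pooled":
            sub, fixed = data, ["winter"]
        else:
            sub, fixed = data[data["winter"] == scope], []
        fits: dict[str, FitResult] = {}
        for mid, names in models.items():
            terms = _make_terms(names, amatrix, spatial, envsim)
            fit = reml_fit(sub, ModelSpec(response, fixed, terms), options)
            fits[mid] = fit
            res = ModelLadderResult(
                model_id=mid,
                trait=trait,
                scope=scope,
                fit=fit,
                proportions=fit.proportions(),
                ratios=_ratios(fit, names),
            )
            partner = _LRT_PARTNERS.get(mid)
            if partner in fits:
                try:
                    res.lrt_vs[partner] = lrt(fit, fits[partner])
                except ValueError:
                    pass
            results.append(res)
    return results


def _scopes(data: pd.DataFrame) -> list[str]:
    winters = sorted(data["winter"].astype(str).unique())
    scopes = list(winters)
    if len(winters) > 1:
        scopes.append("pooled")
    return scopes


def run_group_size_ladder(
    obs: pd.DataFrame,
    ped: Pedigree,
    unpedigreed: str = "founders",
    options=None,
) -> list[ModelLadderResult]:
    """Models 1-5 for event-level group size, per winter and pooled.

    ``obs`` needs columns individual, logger, group_size, winter. With
    the ``"drop"`` policy, birds without pedigree records are removed
    before fitting; with ``"founders"`` (default) they enter the
    relatedness matrix as unrelated founders.
    """
    need = {"individual", "logger", "group_size", "winter"} - set(obs.columns)
    if need:
        raise ValueError(f"observation table lacks columns: {sorted(need)}")
    amatrix, keep = _amatrix_for(obs["individual"], ped, unpedigreed)
    data = obs[obs["individual"].isin(keep)]
    return _run_ladder(
        data, "group_size", GROUP_SIZE_MODELS, _scopes(data), "group_size",
        amatrix, options=options,
    )


def run_network_trait_ladder(
    metrics: pd.DataFrame,
    ped: Pedigree,
    traits: tuple[str, ...] = NETWORK_TRAITS,
    unpedigreed: str = "founders",
    options=None,
) -> list[ModelLadderResult]:
    """Models 1-2 for weekend-level network traits, per winter and pooled.

    ``metrics`` is wide: one row per (individual, winter, weekend) with a
    column per trait. No logger term is fitted — the weekend networks
    span multiple feeder locations. Pooled fits stack winters with
    individual identity linking across years.
    """
    unknown = set(traits) - set(NETWORK_TRAITS)
    if unknown:
        raise ValueError(f"unknown network traits: {sorted(unknown)}")
    amatrix, keep = _amatrix_for(metrics["individual"], ped, unpedigreed)
    data = metrics[metrics["individual"].isin(keep)]
    results = []
    for trait in traits:
        results.extend(
            _run_ladder(
                data.dropna(subset=[trait]), trait, NETWORK_MODELS,
                _scopes(data), trait, amatrix, options=options,
            )
        )
    return results


def run_natal_ladder(
    data: pd.DataFrame,
    ped: Pedigree,
    spatial: SimilarityMatrix | None = None,
    envsim: SimilarityMatrix | None = None,
    response: str = "group_size",
    models: tuple[str, ...] = tuple(NATAL_MODELS),
    unpedigreed: str = "founders",
    options=None,
) -> list[ModelLadderResult]:
    """Natal-effects Models a-i on the locally-born subset, pooled scope.

    ``data`` must carry natal_section and brood_id columns; rows missing
    either are dropped (their count reported in a warning). The logger
    term in Model f is retained for group size and removed for any other
    response, matching the two trait-specific ladders. ``spatial`` and
    ``envsim`` are similarity matrices over (at least) the locally-born
    individuals; they are required only when Models g-i are requested.
    """
    need = {"individual", "winter", response, "natal_section", "brood_id"} - set(
        data.columns
    )
    if need:
        raise ValueError(f"natal ladder input lacks columns: {sorted(need)}")
    ok = data["natal_section"].notna() & data["brood_id"].notna()
    if (~ok).any():
        warnings.warn(
            f"dropping {(~ok).sum()} observations without natal data", stacklevel=2
        )
    local = data[ok]
    amatrix, keep = _amatrix_for(local["individual"], ped, unpedigreed)
    local = local[local["individual"].isin(keep)]
    scopes = ["pooled"] if local["winter"].nunique() > 1 else _scopes(local)
    mdl: dict[str, tuple[str, ...]] = {}
    for mid in models:
        names = NATAL_MODELS[mid]
        if mid == "f" and response != "group_size":
            names = tuple(n for n in names if n != "LOG")
        mdl[mid] = names
    return _run_ladder(
        local, response, mdl, scopes, response, amatrix, spatial, envsim,
        options=options,
    )


def variance_table(results: list[ModelLadderResult]) -> pd.DataFrame:
    """Tidy variance-component table: one row per model x term.

    Columns: model_id, trait, scope, term, estimate, se, proportion;
    proportions sum to 1 within each fit.
    """
    if not results:
        raise ValueError("no ladder results")
    rows = []
    for r in results:
        for term, est in r.fit.components.items():
            rows.append(
                {
                    "model_id": r.model_id,
                    "trait": r.trait,
                    "scope": r.scope,
                    "term": term,
                    "estimate": est,
                    "se": r.fit.se.get(term, np.nan),
                    "proportion": r.proportions[term],
                }
            )
    return pd.DataFrame(rows)
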
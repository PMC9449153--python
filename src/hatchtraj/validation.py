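"""Model comparison and forward-validation predictive ability.

Candidate random-regression models are compared by restricted
log-likelihood, AIC and likelihood-ratio tests against the full model.
Predictive ability follows the forward-validation recipe for breeding
programs: fixed-effect-adjusted phenotypes from the full data, truncation
of the youngest ~10% of hens into a validation set, re-estimation of
breeding values on the reduced data, and the Pearson correlation between
the reduced-data (G)EBV and the full-data adjusted phenotypes of the
validation animals (per biweekly age for RR, with the unweighted mean as
the single summary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, pearsonr

from .legendre import AgeGrid
from .mixed_model import (
    EvaluationResult,
    ModelSpec,
    REMLResult,
    build_design,
    ebv_per_age,
)
from .relationships import Pedigree

__all__ = [
    "ModelFit",
    "compare_models",
    "adjust_phenotypes",
    "ValidationSplit",
    "forward_split",
    "PredictiveAbility",
    "predictive_ability",
]


@dataclass(frozen=True)
class ModelFit:
    """One fitted candidate: orders per random term, logL, parameter count."""

    name: str
    orders: dict
    logL: float
    n_params: int

    @staticmethod
    def from_reml(
        name: str, result: REMLResult, n_residual_classes: int, extra: int = 1
    ) -> "ModelFit":
        return ModelFit(
            name=name,
            orders=result.spec.orders,
            logL=result.logL,
            n_params=result.spec.n_vc_parameters(n_residual_classes, extra=extra),
        )


def compare_models(fits: list[ModelFit], alpha: float = 0.05) -> pd.DataFrame:
    """AIC and likelihood-ratio tests of reduced models against the full one.

    The first fit is the full model; every other fit must be nested in it
    (no random-term order exceeding the full model's).  AIC = -2 logL + 2p;
    the LRT statistic is 2 (logL_full - logL_reduced) on df = delta p.
    """
    if not fits:
        raise ValueError("no model fits supplied")
    full = fits[0]
    rows = []
    for fit in fits:
        if set(fit.orders) != set(full.orders):
            raise ValueError(f"model {fit.name!r} has different random terms")
        if any(fit.orders[k] > full.orders[k] for k in full.orders):
            raise ValueError(f"model {fit.name!r} is not nested in {full.name!r}")
        aic = -2.0 * fit.logL + 2.0 * fit.n_params
        if fit is full:
            lrt, df, pval, flag = np.nan, 0, np.nan, "full model"
        else:
            lrt = 2.0 * (full.logL - fit.logL)
            df = full.n_params - fit.n_params
            if lrt < 0 and lrt > -1e-6:
                lrt = 0.0
            pval = float(chi2.sf(lrt, df)) if df > 0 else np.nan
            flag = "NS" if (np.isnan(pval) or pval >= alpha) else f"p<{alpha:g}"
        rows.append(
            {
                "model": fit.name,
                **{f"order_{k}": v for k, v in fit.orders.items()},
                "logL": fit.logL,
                "p": fit.n_params,
                "AIC": aic,
                "LRT": lrt,
                "df": df,
                "p_value": pval,
                "significance": flag,
            }
        )
    return pd.DataFrame(rows)


def adjust_phenotypes(
    data: pd.DataFrame,
    full_fit: EvaluationResult,
    ped: Pedigree | None = None,
    grid: AgeGrid | None = None,
) -> pd.DataFrame:
    """Observed records minus every fitted fixed effect of the full model.

    Returns a copy of ``data`` with an ``adjusted`` column; raises if a
    record's factor level has no estimate in the fit.
    """
    design = build_design(full_fit.spec, data, ped=ped, grid=grid)
    have = set(design.fixed_labels)
    missing = have - set(full_fit.fixed.index)
    if missing:
        raise ValueError(f"fixed-effect levels without estimates: {sorted(missing)[:10]}")
    beta = full_fit.fixed.reindex(design.fixed_labels).to_numpy()
    out = data.copy()
    out["adjusted"] = design.y - design.X @ beta
    return out


@dataclass(frozen=True)
class ValidationSplit:
    training_ids: np.ndarray
    validation_ids: np.ndarray
    criterion: str
    validation_cohorts: tuple


def forward_split(
    ped: Pedigree, data: pd.DataFrame, fraction: float = 0.10
) -> ValidationSplit:
    """Assign the youngest cohorts of recorded hens to validation.

    Cohorts order hens by birth time: pedigree generation refined by the
    hatch-week factor when present (the synthetic analog of truncating the
    youngest hatch years).  Youngest cohorts are accumulated until their
    cumulative share of hens is closest to ``fraction``.  Training and
    validation are disjoint and validation never swallows every cohort.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("validation fraction must lie strictly between 0 and 1")
    hens = np.unique(data["hen"].to_numpy())
    gen = ped.generation_of(hens)
    if "hatch_week" in data.columns:
        hw = data.groupby("hen")["hatch_week"].first()
        cohort = [(int(g), int(hw[h])) for g, h in zip(gen, hens)]
    else:
        cohort = [(int(g), 0) for g in gen]
    cohort = np.array(cohort)
    order = np.unique(cohort, axis=0)[::-1]  # youngest (max) first
    total = hens.size
    best_k, best_gap = 1, np.inf
    cum = 0
    for k in range(1, len(order)):  # never take every cohort
        c = order[k - 1]
        cum += int(np.sum((cohort[:, 0] == c[0]) & (cohort[:, 1] == c[1])))
        gap = abs(cum / total - fraction)
        if gap < best_gap:
            best_k, best_gap = k, gap
    chosen = {tuple(c) for c in order[:best_k]}
    val_mask = np.array([tuple(c) in chosen for c in cohort])
    return ValidationSplit(
        training_ids=hens[~val_mask],
        validation_ids=hens[val_mask],
        criterion="youngest_cohorts",
        validation_cohorts=tuple(sorted(chosen)),
    )


@dataclass
class PredictiveAbility:
    summary: float
    per_age: pd.Series | None
    n_validation: int


def predictive_ability(
    adjusted: pd.DataFrame,
    reduced_fit: EvaluationResult,
    split: ValidationSplit,
    grid: AgeGrid | None = None,
    term: str | None = None,
    min_animals: int = 3,
) -> PredictiveAbility:
    """Pearson correlation of reduced-data (G)EBV with adjusted phenotypes.

    Cumulative model: one correlation over validation hens.  RR model: one
    correlation per biweekly age between that age's adjusted records and
    the per-age EBV, and their unweighted mean as the summary.  Ages with
    fewer than ``min_animals`` validation records are reported missing.
    """
    val = set(int(v) for v in split.validation_ids)
    sub = adjusted[adjusted["hen"].astype(int).isin(val)]
    spec = reduced_fit.spec
    if spec.kind == "cumulative":
        ebv = ebv_per_age(reduced_fit, term=term)["ebv"]
        merged = sub.set_index("hen")["adjusted"]
        common = merged.index.intersection(ebv.index)
        if common.size < min_animals:
            raise ValueError("too few validation animals with records")
        r = float(pearsonr(merged.loc[common], ebv.loc[common])[0])
        return PredictiveAbility(summary=r, per_age=None, n_validation=int(common.size))
    grid = grid or AgeGrid()
    from .legendre import legendre_matrix  # local to avoid cycle at import

    term_name = term or next(t.name for t in spec.terms if t.covariance == "additive")
    spec_term = next(t for t in spec.terms if t.name == term_name)
    basis = legendre_matrix(grid, spec_term.order)
    ebv = ebv_per_age(reduced_fit, basis=basis, term=term_name)
    per_age = {}
    for age in grid.ages:
        rows = sub[sub["age_weeks"] == age]
        hens = rows["hen"].to_numpy()
        if hens.size < min_animals:
            per_age[age] = np.nan
            continue
        per_age[age] = float(
            pearsonr(rows["adjusted"].to_numpy(), ebv.loc[hens, age].to_numpy())[0]
        )
    per_age = pd.Series(per_age, name="predictive_ability")
    return PredictiveAbility(
        summary=float(per_age.mean(skipna=True)),
        per_age=per_age,
        n_validation=int(sub["hen"].nunique()),
    )
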
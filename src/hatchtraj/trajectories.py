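"""Age trajectories of variance components, heritability and correlations.

A random-regression fit yields coefficient covariances K per term; the
variance contributed at hen age t is the quadratic form z(t)' K z(t) in the
Legendre covariates.  This module converts fitted components into per-age
variance tables, heritability h2(t) and repeatability re(t) trajectories,
between-age genetic and phenotypic correlation matrices, and single-value
summaries (plain means over the age grid) comparable with a cumulative
model.

Headline heritability uses the hen additive component only (tom additive
contributions to these traits are near zero); a flag adds the tom additive
variance to the numerator and both variants appear in the output table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .legendre import AgeGrid, BasisMatrix, legendre_matrix
from .mixed_model import VarianceComponents

__all__ = [
    "variance_at_age",
    "component_trajectories",
    "heritability",
    "repeatability",
    "heritability_trajectory",
    "repeatability_trajectory",
    "correlation_matrices",
    "average_components",
    "triangle_report",
]

# canonical term names of the RR model
_TERMS = ("hen_additive", "tom_additive", "hen_pe", "tom_pe")


def variance_at_age(K: np.ndarray, basis: BasisMatrix, t=None):
    """Quadratic-form variance z(t)' K z(t); all grid ages when t is None."""
    K = np.atleast_2d(np.asarray(K, dtype=float))
    if K.shape[0] != basis.n_coef:
        raise ValueError(
            f"K of size {K.shape[0]} does not match basis with {basis.n_coef} covariates"
        )
    Z = basis.values if t is None else np.atleast_2d(basis.row(t))
    out = np.einsum("ij,jk,ik->i", Z, K, Z)
    return out if t is None else float(out[0]) if np.isscalar(t) else out


def heritability(additive: float, phenotypic: float) -> float:
    """h2 = additive / phenotypic variance."""
    if phenotypic <= 0:
        raise ValueError("phenotypic variance must be positive")
    return additive / phenotypic


def repeatability(additive: float, permanent: float, phenotypic: float) -> float:
    """re = (additive + permanent environment) / phenotypic variance."""
    if phenotypic <= 0:
        raise ValueError("phenotypic variance must be positive")
    return (additive + permanent) / phenotypic


def _bases(vc: VarianceComponents, grid: AgeGrid) -> dict[str, BasisMatrix]:
    return {
        name: legendre_matrix(grid, vc.K[name].shape[0] - 1)
        for name in _TERMS
        if name in vc.K
    }


def component_trajectories(vc: VarianceComponents, grid: AgeGrid | None = None) -> pd.DataFrame:
    """Per-age variance components and derived ratios for an RR fit.

    Columns: the four random-term variances, residual, phenotypic (their
    sum), h2 (hen additive / phenotypic), h2_total (hen + tom additive in
    the numerator) and repeatability (hen additive + hen permanent
    environment over phenotypic).
    """
    grid = grid or AgeGrid()
    bases = _bases(vc, grid)
    missing = [t for t in _TERMS if t not in bases]
    if missing:
        raise ValueError(f"variance components lack RR terms: {missing}")
    if vc.sigma2_e.size != grid.n_ages:
        raise ValueError("need one residual variance per grid age")
    tbl = pd.DataFrame({"age": list(grid.ages)}).set_index("age")
    for name in _TERMS:
        tbl[name] = variance_at_age(vc.K[name], bases[name])
    tbl["residual"] = vc.sigma2_e
    tbl["phenotypic"] = tbl[list(_TERMS)].sum(axis=1) + tbl["residual"]
    tbl["h2"] = tbl["hen_additive"] / tbl["phenotypic"]
    tbl["h2_total"] = (tbl["hen_additive"] + tbl["tom_additive"]) / tbl["phenotypic"]
    tbl["repeatability"] = (tbl["hen_additive"] + tbl["hen_pe"]) / tbl["phenotypic"]
    return tbl


def heritability_trajectory(
    vc: VarianceComponents, grid: AgeGrid | None = None, include_tom: bool = False
) -> pd.Series:
    tbl = component_trajectories(vc, grid)
    return tbl["h2_total" if include_tom else "h2"]


def repeatability_trajectory(vc: VarianceComponents, grid: AgeGrid | None = None) -> pd.Series:
    return component_trajectories(vc, grid)["repeatability"]


def correlation_matrices(
    vc: VarianceComponents, grid: AgeGrid | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Between-age genetic and phenotypic correlation matrices.

    Genetic covariance between ages is z(t1)' K_aF z(t2) (hen additive);
    phenotypic covariance sums the covariance functions of all four random
    terms, with the residual contributing only on the diagonal.
    """
    grid = grid or AgeGrid()
    bases = _bases(vc, grid)
    ages = list(grid.ages)
    ZaF = bases["hen_additive"].values
    Cg = ZaF @ vc.K["hen_additive"] @ ZaF.T
    Cp = np.zeros_like(Cg)
    for name in _TERMS:
        Z = bases[name].values
        Cp += Z @ vc.K[name] @ Z.T
    Cp += np.diag(vc.sigma2_e)

    def _norm(C: np.ndarray, label: str) -> pd.DataFrame:
        d = np.diag(C)
        if np.any(d <= 0):
            raise ValueError(f"nonpositive {label} variance on the diagonal")
        R = C / np.sqrt(np.outer(d, d))
        np.fill_diagonal(R, 1.0)
        return pd.DataFrame(R, index=ages, columns=ages)

    return _norm(Cg, "genetic"), _norm(Cp, "phenotypic")


def average_components(tbl: pd.DataFrame) -> pd.Series:
    """Single-value summaries: plain means over ages of each component and
    ratio, plus ratios of averaged components (both conventions reported)."""
    out = tbl.mean(axis=0)
    out["h2_of_averages"] = out["hen_additive"] / out["phenotypic"]
    out["repeatability_of_averages"] = (
        out["hen_additive"] + out["hen_pe"]
    ) / out["phenotypic"]
    return out


def triangle_report(
    h2: pd.Series, genetic: pd.DataFrame, phenotypic: pd.DataFrame
) -> pd.DataFrame:
    """Combined age x age table: h2 on the diagonal, genetic correlations
    above it, phenotypic correlations below."""
    out = genetic.copy()
    ages = out.index
    vals = out.to_numpy()
    low = np.tril_indices(len(ages), k=-1)
    vals[low] = phenotypic.to_numpy()[low]
    np.fill_diagonal(vals, h2.to_numpy())
    return pd.DataFrame(vals, index=ages, columns=ages)
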
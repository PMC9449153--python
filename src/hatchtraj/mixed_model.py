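"""Henderson mixed-model equations and REML for cumulative and RR models.

Two model families are supported:

* the cumulative (CUM) animal model ``y = hatch week + animal + e`` with a
  single record per hen, a scalar additive variance and homogeneous
  residual, and
* the random-regression (RR) model with hatch-week and egg-hatch-week fixed
  effects, a cubic fixed Legendre age regression, hen/tom additive and
  permanent-environment random regressions, and heterogeneous residual
  variances per biweekly age class.

Additive terms take any relationship inverse with ``.matrix``/``.logdet``
(pedigree ``A^-1`` or single-step ``H^-1``), so pedigree BLUP and ssGBLUP
share one code path.  Random-effect order is animal-major: the coefficient
covariance of an additive term is ``Rel (x) K`` and its contribution to the
coefficient matrix is ``Rel^-1 (x) K^-1``.

Variance components are estimated by restricted maximum likelihood:

* models with one scalar random term and homogeneous residual (CUM) use an
  exact one-dimensional profile likelihood in the variance ratio,
* everything else uses average-information (AI) REML on a log-Cholesky
  parameterization with step-halving on the exact restricted log-likelihood.
  Trace terms of the score use exact mixed-model-equation identities when
  the coefficient matrix is small enough to invert densely, and Hutchinson
  (Rademacher-probe) stochastic estimates on large sparse systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from scipy.sparse.linalg import splu

from .legendre import AgeGrid, BasisMatrix, legendre_matrix, legendre_row
from .relationships import Pedigree, RelationshipInverse, pedigree_relationship_inverse
from .selected_inverse import SymmetricSparseFactor, _SymbolicCache

__all__ = [
    "RandomTerm",
    "ModelSpec",
    "VarianceComponents",
    "DesignMatrices",
    "MMESystem",
    "EvaluationResult",
    "REMLOptions",
    "REMLResult",
    "build_design",
    "assemble_mme",
    "solve_mme",
    "log_likelihood",
    "reml_estimate",
    "ebv_per_age",
    "aggregate_cumulative",
    "default_start",
]

_TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class RandomTerm:
    """One random effect: subject column, basis order, covariance source."""

    name: str
    subject: str  # data column holding the subject id ("hen" or "tom")
    order: int
    covariance: str = "additive"  # "additive" (A or H) | "iid"
    basis: str = "legendre"  # "legendre" | "indicator"

    @property
    def n_coef(self) -> int:
        return 1 if self.basis == "indicator" else self.order + 1


@dataclass(frozen=True)
class ModelSpec:
    """Model structure: fixed factors, fixed regression, random terms."""

    kind: str
    fixed_factors: tuple[str, ...]
    fixed_regression_order: int
    terms: tuple[RandomTerm, ...]
    residual: str  # "homogeneous" | "per_age_class"

    @staticmethod
    def cumulative() -> "ModelSpec":
        return ModelSpec(
            kind="cumulative",
            fixed_factors=("hatch_week",),
            fixed_regression_order=0,
            terms=(RandomTerm("animal", "hen", 0, "additive", "indicator"),),
            residual="homogeneous",
        )

    @staticmethod
    def random_regression(
        aF: int = 3, aM: int = 1, peF: int = 3, peM: int = 2
    ) -> "ModelSpec":
        """RR spec; default orders are the selected parsimonious model."""
        return ModelSpec(
            kind="random_regression",
            fixed_factors=("hatch_week", "egg_hatch_week"),
            fixed_regression_order=3,
            terms=(
                RandomTerm("hen_additive", "hen", aF, "additive"),
                RandomTerm("tom_additive", "tom", aM, "additive"),
                RandomTerm("hen_pe", "hen", peF, "iid"),
                RandomTerm("tom_pe", "tom", peM, "iid"),
            ),
            residual="per_age_class",
        )

    @property
    def orders(self) -> dict[str, int]:
        return {t.name: t.order for t in self.terms}

    def n_vc_parameters(self, n_residual_classes: int, extra: int = 1) -> int:
        """Free (co)variance parameters; ``extra`` matches reported counts."""
        k = sum(t.n_coef * (t.n_coef + 1) // 2 for t in self.terms)
        return k + n_residual_classes + extra


@dataclass
class VarianceComponents:
    """Covariances of RR coefficients per term plus residual variances."""

    K: dict[str, np.ndarray]
    sigma2_e: np.ndarray

    def __post_init__(self) -> None:
        self.K = {k: np.atleast_2d(np.asarray(v, dtype=float)) for k, v in self.K.items()}
        self.sigma2_e = np.atleast_1d(np.asarray(self.sigma2_e, dtype=float))
        for name, K in self.K.items():
            if not np.allclose(K, K.T, atol=1e-8):
                raise ValueError(f"K for term {name!r} must be symmetric")
        if np.any(self.sigma2_e <= 0):
            raise ValueError("residual variances must be positive")

    def copy(self) -> "VarianceComponents":
        return VarianceComponents(
            {k: v.copy() for k, v in self.K.items()}, self.sigma2_e.copy()
        )


@dataclass
class DesignMatrices:
    """Design matrices for one trait's records."""

    y: np.ndarray
    X: sparse.csr_matrix
    fixed_labels: list
    Z: dict
    term_levels: dict
    age_class: np.ndarray
    n_classes: int
    spec: ModelSpec
    grid: AgeGrid | None
    data: pd.DataFrame


def build_design(
    spec: ModelSpec,
    data: pd.DataFrame,
    ped: Pedigree | None = None,
    grid: AgeGrid | None = None,
) -> DesignMatrices:
    """Incidence and covariate matrices for the records in ``data``.

    Fixed effects are an intercept plus first-level-zeroed factor dummies
    (an equivalent constraint to absorbing the mean into the first factor)
    plus, for RR, the cubic fixed Legendre age regression.  Each random
    term's design carries the record's basis row in the columns of its
    subject; additive terms span every pedigree animal so the relationship
    inverse conforms.
    """
    if "trait" in data.columns and data["trait"].nunique() > 1:
        raise ValueError("build_design expects records of a single trait")
    n = len(data)
    y = data["value"].to_numpy(dtype=float)

    # fixed part
    cols = [sparse.csr_matrix(np.ones((n, 1)))]
    labels: list[str] = ["intercept"]
    for factor in spec.fixed_factors:
        levels = np.sort(data[factor].unique())
        codes = pd.Categorical(data[factor], categories=levels).codes
        for lev in levels[1:]:
            labels.append(f"{factor}[{lev}]")
        if levels.size > 1:
            mask = codes > 0
            inc = sparse.coo_matrix(
                (np.ones(mask.sum()), (np.where(mask)[0], codes[mask] - 1)),
                shape=(n, levels.size - 1),
            )
            cols.append(inc.tocsr())
    if spec.fixed_regression_order > 0:
        if grid is None:
            grid = AgeGrid()
        reg = legendre_row(
            data["age_weeks"].to_numpy(dtype=float), grid, spec.fixed_regression_order
        )[:, 1:]
        cols.append(sparse.csr_matrix(reg))
        labels += [f"age_leg{l}" for l in range(1, spec.fixed_regression_order + 1)]
    X = sparse.hstack(cols, format="csr")

    # residual classes
    if spec.residual == "per_age_class":
        if grid is None:
            grid = AgeGrid()
        age_class = grid.age_class(data["age_weeks"].to_numpy())
        n_classes = grid.n_ages
    else:
        age_class = np.zeros(n, dtype=int)
        n_classes = 1

    # random terms
    Z: dict[str, sparse.csr_matrix] = {}
    term_levels: dict[str, np.ndarray] = {}
    for term in spec.terms:
        subjects = data[term.subject].to_numpy()
        if term.covariance == "additive":
            if ped is None:
                raise ValueError(f"term {term.name!r} needs a pedigree")
            missing = sorted(set(int(s) for s in subjects) - set(ped.ids.tolist()))
            if missing:
                raise ValueError(
                    f"records reference animals absent from the pedigree: {missing[:10]}"
                )
            levels = ped.ids
        else:
            levels = np.unique(subjects)
        pos = {int(a): i for i, a in enumerate(levels)}
        lev_idx = np.array([pos[int(s)] for s in subjects])
        q = term.n_coef
        if term.basis == "indicator":
            vals = np.ones((n, 1))
        else:
            if grid is None:
                grid = AgeGrid()
            vals = legendre_row(data["age_weeks"].to_numpy(dtype=float), grid, term.order)
        rows = np.repeat(np.arange(n), q)
        colidx = (lev_idx[:, None] * q + np.arange(q)[None, :]).ravel()
        Z[term.name] = sparse.coo_matrix(
            (vals.ravel(), (rows, colidx)), shape=(n, levels.size * q)
        ).tocsr()
        term_levels[term.name] = np.asarray(levels)

    return DesignMatrices(
        y=y,
        X=X,
        fixed_labels=labels,
        Z=Z,
        term_levels=term_levels,
        age_class=age_class,
        n_classes=n_classes,
        spec=spec,
        grid=grid,
        data=data,
    )


def _kron_full_block(rel: sparse.spmatrix, Kinv: np.ndarray) -> sparse.csc_matrix:
    """kron(rel, Kinv) with every q x q block stored in full.

    Explicit zeros are kept so the coefficient matrix's stored pattern
    covers everything the REML trace computations look up.
    """
    rel = sparse.coo_matrix(rel)
    q = Kinv.shape[0]
    qi = np.arange(q)
    block_rows = np.repeat(qi, q)
    block_cols = np.tile(qi, q)
    rows = (rel.row[:, None] * q + block_rows[None, :]).ravel()
    cols = (rel.col[:, None] * q + block_cols[None, :]).ravel()
    data = np.einsum("n,ij->nij", rel.data, Kinv).ravel()
    n = rel.shape[0] * q
    out = sparse.csc_matrix((data, (rows, cols)), shape=(n, n))
    return out


class MMESystem:
    """Assembled mixed-model equations ``C theta = rhs`` for given components."""

    def __init__(
        self,
        design: DesignMatrices,
        vc: VarianceComponents,
        relinv: RelationshipInverse | None = None,
        dense_threshold: int = 2600,
        factor_cache=None,
    ):
        self.design = design
        self.vc = vc
        self.relinv = relinv
        self.dense_threshold = dense_threshold
        self.factor_cache = factor_cache
        spec = design.spec
        if vc.sigma2_e.size != design.n_classes:
            raise ValueError("residual variance vector does not match residual classes")
        self.rinv = 1.0 / vc.sigma2_e[design.age_class]
        blocks = [design.X] + [design.Z[t.name] for t in spec.terms]
        self.W = sparse.hstack(blocks, format="csr")
        WtRi = self.W.T.multiply(self.rinv).tocsr()
        data_block = sparse.coo_matrix(WtRi @ self.W)
        dim = self.W.shape[1]
        # assemble in one pass and union in the value-independent structural
        # pattern: scipy prunes entries that cancel to exactly zero (and
        # explicitly stored zeros), but the REML trace lookups need the full
        # stored pattern of the coefficient matrix
        Wpat = self.W.copy()
        Wpat.data = np.ones_like(Wpat.data)
        pat = sparse.coo_matrix(Wpat.T @ Wpat)
        rows = [data_block.row, pat.row]
        cols = [data_block.col, pat.col]
        vals = [data_block.data, np.zeros_like(pat.data)]
        self.p_fixed = design.X.shape[1]
        self.offsets: dict[str, tuple[int, int, int]] = {}
        off = self.p_fixed
        for term in spec.terms:
            q = term.n_coef
            nlev = design.term_levels[term.name].size
            K = vc.K[term.name]
            if K.shape != (q, q):
                raise ValueError(
                    f"K for term {term.name!r} has shape {K.shape}, expected {(q, q)}"
                )
            try:
                Kinv = np.linalg.inv(K)
            except np.linalg.LinAlgError:
                raise np.linalg.LinAlgError(
                    f"singular coefficient covariance for term {term.name!r}"
                ) from None
            if term.covariance == "additive":
                if relinv is None:
                    raise ValueError(f"term {term.name!r} needs a relationship inverse")
                block = _kron_full_block(relinv.matrix, Kinv)
            else:
                block = _kron_full_block(sparse.identity(nlev, format="csc"), Kinv)
            block = sparse.coo_matrix(block)
            rows.append(block.row + off)
            cols.append(block.col + off)
            vals.append(block.data)
            self.offsets[term.name] = (off, nlev, q)
            off += nlev * q
        self.C = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(dim, dim),
        ).tocsc()
        self.rhs = WtRi @ design.y
        self.n = design.y.size
        self._factor = None
        self._dense = None
        self._solution = None

    # -- factorization ----------------------------------------------------
    def factorize(self) -> None:
        if self._factor is not None:
            return
        dim = self.C.shape[0]
        if dim <= self.dense_threshold:
            Cd = self.C.toarray()
            cf = cho_factor(Cd, lower=True)
            self.logdet_C = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
            self._factor = ("dense", cf)
        else:
            fac = SymmetricSparseFactor(
                self.C.tocsc(),
                block_of=self._block_membership(),
                cache=self.factor_cache,
            )
            self.logdet_C = fac.logdet
            self._factor = ("sparse_sym", fac)

    def _block_membership(self) -> np.ndarray:
        """Supernode id per equation: fixed effects in one block, and all of
        a subject's regression coefficients (across terms) in one block, so
        the factorization's elimination graph is the animal graph."""
        block_of = np.zeros(self.C.shape[0], dtype=np.int64)
        if self.relinv is not None:
            pos = {int(a): i + 1 for i, a in enumerate(self.relinv.ids)}
            next_free = len(pos) + 1
        else:
            pos = {}
            next_free = 1
        for term in self.design.spec.terms:
            off, nlev, q = self.offsets[term.name]
            levels = self.design.term_levels[term.name]
            for i, lev in enumerate(levels):
                b = pos.get(int(lev))
                if b is None:
                    b = next_free
                    pos[int(lev)] = b
                    next_free += 1
                block_of[off + i * q : off + (i + 1) * q] = b
        # compress ids in case some never occurred
        used = np.unique(block_of)
        remap = np.zeros(int(used.max()) + 1, dtype=np.int64)
        remap[used] = np.arange(used.size)
        return remap[block_of]

    def solve(self, b: np.ndarray) -> np.ndarray:
        self.factorize()
        kind, fac = self._factor
        if kind == "dense":
            return cho_solve(fac, b)
        return fac.solve(b)

    def solution(self) -> np.ndarray:
        if self._solution is None:
            self._solution = self.solve(self.rhs)
        return self._solution

    def dense_inverse(self) -> np.ndarray:
        if self._dense is None:
            self.factorize()
            kind, fac = self._factor
            if kind != "dense":
                raise RuntimeError("dense inverse requested on a sparse factorization")
            self._dense = cho_solve(fac, np.eye(self.C.shape[0]))
        return self._dense

    # -- derived quantities ------------------------------------------------
    def ypy(self) -> float:
        y = self.design.y
        return float(y @ (self.rinv * y) - self.solution() @ self.rhs)

    def projected(self, v: np.ndarray) -> np.ndarray:
        """Apply the REML projector P = R^-1 - R^-1 W C^-1 W' R^-1."""
        rv = self.rinv[:, None] * v if v.ndim == 2 else self.rinv * v
        sol = self.solve(self.W.T @ rv)
        back = self.W @ sol
        return rv - (self.rinv[:, None] * back if v.ndim == 2 else self.rinv * back)

    def logdet_R(self) -> float:
        counts = np.bincount(self.design.age_class, minlength=self.design.n_classes)
        return float(np.sum(counts * np.log(self.vc.sigma2_e)))

    def logdet_G(self) -> float:
        total = 0.0
        for term in self.design.spec.terms:
            _, nlev, q = self.offsets[term.name]
            sign, ld = np.linalg.slogdet(self.vc.K[term.name])
            if sign <= 0:
                raise np.linalg.LinAlgError(f"K for {term.name!r} not positive definite")
            total += nlev * ld
            if term.covariance == "additive":
                total += q * self.relinv.logdet
        return total

    def restricted_loglik(self) -> float:
        self.factorize()
        n_p = self.n - self.p_fixed
        return -0.5 * (
            self.ypy()
            + self.logdet_R()
            + self.logdet_G()
            + self.logdet_C
            + n_p * np.log(_TWO_PI)
        )


def assemble_mme(
    design: DesignMatrices,
    vc: VarianceComponents,
    relinv: RelationshipInverse | None = None,
    dense_threshold: int = 2600,
) -> MMESystem:
    return MMESystem(design, vc, relinv, dense_threshold)


@dataclass
class EvaluationResult:
    """Solutions of one evaluation: fixed effects and RR coefficients."""

    fixed: pd.Series
    coefficients: dict
    spec: ModelSpec
    vc: VarianceComponents
    meta: dict = field(default_factory=dict)


def solve_mme(system: MMESystem) -> EvaluationResult:
    sol = system.solution()
    design = system.design
    fixed = pd.Series(sol[: system.p_fixed], index=design.fixed_labels, name="estimate")
    coefficients = {}
    for term in design.spec.terms:
        off, nlev, q = system.offsets[term.name]
        block = sol[off : off + nlev * q].reshape(nlev, q)
        coefficients[term.name] = pd.DataFrame(
            block,
            index=pd.Index(design.term_levels[term.name], name=term.subject),
            columns=[f"c{l}" for l in range(q)],
        )
    resid = system.C @ sol - system.rhs
    return EvaluationResult(
        fixed=fixed,
        coefficients=coefficients,
        spec=design.spec,
        vc=system.vc,
        meta={
            "dim": system.C.shape[0],
            "residual_norm": float(np.linalg.norm(resid) / max(1.0, np.linalg.norm(system.rhs))),
        },
    )


def log_likelihood(
    design: DesignMatrices,
    vc: VarianceComponents,
    relinv: RelationshipInverse | None = None,
    dense_threshold: int = 2600,
) -> float:
    """Restricted log-likelihood (including the (n-p) log 2 pi constant)."""
    return MMESystem(design, vc, relinv, dense_threshold).restricted_loglik()


def ebv_per_age(
    result: EvaluationResult,
    basis: BasisMatrix | None = None,
    term: str | None = None,
) -> pd.DataFrame:
    """Per-age breeding values EBV(animal, t) = z(t)' alpha_hat.

    For the cumulative model (indicator basis) the single coefficient is the
    breeding value and one column ``ebv`` is returned.
    """
    if term is None:
        term = next(t.name for t in result.spec.terms if t.covariance == "additive")
    spec_term = next(t for t in result.spec.terms if t.name == term)
    coefs = result.coefficients[term]
    if spec_term.basis == "indicator":
        return coefs.rename(columns={"c0": "ebv"})
    if basis is None:
        raise ValueError("a basis matrix is required for regression terms")
    if basis.n_coef != spec_term.n_coef:
        raise ValueError(
            f"basis has {basis.n_coef} columns but term {term!r} expects {spec_term.n_coef}"
        )
    vals = coefs.to_numpy() @ basis.values.T
    return pd.DataFrame(vals, index=coefs.index, columns=list(basis.grid.ages))


def aggregate_cumulative(data: pd.DataFrame) -> pd.DataFrame:
    """Collapse biweekly records to one cumulative record per hen and trait.

    The cumulative record is the mean percentage across a hen's recorded
    ages (the whole-lay summary); cohort factors and the mate are constant
    within hen and carried through.
    """
    keys = ["trait", "hen"] if "trait" in data.columns else ["hen"]
    agg = {"value": "mean", "hatch_week": "first"}
    if "tom" in data.columns:
        agg["tom"] = "first"
    out = data.groupby(keys, as_index=False).agg(agg)
    return out


# -- REML --------------------------------------------------------------------

@dataclass
class REMLOptions:
    max_iter: int = 60
    tol_logL: float = 1e-8
    tol_param: float = 1e-6
    tol_flat: float = 1e-4  # plateau rule: three consecutive tiny gains
    dense_threshold: int = 1200
    max_halvings: int = 8
    max_step: float = 2.0
    min_residual_frac: float = 1e-8
    k_floor_frac: float = 1e-6  # constant ridge on each K, x var(y)
    verbose: bool = False


@dataclass
class REMLResult:
    vc: VarianceComponents
    logL: float
    converged: bool
    n_iter: int
    trace: list
    status: str
    spec: ModelSpec


def default_start(
    design: DesignMatrices, grid: AgeGrid | None = None
) -> VarianceComponents:
    """Half the phenotypic variance to the residual, the rest split equally
    over random terms with diagonal K scaled so each term contributes its
    share of per-age variance."""
    spec = design.spec
    s2p = float(np.var(design.y))
    share = 0.5 * s2p / max(1, len(spec.terms))
    K = {}
    for term in spec.terms:
        q = term.n_coef
        if term.basis == "indicator":
            K[term.name] = np.array([[share]])
        else:
            g = grid or design.grid or AgeGrid()
            phi2 = np.mean(legendre_matrix(g, term.order).values ** 2, axis=0)
            K[term.name] = np.diag(share / (q * phi2))
    sigma2_e = np.full(design.n_classes, 0.5 * s2p)
    return VarianceComponents(K, sigma2_e)


class _ParamMap:
    """Log-Cholesky parameterization of all (co)variance parameters.

    Each K is LL' plus a small constant ridge ``k_floor`` (a fraction of
    the phenotypic variance).  The ridge keeps every K's condition number
    bounded when a component sits on the boundary, which the exact trace
    identities of the REML score need; it is far below any scientifically
    meaningful variance.
    """

    def __init__(self, spec: ModelSpec, n_classes: int, floor: float, k_floor: float = 0.0):
        self.spec = spec
        self.n_classes = n_classes
        self.floor = floor
        self.k_floor = k_floor
        self.entries: list[tuple] = []
        for t_idx, term in enumerate(spec.terms):
            q = term.n_coef
            for a in range(q):
                for b in range(a + 1):
                    self.entries.append(("K", t_idx, a, b))
        for c in range(n_classes):
            self.entries.append(("resid", c))
        self.n_params = len(self.entries)

    def pack(self, vc: VarianceComponents) -> np.ndarray:
        theta = np.empty(self.n_params)
        chols = {}
        for t_idx, term in enumerate(self.spec.terms):
            K = vc.K[term.name]
            q = K.shape[0]
            chols[t_idx] = np.linalg.cholesky(K + 1e-10 * np.trace(K) / q * np.eye(q))
        for i, ent in enumerate(self.entries):
            if ent[0] == "K":
                _, t_idx, a, b = ent
                L = chols[t_idx]
                theta[i] = np.log(L[a, a]) if a == b else L[a, b]
            else:
                theta[i] = np.log(vc.sigma2_e[ent[1]])
        return theta

    def chol(self, theta: np.ndarray, t_idx: int) -> np.ndarray:
        q = self.spec.terms[t_idx].n_coef
        L = np.zeros((q, q))
        for i, ent in enumerate(self.entries):
            if ent[0] == "K" and ent[1] == t_idx:
                _, _, a, b = ent
                L[a, b] = np.exp(theta[i]) if a == b else theta[i]
        return L

    def unpack(self, theta: np.ndarray) -> VarianceComponents:
        K = {}
        for t_idx, term in enumerate(self.spec.terms):
            L = self.chol(theta, t_idx)
            K[term.name] = L @ L.T + self.k_floor * np.eye(L.shape[0])
        sigma2_e = np.empty(self.n_classes)
        for i, ent in enumerate(self.entries):
            if ent[0] == "resid":
                sigma2_e[ent[1]] = max(np.exp(theta[i]), self.floor)
        return VarianceComponents(K, sigma2_e)

    def dK(self, theta: np.ndarray, idx: int) -> np.ndarray:
        """dK/d theta_idx for a K entry (None for residual entries)."""
        ent = self.entries[idx]
        if ent[0] != "K":
            return None
        _, t_idx, a, b = ent
        L = self.chol(theta, t_idx)
        q = L.shape[0]
        dL = np.zeros((q, q))
        dL[a, b] = L[a, a] if a == b else 1.0
        return dL @ L.T + L @ dL.T


class _AIREML:
    def __init__(
        self,
        design: DesignMatrices,
        relinv: RelationshipInverse | None,
        options: REMLOptions,
    ):
        self.design = design
        self.relinv = relinv
        self.options = options
        self.spec = design.spec
        var_y = float(np.var(design.y))
        self.pm = _ParamMap(
            self.spec,
            design.n_classes,
            options.min_residual_frac * var_y,
            k_floor=options.k_floor_frac * var_y,
        )
        self.need_rel = any(t.covariance == "additive" for t in self.spec.terms)
        self.rel_factor = splu(relinv.matrix.tocsc()) if self.need_rel else None
        self.sym_cache = _SymbolicCache()

    # ∂V/∂theta_i applied to a matrix of vectors
    def dV_apply(self, theta: np.ndarray, idx: int, V: np.ndarray) -> np.ndarray:
        ent = self.pm.entries[idx]
        V2 = V if V.ndim == 2 else V[:, None]
        if ent[0] == "resid":
            c = ent[1]
            sigma2 = max(np.exp(theta[idx]), self.pm.floor)
            out = np.zeros_like(V2)
            mask = self.design.age_class == c
            out[mask] = sigma2 * V2[mask]
        else:
            _, t_idx, _, _ = ent
            term = self.spec.terms[t_idx]
            dK = self.pm.dK(theta, idx)
            Z = self.design.Z[term.name]
            nlev = self.design.term_levels[term.name].size
            q = term.n_coef
            m = V2.shape[1]
            U = (Z.T @ V2).reshape(nlev, q, m)
            M = np.einsum("lqm,qr->lrm", U, dK)
            if term.covariance == "additive":
                M = self.rel_factor.solve(M.reshape(nlev, q * m)).reshape(nlev, q, m)
            out = Z @ M.reshape(nlev * q, m)
        return out if V.ndim == 2 else out[:, 0]

    def evaluate(self, theta: np.ndarray):
        vc = self.pm.unpack(theta)
        system = MMESystem(
            self.design,
            vc,
            self.relinv,
            self.options.dense_threshold,
            factor_cache=self.sym_cache,
        )
        system.factorize()
        sol = system.solution()
        Py = system.rinv * (self.design.y - system.W @ sol)
        return vc, system, Py, system.restricted_loglik()

    def traces_exact(self, theta, system: MMESystem) -> np.ndarray:
        Cinv = system.dense_inverse()
        tr = np.empty(self.pm.n_params)
        W = system.W.tocsr()
        for i, ent in enumerate(self.pm.entries):
            if ent[0] == "resid":
                c = ent[1]
                sigma2 = system.vc.sigma2_e[c]
                mask = self.design.age_class == c
                n_c = int(mask.sum())
                Wc = W[mask]
                Sc = (Wc.T @ Wc).tocoo()
                t2 = float(np.sum(Sc.data * Cinv[Sc.col, Sc.row]))
                tr[i] = n_c - t2 / sigma2
            else:
                _, t_idx, _, _ = ent
                term = self.spec.terms[t_idx]
                off, nlev, q = system.offsets[term.name]
                K = system.vc.K[term.name]
                Kinv = np.linalg.inv(K)
                dK = self.pm.dK(theta, i)
                B = Kinv @ dK @ Kinv
                t1 = nlev * float(np.trace(Kinv @ dK))
                rel = (
                    self.relinv.matrix
                    if term.covariance == "additive"
                    else sparse.identity(nlev, format="csc")
                )
                Q = sparse.kron(rel, B).tocoo()
                Cblk = Cinv[off : off + nlev * q, off : off + nlev * q]
                t2 = float(np.sum(Q.data * Cblk[Q.col, Q.row]))
                tr[i] = t1 - t2
        return tr

    def traces_sparse(self, theta, system: MMESystem) -> np.ndarray:
        """Exact traces tr(P dV_i) from the Takahashi selected inverse.

        Uses the mixed-model identities
        tr(P Z (Rel x dK) Z') = nlev tr(K^-1 dK) - tr(C^uu (Rel^-1 x K^-1 dK K^-1))
        and, for a residual class on the log scale,
        tr(P dV_c) = n_c - tr(C^-1 W_c' W_c) / sigma2_c.
        Every trace only touches C^-1 on the sparsity pattern of C, which
        the selected inverse provides exactly.
        """
        kind, fac = system._factor
        if kind != "sparse_sym":
            raise RuntimeError("sparse exact traces need a symmetric factorization")
        dim = system.C.shape[0]
        W = system.W.tocsr()
        tr = np.empty(self.pm.n_params)
        for i, ent in enumerate(self.pm.entries):
            if ent[0] == "resid":
                c = ent[1]
                sigma2 = system.vc.sigma2_e[c]
                mask = self.design.age_class == c
                n_c = int(mask.sum())
                Wc = W[mask]
                Sc = (Wc.T @ Wc).tocoo()
                tr[i] = n_c - fac.trace_inverse_product(Sc) / sigma2
            else:
                _, t_idx, _, _ = ent
                term = self.spec.terms[t_idx]
                off, nlev, q = system.offsets[term.name]
                K = system.vc.K[term.name]
                Kinv = np.linalg.inv(K)
                dK = self.pm.dK(theta, i)
                B = Kinv @ dK @ Kinv
                t1 = nlev * float(np.trace(Kinv @ dK))
                rel = (
                    self.relinv.matrix
                    if term.covariance == "additive"
                    else sparse.identity(nlev, format="csc")
                )
                Q = sparse.kron(rel, B).tocoo()
                Qg = sparse.coo_matrix(
                    (Q.data, (Q.row + off, Q.col + off)), shape=(dim, dim)
                )
                tr[i] = t1 - fac.trace_inverse_product(Qg)
        return tr

    def score_and_ai(self, theta, system: MMESystem, Py: np.ndarray):
        npar = self.pm.n_params
        n = Py.size
        F = np.empty((n, npar))
        for i in range(npar):
            F[:, i] = self.dV_apply(theta, i, Py)
        PF = system.projected(F)
        AI = 0.5 * (F.T @ PF)
        AI = 0.5 * (AI + AI.T)
        quad = F.T @ Py
        if system.C.shape[0] <= self.options.dense_threshold:
            tr = self.traces_exact(theta, system)
        else:
            tr = self.traces_sparse(theta, system)
        score = -0.5 * (tr - quad)
        return score, AI

    def run(self, start: VarianceComponents) -> REMLResult:
        opts = self.options
        theta = self.pm.pack(start)
        vc, system, Py, logL = self.evaluate(theta)
        trace = [(0, logL)]
        converged = False
        status = "max_iterations"
        it = 0
        lam = 1e-6  # Levenberg-Marquardt damping, adapted across iterations
        flat_run = 0
        for it in range(1, opts.max_iter + 1):
            score, AI = self.score_and_ai(theta, system, Py)
            scale = max(1.0, float(np.max(np.abs(np.diag(AI)))))
            accepted = False
            for _ in range(opts.max_halvings):
                try:
                    delta = np.linalg.solve(
                        AI + lam * scale * np.eye(AI.shape[0]), score
                    )
                except np.linalg.LinAlgError:
                    lam = max(lam * 10.0, 1e-4)
                    continue
                if float(score @ delta) <= 0.0:
                    lam = max(lam * 10.0, 1e-4)
                    continue
                norm = float(np.max(np.abs(delta)))
                if norm > opts.max_step:
                    delta *= opts.max_step / norm
                cand = theta + delta
                try:
                    vc_c, sys_c, Py_c, logL_c = self.evaluate(cand)
                except np.linalg.LinAlgError:
                    lam = max(lam * 10.0, 1e-4)
                    continue
                # tolerance scaled to the likelihood's numerical resolution,
                # so long Newton steps along flat directions are not rejected
                # for rounding-level wiggles
                if logL_c >= logL - 1e-9 * max(1.0, abs(logL)):
                    accepted = True
                    lam = max(lam / 100.0, 1e-8)
                    break
                lam = max(lam * 10.0, 1e-4)
            if not accepted:
                status = "stalled"
                converged = float(np.max(np.abs(score))) < 1e-2
                break
            d_logL = logL_c - logL
            d_par = float(np.max(np.abs(cand - theta) / np.maximum(1.0, np.abs(theta))))
            theta, vc, system, Py, logL = cand, vc_c, sys_c, Py_c, logL_c
            trace.append((it, logL))
            if abs(d_logL) < opts.tol_logL and d_par < opts.tol_param:
                converged = True
                status = "converged"
                break
            flat_run = flat_run + 1 if abs(d_logL) < opts.tol_flat else 0
            if flat_run >= 3:
                # likelihood plateau (typically a boundary drift in a
                # near-singular K direction); estimates are stable
                converged = True
                status = "flat"
                break
        return REMLResult(
            vc=vc,
            logL=logL,
            converged=converged,
            n_iter=it,
            trace=trace,
            status=status,
            spec=self.spec,
        )


def _profile_reml(
    design: DesignMatrices,
    relinv: RelationshipInverse,
    options: REMLOptions,
) -> REMLResult:
    """Exact REML for one scalar random term with homogeneous residual.

    Profiles the likelihood over the variance ratio lambda = sigma2_e /
    sigma2_a and maximizes it by bounded scalar search.
    """
    spec = design.spec
    term = spec.terms[0]
    X, Z, y = design.X, design.Z[term.name], design.y
    n, p = y.size, X.shape[1]
    nlev = design.term_levels[term.name].size
    XtX = (X.T @ X).tocsc()
    XtZ = (X.T @ Z).tocsc()
    ZtZ = (Z.T @ Z).tocsc()
    Relinv = relinv.matrix.tocsc()
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    yty = float(y @ y)

    def neg2(loglam: float) -> tuple[float, float]:
        lam = np.exp(loglam)
        C0 = sparse.bmat(
            [[XtX, XtZ], [XtZ.T, ZtZ + lam * Relinv]], format="csc"
        )
        lu = splu(C0, permc_spec="MMD_AT_PLUS_A", options={"SymmetricMode": True})
        logdet_C0 = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        sol = lu.solve(rhs)
        ypy0 = yty - float(sol @ rhs)
        sigma2_e = max(ypy0 / (n - p), options.min_residual_frac * float(np.var(y)))
        val = (
            (n - p) * np.log(_TWO_PI)
            + (n - p) * np.log(sigma2_e)
            + (n - p)
            + logdet_C0
            + nlev * (-loglam)
            + relinv.logdet
        )
        return val, sigma2_e

    res = minimize_scalar(
        lambda t: neg2(t)[0],
        bounds=(np.log(1e-4), np.log(1e6)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    val, sigma2_e = neg2(res.x)
    lam = float(np.exp(res.x))
    vc = VarianceComponents({term.name: np.array([[sigma2_e / lam]])}, np.array([sigma2_e]))
    return REMLResult(
        vc=vc,
        logL=-0.5 * val,
        converged=res.success,
        n_iter=int(res.nfev),
        trace=[(int(res.nfev), -0.5 * val)],
        status="converged" if res.success else "search_failed",
        spec=spec,
    )


def reml_estimate(
    spec: ModelSpec,
    data: pd.DataFrame,
    ped: Pedigree | None = None,
    relinv: RelationshipInverse | None = None,
    start: VarianceComponents | None = None,
    grid: AgeGrid | None = None,
    options: REMLOptions | None = None,
) -> REMLResult:
    """Estimate variance components by restricted maximum likelihood.

    ``relinv`` supplies the relationship inverse for additive terms
    (pedigree A^-1 by default, built from ``ped``; pass an H^-1 parts object
    for single-step evaluation).
    """
    options = options or REMLOptions()
    design = build_design(spec, data, ped=ped, grid=grid)
    if relinv is None and any(t.covariance == "additive" for t in spec.terms):
        if ped is None:
            raise ValueError("additive terms need a pedigree or relationship inverse")
        relinv = pedigree_relationship_inverse(ped)
    single_scalar = (
        len(spec.terms) == 1
        and spec.terms[0].n_coef == 1
        and design.n_classes == 1
        and spec.terms[0].covariance == "additive"
    )
    if single_scalar and start is None:
        return _profile_reml(design, relinv, options)
    start = start or default_start(design, grid)
    return _AIREML(design, relinv, options).run(start)
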
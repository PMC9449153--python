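"""Pedigree and genomic relationship matrices for single-step evaluation.

This module holds everything relationship-shaped:

* ``Pedigree`` with inbreeding coefficients via the Meuwissen–Luo recursion,
* the numerator relationship matrix ``A`` (tabular method) and its sparse
  inverse from Henderson's rules with inbreeding,
* VanRaden's genomic relationship matrix ``G`` from centered SNP dosages,
* SNP quality control (autosome / MAF / Hardy–Weinberg filters),
* the single-step inverse ``H^-1 = A^-1 + [0 0; 0 (w G + (1-w) A22)^-1 - A22^-1]``
  with the genotyped-block correction kept as explicit parts.

Allele frequencies used in ``G`` are the observed frequencies in the
genotyped set; the blend weight defaults to ``w = 0.95``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import chi2

__all__ = [
    "Pedigree",
    "GenotypeMatrix",
    "QCResult",
    "RelationshipInverse",
    "HInverseParts",
    "qc_filter",
    "build_A",
    "build_A_inverse",
    "pedigree_relationship_inverse",
    "build_G",
    "build_H_inverse",
]

UNKNOWN = -1  # internal position code for a missing parent


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Ordered pedigree: parents precede offspring.

    ``sire``/``dam`` hold positions into ``ids`` (-1 = unknown parent).
    ``sex`` ('F'/'M') and ``generation`` are optional annotations used by the
    simulator and by forward validation; ``matings`` optionally records the
    hen -> tom mate assignment of a simulated breeding program.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray | None = None
    generation: np.ndarray | None = None
    matings: pd.DataFrame | None = None
    _pos: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = self.ids.size
        if len(set(self.ids.tolist())) != n:
            raise PedigreeError("duplicate animal ids in pedigree")
        for arr in (self.sire, self.dam):
            if arr.size != n:
                raise PedigreeError("sire/dam arrays must match ids")
            bad = arr >= np.arange(n)
            if np.any(bad & (arr != UNKNOWN)):
                raise PedigreeError("every parent must precede its offspring")
            if np.any(arr < UNKNOWN):
                raise PedigreeError("parent positions must be >= -1")
        self._pos = {int(a): i for i, a in enumerate(self.ids)}

    # -- construction -----------------------------------------------------
    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Pedigree":
        """Build from a DataFrame with columns id, sire, dam (0/NA = unknown).

        Rows may be in any order; a topological sort (parents first) is
        applied and cycles (an animal its own ancestor) are rejected.
        """
        df = frame.copy()
        for col in ("id", "sire", "dam"):
            if col not in df.columns:
                raise PedigreeError(f"pedigree frame lacks column {col!r}")
            df[col] = pd.to_numeric(df[col], errors="raise").fillna(0).astype(np.int64)
        ids = df["id"].to_numpy()
        known = set(ids.tolist())
        parents = {
            int(r.id): tuple(int(p) for p in (r.sire, r.dam) if p != 0)
            for r in df.itertuples()
        }
        for a, ps in parents.items():
            for p in ps:
                if p not in known:
                    raise PedigreeError(f"parent {p} of animal {a} has no pedigree row")
        order: list[int] = []
        state: dict[int, int] = {}

        def visit(a: int) -> None:
            stack = [(a, iter(parents[a]))]
            state[a] = 1
            while stack:
                node, it = stack[-1]
                for p in it:
                    st = state.get(p, 0)
                    if st == 1:
                        raise PedigreeError(f"animal {node} is its own ancestor")
                    if st == 0:
                        state[p] = 1
                        stack.append((p, iter(parents[p])))
                        break
                else:
                    stack.pop()
                    state[node] = 2
                    order.append(node)

        for a in ids:
            if state.get(int(a), 0) == 0:
                visit(int(a))
        pos = {a: i for i, a in enumerate(order)}
        sire = np.array(
            [pos[parents[a][0]] if len(parents[a]) >= 1 else UNKNOWN for a in order]
        )
        dam = np.array(
            [pos[parents[a][1]] if len(parents[a]) >= 2 else UNKNOWN for a in order]
        )
        extra = {}
        if "sex" in df.columns:
            by_id = df.set_index("id")["sex"]
            extra["sex"] = np.array([by_id[a] for a in order])
        if "generation" in df.columns:
            by_id = df.set_index("id")["generation"]
            extra["generation"] = np.array([int(by_id[a]) for a in order])
        return cls(np.array(order), sire, dam, **extra)

    # -- basic accessors --------------------------------------------------
    @property
    def n(self) -> int:
        return self.ids.size

    def positions(self, ids) -> np.ndarray:
        """Positions of animal ids (error on unknown id)."""
        try:
            return np.array([self._pos[int(a)] for a in np.atleast_1d(ids)], dtype=int)
        except KeyError as exc:
            raise PedigreeError(f"animal id {exc.args[0]} not in pedigree") from None

    def generation_of(self, ids) -> np.ndarray:
        if self.generation is None:
            raise PedigreeError("pedigree carries no generation annotation")
        return self.generation[self.positions(ids)]

    # -- inbreeding (Meuwissen & Luo recursion) ---------------------------
    @cached_property
    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficient F per animal."""
        return self._f_and_d[0]

    @cached_property
    def mendelian_variance(self) -> np.ndarray:
        """Within-family (Mendelian sampling) variance d per animal.

        d = 1 (no parents), 0.75 - F_p/4 (one parent),
        0.5 - (F_s + F_d)/4 (both parents); these are the diagonal of D in
        the A = T D T' decomposition, so log|A| = sum(log d).
        """
        return self._f_and_d[1]

    @cached_property
    def _f_and_d(self) -> tuple[np.ndarray, np.ndarray]:
        n = self.n
        F = np.zeros(n)
        D = np.ones(n)
        sire, dam = self.sire, self.dam
        for i in range(n):
            s, d = sire[i], dam[i]
            if s == UNKNOWN and d == UNKNOWN:
                D[i] = 1.0
                continue
            if s == UNKNOWN or d == UNKNOWN:
                p = s if s != UNKNOWN else d
                D[i] = 0.75 - 0.25 * F[p]
                continue
            D[i] = 0.5 - 0.25 * (F[s] + F[d])
            # a_ii of animal i via path coefficients over its ancestors
            L = np.zeros(i + 1)
            L[i] = 1.0
            aii = 0.0
            for j in range(i, -1, -1):
                lj = L[j]
                if lj == 0.0:
                    continue
                aii += lj * lj * D[j]
                if sire[j] != UNKNOWN:
                    L[sire[j]] += 0.5 * lj
                if dam[j] != UNKNOWN:
                    L[dam[j]] += 0.5 * lj
            F[i] = aii - 1.0
        return F, D

    @property
    def logdet_A(self) -> float:
        return float(np.sum(np.log(self.mendelian_variance)))


# -- numerator relationship matrix -----------------------------------------

def build_A(ped: Pedigree, subset=None) -> np.ndarray:
    """Additive (numerator) relationship matrix by the tabular method.

    Diagonal is ``1 + F``.  With ``subset`` (animal ids), returns the
    corresponding block of the full matrix (rows/columns in subset order).
    """
    n = ped.n
    A = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        if s != UNKNOWN and d != UNKNOWN:
            row = 0.5 * (A[s, :i] + A[d, :i])
            diag = 1.0 + 0.5 * A[s, d]
        elif s != UNKNOWN or d != UNKNOWN:
            p = s if s != UNKNOWN else d
            row = 0.5 * A[p, :i]
            diag = 1.0
        else:
            row = np.zeros(i)
            diag = 1.0
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = diag
    if subset is not None:
        idx = ped.positions(subset)
        A = A[np.ix_(idx, idx)]
    return A


def build_A_inverse(ped: Pedigree) -> sparse.csr_matrix:
    """Sparse inverse of A by Henderson's rules with inbreeding."""
    n = ped.n
    d = ped.mendelian_variance
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i in range(n):
        alpha = 1.0 / d[i]
        parents = [p for p in (ped.sire[i], ped.dam[i]) if p != UNKNOWN]
        rows.append(i)
        cols.append(i)
        vals.append(alpha)
        for p in parents:
            rows += [i, p]
            cols += [p, i]
            vals += [-0.5 * alpha, -0.5 * alpha]
        for p in parents:
            for q in parents:
                rows.append(p)
                cols.append(q)
                vals.append(0.25 * alpha)
    return sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


@dataclass(frozen=True)
class RelationshipInverse:
    """A relationship inverse together with log|Rel| (of the matrix itself)."""

    matrix: sparse.spmatrix
    logdet: float
    ids: np.ndarray


def pedigree_relationship_inverse(ped: Pedigree) -> RelationshipInverse:
    return RelationshipInverse(
        matrix=build_A_inverse(ped).tocsc(), logdet=ped.logdet_A, ids=ped.ids
    )


# -- genotypes --------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """SNP dosages (animals x markers, coded 0/1/2) with marker metadata.

    ``marker_meta`` columns: marker, chromosome (str; non-numeric labels such
    as 'Z' mark non-autosomal markers), position.
    """

    dosages: np.ndarray
    animal_ids: np.ndarray
    marker_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        self.animal_ids = np.asarray(self.animal_ids, dtype=np.int64)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (animals x markers)")
        if self.dosages.shape[0] != self.animal_ids.size:
            raise ValueError("animal_ids must match dosage rows")
        if self.dosages.shape[1] != len(self.marker_meta):
            raise ValueError("marker_meta must match dosage columns")
        vals = np.unique(self.dosages)
        if not np.all(np.isin(vals, [0, 1, 2])):
            raise ValueError("dosages must be coded 0/1/2 (no missing values)")

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Observed counted-allele frequency per marker."""
        return self.dosages.mean(axis=0) / 2.0


@dataclass
class QCResult:
    genotypes: GenotypeMatrix
    exclusions: pd.DataFrame  # marker, reason, statistic


def _hwe_chi2_pvalues(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """1-df chi-square Hardy–Weinberg test from genotype counts per marker."""
    n = dosages.shape[0]
    n2 = (dosages == 2).sum(axis=0)
    n1 = (dosages == 1).sum(axis=0)
    n0 = n - n1 - n2
    p = (2 * n2 + n1) / (2.0 * n)
    q = 1.0 - p
    exp = np.stack([n * q * q, 2 * n * p * q, n * p * p])
    obs = np.stack([n0, n1, n2]).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0)
    stat = contrib.sum(axis=0)
    return stat, chi2.sf(stat, df=1)


def qc_filter(
    geno: GenotypeMatrix, maf_min: float = 0.05, hwe_alpha: float = 1e-8
) -> QCResult:
    """Marker quality control: autosomes only, MAF and Hardy–Weinberg filters.

    Removes non-autosomal markers (chromosome label not a positive integer),
    markers with minor-allele frequency strictly below ``maf_min``, and
    markers whose 1-df chi-square Hardy–Weinberg P-value is below
    ``hwe_alpha``.  Idempotent; raises if nothing survives.
    """
    chrom = geno.marker_meta["chromosome"].astype(str)
    autosomal = chrom.str.fullmatch(r"\d+").to_numpy()
    p = geno.allele_frequencies()
    maf = np.minimum(p, 1.0 - p)
    hwe_stat, hwe_p = _hwe_chi2_pvalues(geno.dosages)

    reasons = np.full(geno.n_markers, "", dtype=object)
    stats = np.full(geno.n_markers, np.nan)
    drop = ~autosomal
    reasons[drop] = "non_autosomal"
    m = autosomal & (maf < maf_min)
    reasons[m], stats[m], drop = "maf", maf[m], drop | m
    m = autosomal & ~(maf < maf_min) & (hwe_p < hwe_alpha)
    reasons[m], stats[m], drop = "hwe", hwe_p[m], drop | m

    if drop.all():
        raise ValueError("quality control removed every marker")
    keep = ~drop
    excl = pd.DataFrame(
        {
            "marker": geno.marker_meta["marker"].to_numpy()[drop],
            "reason": reasons[drop],
            "statistic": stats[drop],
        }
    )
    filtered = GenotypeMatrix(
        dosages=geno.dosages[:, keep],
        animal_ids=geno.animal_ids,
        marker_meta=geno.marker_meta.loc[keep].reset_index(drop=True),
    )
    return QCResult(genotypes=filtered, exclusions=excl)


def build_G(geno: GenotypeMatrix) -> np.ndarray:
    """VanRaden genomic relationship matrix ZZ' / (2 sum p(1-p)).

    ``Z`` centers dosages by twice the observed allele frequency in the
    genotyped set.  Monomorphic markers make the scale undefined and raise.
    """
    p = geno.allele_frequencies()
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError(
            "monomorphic marker encountered; run qc_filter before build_G"
        )
    Z = geno.dosages.astype(float) - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    return (Z @ Z.T) / denom


# -- single-step H inverse ---------------------------------------------------

@dataclass
class HInverseParts:
    """Parts of the single-step inverse relationship matrix.

    ``correction = (w G + (1-w) A22)^-1 - A22^-1`` lives on the genotyped
    block; the assembled sparse ``matrix`` is ``A^-1`` plus the scattered
    correction.  ``logdet`` is log|H| = log|A| + log|blend| - log|A22|.
    """

    A_inv: sparse.spmatrix
    A22_inv: np.ndarray
    G_blend_inv: np.ndarray
    genotyped_positions: np.ndarray
    genotyped_ids: np.ndarray
    ids: np.ndarray
    w_g: float
    logdet_A: float
    logdet_blend: float
    logdet_A22: float

    @property
    def correction(self) -> np.ndarray:
        return self.G_blend_inv - self.A22_inv

    @cached_property
    def matrix(self) -> sparse.csc_matrix:
        H = self.A_inv.tocoo()
        k = self.genotyped_positions.size
        if k == 0:
            return self.A_inv.tocsc()
        gi = self.genotyped_positions
        rows = np.repeat(gi, k)
        cols = np.tile(gi, k)
        corr = sparse.coo_matrix(
            (self.correction.ravel(), (rows, cols)), shape=H.shape
        )
        return (H + corr).tocsc()

    @property
    def logdet(self) -> float:
        return self.logdet_A + self.logdet_blend - self.logdet_A22


def build_H_inverse(
    ped: Pedigree, geno: GenotypeMatrix | None, w_g: float = 0.95
) -> HInverseParts:
    """Assemble the parts of H^-1 for single-step evaluation.

    ``w_g`` is the weight on G in the blended genotyped-block matrix
    ``w_g G + (1 - w_g) A22`` (default 0.95).  With no genotyped animals the
    correction is empty and H^-1 reduces to A^-1 exactly.
    """
    if not 0.0 < w_g <= 1.0:
        raise ValueError("blend weight must be in (0, 1]")
    A_inv = build_A_inverse(ped).tocsc()
    if geno is None or geno.n_animals == 0:
        return HInverseParts(
            A_inv=A_inv,
            A22_inv=np.zeros((0, 0)),
            G_blend_inv=np.zeros((0, 0)),
            genotyped_positions=np.array([], dtype=int),
            genotyped_ids=np.array([], dtype=np.int64),
            ids=ped.ids,
            w_g=w_g,
            logdet_A=ped.logdet_A,
            logdet_blend=0.0,
            logdet_A22=0.0,
        )
    gpos = ped.positions(geno.animal_ids)
    A22 = build_A(ped, subset=geno.animal_ids)
    G = build_G(geno)
    blend = w_g * G + (1.0 - w_g) * A22
    sign_b, logdet_blend = np.linalg.slogdet(blend)
    if sign_b <= 0:
        raise np.linalg.LinAlgError(
            "blended genomic matrix is singular; increase the A22 share (1 - w_g)"
        )
    # plain symmetric inverses (genotyped blocks are modest-sized and dense)
    blend_inv = np.linalg.inv(blend)
    sign_a, logdet_A22 = np.linalg.slogdet(A22)
    if sign_a <= 0:
        raise np.linalg.LinAlgError("A22 is singular (duplicate animals?)")
    A22_inv = np.linalg.inv(A22)
    return HInverseParts(
        A_inv=A_inv,
        A22_inv=A22_inv,
        G_blend_inv=blend_inv,
        genotyped_positions=gpos,
        genotyped_ids=np.asarray(geno.animal_ids, dtype=np.int64),
        ids=ped.ids,
        w_g=w_g,
        logdet_A=ped.logdet_A,
        logdet_blend=float(logdet_blend),
        logdet_A22=float(logdet_A22),
    )
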
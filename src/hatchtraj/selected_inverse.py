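"""Blocked sparse LDL' factorization with a Takahashi selected inverse.

The AI-REML score needs traces tr(C^-1 M) where C is the (sparse, SPD)
mixed-model coefficient matrix and each M shares (a subset of) C's
sparsity pattern.  Dense inversion is infeasible at scale, but the entries
of C^-1 on the *filled* pattern of the Cholesky factor suffice, and the
Takahashi recurrences deliver exactly those at roughly the cost of the
factorization:

    Z_jj = D_j^-1 - sum_{k in S_j} L_kj' Z_kj
    Z_ij = -sum_{k in S_j} Z_(ik) L_kj          (i in S_j, i > j)

processed for block columns j from last to first, where S_j is the
off-diagonal block pattern of column j of the unit block-lower factor L
and Z_(ik) is the symmetric block lookup.

Mixed-model coefficient matrices are naturally blocked — one dense block
per animal holding all of its regression coefficients, plus one block of
fixed effects — so everything here works on that block structure:

* the fill-reducing ordering is a minimum-degree preorder of the collapsed
  animal graph (harvested from SuperLU);
* the symbolic analysis (block elimination tree, full column patterns,
  value offsets) runs once per pattern and is cached across the
  refactorizations of a REML fit;
* the numeric phase is a left-looking supernodal LDL' whose updates are
  dense panel products (BLAS via numba's np.dot);
* the selected inverse assembles, per block column, the dense clique
  submatrix of already-computed inverse entries and applies the Takahashi
  recurrence as one dense product per column.

Owning the factorization keeps numerically-zero entries in the stored
pattern, which the selected-inverse lookups require (general sparse LU
codes prune them).
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import sparse
from scipy.sparse.linalg import splu

__all__ = ["SymmetricSparseFactor"]


# -- small dense helpers -----------------------------------------------------

@njit(cache=True, inline="always")
def _chol_small(A, n):
    """In-place lower Cholesky of A[:n,:n]; returns False if not PD."""
    for j in range(n):
        s = A[j, j]
        for k in range(j):
            s -= A[j, k] * A[j, k]
        if s <= 0.0:
            return False
        A[j, j] = np.sqrt(s)
        for i in range(j + 1, n):
            t = A[i, j]
            for k in range(j):
                t -= A[i, k] * A[j, k]
            A[i, j] = t / A[j, j]
    return True


@njit(cache=True, inline="always")
def _chol_inverse(L, n, out):
    """Inverse of the SPD matrix whose lower Cholesky factor is L."""
    for j in range(n):
        for i in range(n):
            out[i, j] = 0.0
    for j in range(n):
        out[j, j] = 1.0 / L[j, j]
        for i in range(j + 1, n):
            s = 0.0
            for k in range(j, i):
                s -= L[i, k] * out[k, j]
            out[i, j] = s / L[i, i]
    for i in range(n):
        for j in range(i + 1):
            s = 0.0
            for k in range(i, n):
                s += out[k, i] * out[k, j]
            L[i, j] = s
    for i in range(n):
        for j in range(i + 1):
            out[i, j] = L[i, j]
            out[j, i] = L[i, j]


# -- symbolic phase ----------------------------------------------------------

@njit(cache=True)
def _symbolic_counts(n_b, Ap, Ai, bsz, parent, lnz, lvals, flag):
    """Elimination tree and per-column block/scalar counts (block-upper)."""
    for k in range(n_b):
        parent[k] = -1
        flag[k] = k
        lnz[k] = 0
        lvals[k] = 0
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            while i < k and flag[i] != k:
                if parent[i] == -1:
                    parent[i] = k
                lnz[i] += 1
                lvals[i] += bsz[k]
                flag[i] = k
                i = parent[i]


@njit(cache=True)
def _slot_value_offsets(n_b, Lbp, Lbi, bsz, Vbase, Lvoff):
    for j in range(n_b):
        off = Vbase[j]
        for slot in range(Lbp[j], Lbp[j + 1]):
            Lvoff[slot] = off
            off += bsz[Lbi[slot]] * bsz[j]


@njit(cache=True)
def _symbolic_pattern(n_b, Ap, Ai, parent, flag, Lbp, Lbi, fill):
    """Fill the block row indices of every L column (ascending order)."""
    for k in range(n_b):
        flag[k] = k
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            while i < k and flag[i] != k:
                Lbi[Lbp[i] + fill[i]] = k
                fill[i] += 1
                flag[i] = k
                i = parent[i]


# -- numeric phase (left-looking, panel updates) -----------------------------

@njit(cache=True, fastmath=True)
def _numeric_left(
    n_b, bsz, boff, blk,
    sAp, sAi, sAx,
    Lbp, Lbi, Lvoff, Vbase, colh,
    Lval, Dval, Dinv, Doff,
    head, nextc, hp, pos, F, max_sz,
):
    """Left-looking blocked LDL'.  Returns (failing block | -1, logdet)."""
    logdet = 0.0
    Dtmp = np.zeros((max_sz, max_sz))
    Itmp = np.zeros((max_sz, max_sz))
    for j in range(n_b):
        szj = bsz[j]
        oj = boff[j]
        nblk = Lbp[j + 1] - Lbp[j]
        H = szj + colh[j]  # scalar front height including the pivot block
        for a in range(H):
            for b in range(szj):
                F[a, b] = 0.0
        # scalar offset of every pattern block inside the front
        pos[j] = 0
        off = szj
        for slot in range(Lbp[j], Lbp[j + 1]):
            pos[Lbi[slot]] = off
            off += bsz[Lbi[slot]]
        # load the lower part of C's block column j
        for c in range(oj, oj + szj):
            for p in range(sAp[c], sAp[c + 1]):
                r = sAi[p]
                if r < oj:
                    continue
                rb = blk[r]
                F[pos[rb] + (r - boff[rb]), c - oj] += sAx[p]
        # apply updates from every column k with L_jk != 0
        k = head[j]
        while k != -1:
            knext = nextc[k]
            szk = bsz[k]
            slot0 = hp[k]
            v0 = Lvoff[slot0]
            vend = Vbase[k] + colh[k] * szk
            hK = (vend - v0) // szk
            panel = Lval[v0:vend].reshape(hK, szk)
            # T = D_k @ L_jk' (szk x szj); L_jk is the first block of panel
            T = np.empty((szk, szj))
            dv = Doff[k]
            for a in range(szk):
                for b in range(szj):
                    s = 0.0
                    for t in range(szk):
                        s += Dval[dv + a * szk + t] * panel[b, t]
                    T[a, b] = s
            U = np.dot(panel, T)  # (hK x szj)
            cursor = 0
            for slot2 in range(slot0, Lbp[k + 1]):
                r = Lbi[slot2]
                szr = bsz[r]
                fo = pos[r]
                for a in range(szr):
                    for b in range(szj):
                        F[fo + a, b] -= U[cursor + a, b]
                cursor += szr
            # advance column k to its next block row
            if slot0 + 1 < Lbp[k + 1]:
                hp[k] = slot0 + 1
                rn = Lbi[slot0 + 1]
                nextc[k] = head[rn]
                head[rn] = k
            k = knext
        # pivot block
        dv = Doff[j]
        for a in range(szj):
            for b in range(szj):
                Dval[dv + a * szj + b] = F[a, b]
                Dtmp[a, b] = F[a, b]
        if not _chol_small(Dtmp, szj):
            return j, 0.0
        for a in range(szj):
            logdet += 2.0 * np.log(Dtmp[a, a])
        _chol_inverse(Dtmp, szj, Itmp)
        for a in range(szj):
            for b in range(szj):
                Dinv[dv + a * szj + b] = Itmp[a, b]
        # L column j = F[szj:H] @ Dinv_j, stored contiguously
        if nblk > 0:
            sub = np.ascontiguousarray(F[szj:H, :szj])
            Dj = Dinv[dv : dv + szj * szj].reshape(szj, szj)
            Lcol = np.dot(sub, Dj)
            v = Vbase[j]
            for a in range(H - szj):
                for b in range(szj):
                    Lval[v + a * szj + b] = Lcol[a, b]
            hp[j] = Lbp[j]
            rn = Lbi[Lbp[j]]
            nextc[j] = head[rn]
            head[rn] = j
    return -1, logdet


# -- triangular solves -------------------------------------------------------

@njit(cache=True, fastmath=True)
def _solve(n_b, bsz, boff, Lbp, Lbi, Lvoff, Lval, Dinv, Doff, Vbase, colh, X):
    """In-place solve of L D L' X = X for block-permuted X (n_s x m)."""
    m = X.shape[1]
    for j in range(n_b):
        szj = bsz[j]
        oj = boff[j]
        if colh[j] == 0:
            continue
        H = colh[j]
        panel = Lval[Vbase[j] : Vbase[j] + H * szj].reshape(H, szj)
        Xj = np.ascontiguousarray(X[oj : oj + szj])
        U = np.dot(panel, Xj)  # (H x m)
        cursor = 0
        for slot in range(Lbp[j], Lbp[j + 1]):
            r = Lbi[slot]
            szr = bsz[r]
            orr = boff[r]
            for a in range(szr):
                for col in range(m):
                    X[orr + a, col] -= U[cursor + a, col]
            cursor += szr
    for j in range(n_b):
        szj = bsz[j]
        oj = boff[j]
        dv = Doff[j]
        Dj = Dinv[dv : dv + szj * szj].reshape(szj, szj)
        Xj = np.ascontiguousarray(X[oj : oj + szj])
        Yj = np.dot(Dj, Xj)
        for a in range(szj):
            for col in range(m):
                X[oj + a, col] = Yj[a, col]
    for j in range(n_b - 1, -1, -1):
        szj = bsz[j]
        oj = boff[j]
        if colh[j] == 0:
            continue
        H = colh[j]
        panel = Lval[Vbase[j] : Vbase[j] + H * szj].reshape(H, szj)
        G = np.empty((H, m))
        cursor = 0
        for slot in range(Lbp[j], Lbp[j + 1]):
            r = Lbi[slot]
            szr = bsz[r]
            orr = boff[r]
            for a in range(szr):
                for col in range(m):
                    G[cursor + a, col] = X[orr + a, col]
            cursor += szr
        U = np.dot(panel.T, G)  # (szj x m)
        for a in range(szj):
            for col in range(m):
                X[oj + a, col] -= U[a, col]


# -- selected inverse --------------------------------------------------------

@njit(cache=True, inline="always")
def _find_slot(Lbp, Lbi, col, row):
    lo = Lbp[col]
    hi = Lbp[col + 1]
    while lo < hi:
        mid = (lo + hi) // 2
        v = Lbi[mid]
        if v == row:
            return mid
        if v < row:
            lo = mid + 1
        else:
            hi = mid
    return -1


@njit(cache=True, fastmath=True)
def _takahashi(
    n_b, bsz, Lbp, Lbi, Lvoff, Lval, Dinv, Doff, Vbase, colh,
    Zval, Zdiag, G, max_sz,
):
    """Selected inverse on the pattern of L, one dense front per column."""
    for j in range(n_b - 1, -1, -1):
        szj = bsz[j]
        dz = Doff[j]
        H = colh[j]
        if H == 0:
            for a in range(szj * szj):
                Zdiag[dz + a] = Dinv[dz + a]
            continue
        start = Lbp[j]
        end = Lbp[j + 1]
        # gather the clique submatrix Z[S_j, S_j] into G (H x H)
        offa = 0
        for ai in range(start, end):
            i = Lbi[ai]
            szi = bsz[i]
            offb = 0
            for bi in range(start, ai + 1):
                k = Lbi[bi]
                szk = bsz[k]
                if k == i:
                    di = Doff[i]
                    for a in range(szi):
                        for b in range(szk):
                            G[offa + a, offb + b] = Zdiag[di + a * szi + b]
                else:
                    slot = _find_slot(Lbp, Lbi, k, i)
                    if slot >= 0:
                        zv = Lvoff[slot]  # Z_ik (szi x szk)
                        for a in range(szi):
                            for b in range(szk):
                                v = Zval[zv + a * szk + b]
                                G[offa + a, offb + b] = v
                                G[offb + b, offa + a] = v
                    else:
                        for a in range(szi):
                            for b in range(szk):
                                G[offa + a, offb + b] = 0.0
                                G[offb + b, offa + a] = 0.0
                offb += szk
            offa += szi
        panel = Lval[Vbase[j] : Vbase[j] + H * szj].reshape(H, szj)
        Zcol = np.dot(np.ascontiguousarray(G[:H, :H]), panel)  # (H x szj)
        zbase = Vbase[j]
        for a in range(H):
            for b in range(szj):
                Zval[zbase + a * szj + b] = -Zcol[a, b]
        # Z_jj = Dinv_j - panel' Zcol_with_sign = Dinv_j + panel' Zcol... sign:
        # Z_kj = -Zcol; Z_jj = Dinv_j - sum L_kj' Z_kj = Dinv_j + panel' Zcol
        for a in range(szj):
            for b in range(szj):
                s = 0.0
                for t in range(H):
                    s += panel[t, a] * Zcol[t, b]
                Zdiag[dz + a * szj + b] = Dinv[dz + a * szj + b] + s
        for a in range(szj):
            for b in range(a):
                v = 0.5 * (Zdiag[dz + a * szj + b] + Zdiag[dz + b * szj + a])
                Zdiag[dz + a * szj + b] = v
                Zdiag[dz + b * szj + a] = v


@njit(cache=True, fastmath=True)
def _trace_product(
    bsz, boff, blk, sperm, Lbp, Lbi, Lvoff, Zval, Zdiag, Doff,
    m_rows, m_cols, m_vals,
):
    total = 0.0
    for t in range(m_rows.size):
        r = sperm[m_rows[t]]
        c = sperm[m_cols[t]]
        if r < c:
            r, c = c, r
        i = blk[r]
        j = blk[c]
        if i == j:
            szj = bsz[j]
            total += m_vals[t] * Zdiag[Doff[j] + (r - boff[j]) * szj + (c - boff[j])]
            continue
        slot = _find_slot(Lbp, Lbi, j, i)
        if slot < 0:
            continue
        szj = bsz[j]
        total += m_vals[t] * Zval[Lvoff[slot] + (r - boff[i]) * szj + (c - boff[j])]
    return total


# -- Python driver -----------------------------------------------------------

class _SymbolicCache:
    """Reusable ordering + symbolic analysis for one sparsity pattern."""

    def __init__(self) -> None:
        self.key = None


def _block_ordering(C: sparse.coo_matrix, blk: np.ndarray, n_b: int) -> np.ndarray:
    """Fill-reducing permutation of the collapsed block graph."""
    bi = blk[C.row]
    bj = blk[C.col]
    pat = sparse.coo_matrix((np.ones(bi.size), (bi, bj)), shape=(n_b, n_b)).tocsc()
    pat.data[:] = -1.0
    pat = pat + sparse.identity(n_b, format="csc") * (n_b + 2.0)
    lu = splu(
        pat,
        permc_spec="MMD_AT_PLUS_A",
        diag_pivot_thresh=0.0,
        options={"SymmetricMode": True},
    )
    # perm_c maps original -> eliminated position; return position -> original
    out = np.empty(n_b, dtype=np.int64)
    out[np.asarray(lu.perm_c)] = np.arange(n_b)
    return out


class SymmetricSparseFactor:
    """Blocked LDL' factorization of an SPD matrix with selected inversion.

    ``block_of`` assigns each scalar equation to a dense block (defaults to
    scalar blocks).  The selected inverse, solves and log-determinant refer
    to the original (unpermuted) matrix.
    """

    def __init__(
        self,
        C: sparse.spmatrix,
        block_of: np.ndarray | None = None,
        cache: _SymbolicCache | None = None,
    ):
        C = C.tocsc()
        self.n = C.shape[0]
        if block_of is None:
            block_of = np.arange(self.n, dtype=np.int64)
        block_of = np.asarray(block_of, dtype=np.int64)
        if block_of.size != self.n:
            raise ValueError("block membership must cover every column")
        cache = cache if cache is not None else _SymbolicCache()
        key = (self.n, C.nnz, int(block_of.max()) + 1)
        if cache.key != key:
            self._analyze(C, block_of, cache)
            cache.key = key
        for name in (
            "bsz", "boff", "blk", "sperm", "spinv", "Lbp", "Lbi", "Lvoff",
            "Vbase", "colh", "Doff", "max_sz", "n_b", "nval", "max_front",
        ):
            setattr(self, name, getattr(cache, name))
        self.cache = cache

        Cp = C[self.spinv][:, self.spinv].tocsc()
        Cp.sort_indices()
        sAp = Cp.indptr.astype(np.int64)
        sAi = Cp.indices.astype(np.int64)
        sAx = Cp.data.astype(np.float64)

        n_b = self.n_b
        self.Lval = np.empty(self.nval, dtype=np.float64)
        dsize = int(self.Doff[-1])
        self.Dval = np.empty(dsize, dtype=np.float64)
        self.Dinv = np.empty(dsize, dtype=np.float64)
        head = np.full(n_b, -1, dtype=np.int64)
        nextc = np.full(n_b, -1, dtype=np.int64)
        hp = np.zeros(n_b, dtype=np.int64)
        pos = np.zeros(n_b, dtype=np.int64)
        F = np.zeros((int(self.max_front), int(self.max_sz)), dtype=np.float64)
        bad, logdet = _numeric_left(
            n_b, self.bsz, self.boff, self.blk,
            sAp, sAi, sAx,
            self.Lbp, self.Lbi, self.Lvoff, self.Vbase, self.colh,
            self.Lval, self.Dval, self.Dinv, self.Doff,
            head, nextc, hp, pos, F, int(self.max_sz),
        )
        if bad >= 0:
            raise np.linalg.LinAlgError(
                f"coefficient matrix is not positive definite (block {bad})"
            )
        self.logdet = float(logdet)
        self._zval = None
        self._zdiag = None

    @staticmethod
    def _analyze(C: sparse.csc_matrix, block_of: np.ndarray, cache) -> None:
        n = C.shape[0]
        blk0 = np.asarray(block_of, dtype=np.int64)
        n_b = int(blk0.max()) + 1
        sizes = np.bincount(blk0, minlength=n_b).astype(np.int64)
        if np.any(sizes == 0):
            raise ValueError("every block id up to the maximum must occur")
        members_order = np.argsort(blk0, kind="stable")
        mem_off = np.zeros(n_b + 1, dtype=np.int64)
        np.cumsum(sizes, out=mem_off[1:])
        coo = C.tocoo()
        bperm = _block_ordering(coo, blk0, n_b)  # position -> original block
        bsz = sizes[bperm]
        boff = np.zeros(n_b + 1, dtype=np.int64)
        np.cumsum(bsz, out=boff[1:])
        blk = np.repeat(np.arange(n_b, dtype=np.int64), bsz)
        spinv = np.concatenate(
            [members_order[mem_off[b] : mem_off[b + 1]] for b in bperm]
        ).astype(np.int64)
        sperm = np.empty(n, dtype=np.int64)
        sperm[spinv] = np.arange(n)
        # block-upper pattern of the permuted matrix
        bposition = np.empty(n_b, dtype=np.int64)
        bposition[bperm] = np.arange(n_b)
        bi = bposition[blk0[coo.row]]
        bj = bposition[blk0[coo.col]]
        lower = bi > bj
        bi[lower], bj[lower] = bj[lower], bi[lower]
        pairs = np.unique(bi * np.int64(n_b) + bj)
        rows = (pairs // n_b).astype(np.int64)
        cols = (pairs % n_b).astype(np.int64)
        Ap = np.zeros(n_b + 1, dtype=np.int64)
        np.add.at(Ap[1:], cols, 1)
        np.cumsum(Ap, out=Ap)
        Ai = rows[np.argsort(cols, kind="stable")]
        parent = np.empty(n_b, dtype=np.int64)
        lnz = np.empty(n_b, dtype=np.int64)
        lvals = np.empty(n_b, dtype=np.int64)
        flag = np.empty(n_b, dtype=np.int64)
        _symbolic_counts(n_b, Ap, Ai, bsz, parent, lnz, lvals, flag)
        Lbp = np.zeros(n_b + 1, dtype=np.int64)
        np.cumsum(lnz, out=Lbp[1:])
        Lbi = np.empty(int(Lbp[-1]), dtype=np.int64)
        fill = np.zeros(n_b, dtype=np.int64)
        _symbolic_pattern(n_b, Ap, Ai, parent, flag, Lbp, Lbi, fill)
        Vbase = np.zeros(n_b, dtype=np.int64)
        np.cumsum((lvals * bsz)[:-1], out=Vbase[1:])
        # value offset of every slot (blocks stacked in pattern order)
        Lvoff = np.empty(int(Lbp[-1]), dtype=np.int64)
        _slot_value_offsets(n_b, Lbp, Lbi, bsz, Vbase, Lvoff)
        Doff = np.zeros(n_b + 1, dtype=np.int64)
        np.cumsum(bsz * bsz, out=Doff[1:])
        cache.bsz = bsz
        cache.boff = boff
        cache.blk = blk
        cache.sperm = sperm
        cache.spinv = spinv
        cache.Lbp = Lbp
        cache.Lbi = Lbi
        cache.Lvoff = Lvoff
        cache.Vbase = Vbase
        cache.colh = lvals
        cache.Doff = Doff
        cache.max_sz = int(bsz.max()) if n_b else 1
        cache.max_front = int((lvals + bsz).max()) if n_b else 1
        cache.n_b = n_b
        cache.nval = int(np.sum(lvals * bsz))

    # -- public operations ------------------------------------------------
    def solve(self, b: np.ndarray) -> np.ndarray:
        one_d = b.ndim == 1
        B = b[:, None] if one_d else b
        Bp = np.ascontiguousarray(B[self.spinv], dtype=np.float64)
        _solve(
            self.n_b, self.bsz, self.boff, self.Lbp, self.Lbi, self.Lvoff,
            self.Lval, self.Dinv, self.Doff, self.Vbase, self.colh, Bp,
        )
        out = np.empty_like(Bp)
        out[self.spinv] = Bp
        return out[:, 0] if one_d else out

    def _ensure_selected(self) -> None:
        if self._zval is not None:
            return
        self._zval = np.zeros_like(self.Lval)
        self._zdiag = np.zeros_like(self.Dinv)
        G = np.zeros((int(self.max_front), int(self.max_front)), dtype=np.float64)
        _takahashi(
            self.n_b, self.bsz, self.Lbp, self.Lbi, self.Lvoff, self.Lval,
            self.Dinv, self.Doff, self.Vbase, self.colh,
            self._zval, self._zdiag, G, int(self.max_sz),
        )

    def trace_inverse_product(self, M: sparse.spmatrix) -> float:
        """tr(C^-1 M) for symmetric M whose pattern lies within C's."""
        self._ensure_selected()
        coo = sparse.coo_matrix(M)
        return float(
            _trace_product(
                self.bsz, self.boff, self.blk, self.sperm,
                self.Lbp, self.Lbi, self.Lvoff, self._zval, self._zdiag,
                self.Doff,
                coo.row.astype(np.int64),
                coo.col.astype(np.int64),
                coo.data.astype(np.float64),
            )
        )
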
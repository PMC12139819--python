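"""Sparse negative-Hessian solvers for the random-effect inner problem.

The joint log-likelihood's negative Hessian over the stacked random
intercepts has the form ``H = A' W A + D`` where ``A`` maps coefficients to
per-observation linear predictors (one indicator per grouping factor and
model part), ``W`` holds per-observation 2x2 (cond x zi) weight blocks and
``D`` the Gaussian-prior precisions.  Two solver paths share one interface:

* ``DenseSolver`` — assembles ``H`` densely; used for small problems and as
  the oracle for the structured path.
* ``TwoLevelSolver`` — eliminates the grouping factor with the most levels
  (typically ``individual``, whose block of ``H`` is 2x2-block-diagonal
  because two distinct individuals never share an observation row) and
  forms a dense Schur complement over the remaining factors.  All
  per-iteration work is vectorized bincounts, small einsums and one
  Cholesky of the Schur complement.

Both expose ``logdet``, ``solve``, per-observation 2x2 blocks of
``A H^-1 A'`` (needed for exact Laplace gradients) and ``diag(H^-1)``.

Coefficient layout (both paths): the "O" block lists part-major
(part, factor, level) coefficients for non-eliminated factors; the "I"
block (structured path only) interleaves parts within each eliminated
level.  :class:`RECoords` owns the layout and the gather/scatter maps.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg as sla


from .errors import DegenerateInputError


class NotPositiveDefinite(Exception):
    """H is not positive definite at the current point (needs damping)."""


class RECoords:
    """Index bookkeeping for stacked random-effect coefficients."""

    def __init__(self, factors, codes, n_levels, n_parts, dense_threshold=400):
        self.factors = tuple(factors)
        self.codes = {f: np.asarray(codes[f], dtype=np.int64) for f in self.factors}
        self.n_levels = {f: int(n_levels[f]) for f in self.factors}
        self.n_parts = int(n_parts)
        self.n = len(next(iter(self.codes.values()))) if self.factors else 0
        total = sum(self.n_levels.values())
        self.dim = self.n_parts * total
        if not self.factors:
            raise DegenerateInputError("need at least one random-effect factor")

        biggest = max(self.factors, key=lambda f: self.n_levels[f])
        use_two_level = self.dim > dense_threshold and len(self.factors) > 1
        self.unit_factor = biggest if use_two_level else None
        self.other_factors = tuple(f for f in self.factors if f != self.unit_factor)

        self.offsets = {}
        m = 0
        for f in self.other_factors:
            self.offsets[f] = m
            m += self.n_levels[f]
        self.m_O = m
        self.P = self.n_parts * m
        self.m_I = self.n_levels[self.unit_factor] if self.unit_factor else 0

        if self.other_factors:
            self.other_col = np.column_stack(
                [self.offsets[f] + self.codes[f] for f in self.other_factors]
            )  # (n, n_of)
        else:
            self.other_col = np.zeros((self.n, 0), dtype=np.int64)
        self.unit_codes = self.codes[self.unit_factor] if self.unit_factor else None

        # per-coefficient (factor index, part) metadata in solver layout
        fidx = {f: i for i, f in enumerate(self.factors)}
        coef_factor, coef_part = [], []
        for a in range(self.n_parts):
            for f in self.other_factors:
                coef_factor += [fidx[f]] * self.n_levels[f]
                coef_part += [a] * self.n_levels[f]
        if self.unit_factor:
            for _ in range(self.m_I):
                for a in range(self.n_parts):
                    coef_factor.append(fidx[self.unit_factor])
                    coef_part.append(a)
        self.coef_factor = np.asarray(coef_factor, dtype=np.int64)
        self.coef_part = np.asarray(coef_part, dtype=np.int64)

    # ---- layout helpers -------------------------------------------------
    def coef_index(self, factor: str, part: int) -> np.ndarray:
        """Solver-layout indices of all levels of (factor, part), in level order."""
        if factor == self.unit_factor:
            return self.P + self.n_parts * np.arange(self.m_I) + part
        off = part * self.m_O + self.offsets[factor]
        return off + np.arange(self.n_levels[factor])

    def row_coef_indices(self, part: int):
        """Per-row coefficient indices: list of (n,) arrays, one per factor."""
        out = [part * self.m_O + self.other_col[:, j] for j in range(len(self.other_factors))]
        if self.unit_factor is not None:
            out.append(self.P + self.n_parts * self.unit_codes + part)
        return out

    def gather_rows(self, x: np.ndarray) -> np.ndarray:
        """A x: per-row, per-part sums of coefficients (n, n_parts)."""
        out = np.zeros((self.n, self.n_parts))
        for a in range(self.n_parts):
            for idx in self.row_coef_indices(a):
                out[:, a] += x[idx]
        return out

    def scatter_rows(self, vals: np.ndarray) -> np.ndarray:
        """A' vals for per-row per-part values (n, n_parts) -> (dim,)."""
        out = np.zeros(self.dim)
        for a in range(self.n_parts):
            for idx in self.row_coef_indices(a):
                np.add.at(out, idx, vals[:, a])
        return out


def _part_pairs(n_parts):
    return [(a, b) for a in range(n_parts) for b in range(a, n_parts)]


class DenseSolver:
    """Reference solver: assemble H densely and use LAPACK Cholesky."""

    def __init__(self, coords: RECoords):
        self.c = coords

    def update(self, W: np.ndarray, prec: np.ndarray):
        """W: (n, n_parts, n_parts) row weight blocks; prec[f_idx, part] = 1/sd^2."""
        c = self.c
        H = np.zeros((c.dim, c.dim))
        rows_by_part = [c.row_coef_indices(a) for a in range(c.n_parts)]
        for a in range(c.n_parts):
            for b in range(c.n_parts):
                w = W[:, a, b]
                for ia in rows_by_part[a]:
                    for ib in rows_by_part[b]:
                        np.add.at(H, (ia, ib), w)
        H[np.arange(c.dim), np.arange(c.dim)] += prec[c.coef_factor, c.coef_part]
        try:
            self._chol = sla.cholesky(H, lower=True)
        except sla.LinAlgError as e:
            raise NotPositiveDefinite(str(e)) from e
        self._H = H

    def logdet(self) -> float:
        return 2.0 * float(np.sum(np.log(np.diag(self._chol))))

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        return sla.cho_solve((self._chol, True), rhs)

    def _inv(self) -> np.ndarray:
        return sla.cho_solve((self._chol, True), np.eye(self.c.dim))

    def row_hat_blocks(self) -> np.ndarray:
        """Per-row 2x2 blocks of A H^-1 A' (n, n_parts, n_parts)."""
        c = self.c
        Hinv = self._inv()
        out = np.zeros((c.n, c.n_parts, c.n_parts))
        for a in range(c.n_parts):
            ia_list = c.row_coef_indices(a)
            for b in range(c.n_parts):
                ib_list = c.row_coef_indices(b)
                for ia in ia_list:
                    for ib in ib_list:
                        out[:, a, b] += Hinv[ia, ib]
        return out

    def diag_inv(self) -> np.ndarray:
        return np.diag(self._inv()).copy()


class TwoLevelSolver:
    """Schur-complement solver eliminating the largest grouping factor.

    The coupling block between the eliminated ("unit") factor and the
    remaining coefficients is held in a padded per-unit-level slot layout:
    every observation row of unit level k occupies ``n_of`` consecutive
    slots (one per other factor).  Duplicate columns across a level's rows
    simply split the coefficient weight over slots — every use of the block
    is bilinear, so the sums are unchanged.  This keeps all per-iteration
    work in bincounts, einsums and one dense Cholesky.
    """

    def __init__(self, coords: RECoords):
        c = coords
        assert c.unit_factor is not None
        self.c = c
        n_of = len(c.other_factors)
        m_O = c.m_O
        # flat indices for H_OO assembly: all ordered other-factor pairs
        pair_idx = []
        for i in range(n_of):
            for j in range(n_of):
                pair_idx.append(c.other_col[:, i] * m_O + c.other_col[:, j])
        self._oo_idx = np.concatenate(pair_idx) if pair_idx else np.zeros(0, np.int64)
        self._n_of = n_of

        # padded slot layout for the unit/other coupling block
        rows_per_unit = np.bincount(c.unit_codes, minlength=c.m_I)
        self._J = int(rows_per_unit.max()) * n_of if n_of else 0
        J = self._J
        if n_of:
            order = np.argsort(c.unit_codes, kind="stable")
            rank = np.empty(c.n, dtype=np.int64)
            # rank of each row within its unit level
            seen = np.zeros(c.m_I, dtype=np.int64)
            for pos in order:
                k = c.unit_codes[pos]
                rank[pos] = seen[k]
                seen[k] += 1
            # slot index of (row, factor) inside its unit level
            self._slot_flat = (
                (c.unit_codes[:, None] * J)
                + (rank[:, None] * n_of)
                + np.arange(n_of)[None, :]
            ).ravel(order="F")  # column-major: matches np.tile(w, n_of)
            cols = np.zeros((c.m_I, J), dtype=np.int64)
            np.put(cols, self._slot_flat, c.other_col.ravel(order="F"))
            self._cols = cols
            self._pair_flat = (cols[:, :, None] * m_O + cols[:, None, :]).reshape(-1)
        self._selected = None

    def update(self, W: np.ndarray, prec: np.ndarray):
        c = self.c
        np_, m_O, m_I, P = c.n_parts, c.m_O, c.m_I, c.P
        fidx = {f: i for i, f in enumerate(c.factors)}
        n_of = self._n_of
        J = self._J

        # H_II: per-unit-level part x part blocks + prior precision
        HII = np.zeros((m_I, np_, np_))
        for a in range(np_):
            for b in range(a, np_):
                s = np.bincount(c.unit_codes, weights=W[:, a, b], minlength=m_I)
                HII[:, a, b] = s
                if b != a:
                    HII[:, b, a] = s
        for a in range(np_):
            HII[:, a, a] += prec[fidx[c.unit_factor], a]

        # block inverse of H_II (1x1 or 2x2)
        if np_ == 1:
            if np.any(HII[:, 0, 0] <= 0):
                raise NotPositiveDefinite("unit-factor block not PD")
            Pinv = 1.0 / HII
            self._logdet_II = float(np.sum(np.log(HII[:, 0, 0])))
        else:
            a_, b_, d_ = HII[:, 0, 0], HII[:, 0, 1], HII[:, 1, 1]
            det = a_ * d_ - b_ * b_
            if np.any(a_ <= 0) or np.any(det <= 0):
                raise NotPositiveDefinite("unit-factor block not PD")
            Pinv = np.empty_like(HII)
            Pinv[:, 0, 0] = d_ / det
            Pinv[:, 1, 1] = a_ / det
            Pinv[:, 0, 1] = Pinv[:, 1, 0] = -b_ / det
            self._logdet_II = float(np.sum(np.log(det)))
        self._Pinv = Pinv

        # padded V_{ab}[k, slot]: unit/other coupling values per part pair
        V = np.zeros((np_, np_, m_I, J))
        if n_of:
            for a in range(np_):
                for b in range(a, np_):
                    v = np.bincount(
                        self._slot_flat,
                        weights=np.tile(W[:, a, b], n_of),
                        minlength=m_I * J,
                    ).reshape(m_I, J)
                    V[a, b] = v
                    if b != a:
                        V[b, a] = v
        self._V = V

        # H_OO dense
        S = np.zeros((P, P))
        for a in range(np_):
            for b in range(a, np_):
                if n_of:
                    K = np.bincount(
                        self._oo_idx, weights=np.tile(W[:, a, b], n_of * n_of), minlength=m_O * m_O
                    ).reshape(m_O, m_O)
                else:
                    K = np.zeros((m_O, m_O))
                S[a * m_O : (a + 1) * m_O, b * m_O : (b + 1) * m_O] += K
                if b != a:
                    S[b * m_O : (b + 1) * m_O, a * m_O : (a + 1) * m_O] += K.T
        dpre = np.empty(P)
        for a in range(np_):
            for f in c.other_factors:
                off = a * m_O + c.offsets[f]
                dpre[off : off + c.n_levels[f]] = prec[fidx[f], a]
        S[np.arange(P), np.arange(P)] += dpre

        # Schur correction: C_ab[o,o'] = sum_k sum_{a'b'} Pinv[k,a',b']
        #                                V_{a'a}[k,j@o] V_{b'b}[k,m@o']
        if n_of:
            for a in range(np_):
                for b in range(a, np_):
                    W2 = np.einsum("kAB,Akj,Bkm->kjm", Pinv, V[:, a], V[:, b])
                    Cab = np.bincount(
                        self._pair_flat, weights=W2.reshape(-1), minlength=m_O * m_O
                    ).reshape(m_O, m_O)
                    S[a * m_O : (a + 1) * m_O, b * m_O : (b + 1) * m_O] -= Cab
                    if b != a:
                        S[b * m_O : (b + 1) * m_O, a * m_O : (a + 1) * m_O] -= Cab.T
        try:
            self._cholS = sla.cholesky(S, lower=True)
        except sla.LinAlgError as e:
            raise NotPositiveDefinite(str(e)) from e
        self._selected = None

    def logdet(self) -> float:
        return self._logdet_II + 2.0 * float(np.sum(np.log(np.diag(self._cholS))))

    def _apply_Pinv(self, rI: np.ndarray) -> np.ndarray:
        return np.einsum("kab,kb->ka", self._Pinv, rI)

    def _M_T(self, tI: np.ndarray) -> np.ndarray:
        """M' t for t (m_I, n_parts) -> (P,)."""
        c = self.c
        out = np.zeros(c.P)
        if not self._n_of:
            return out
        for b in range(c.n_parts):
            # weights[k,j] = sum_a V_ab[k,j] t[k,a]
            wts = np.einsum("akj,ka->kj", self._V[:, b], tI)
            out[b * c.m_O : (b + 1) * c.m_O] = np.bincount(
                self._cols.reshape(-1), weights=wts.reshape(-1), minlength=c.m_O
            )
        return out

    def _M(self, xO: np.ndarray) -> np.ndarray:
        """M x for x (P,) -> (m_I, n_parts)."""
        c = self.c
        out = np.zeros((c.m_I, c.n_parts))
        if not self._n_of:
            return out
        for b in range(c.n_parts):
            xg = xO[b * c.m_O : (b + 1) * c.m_O][self._cols]  # (m_I, J)
            out += np.einsum("akj,kj->ka", self._V[:, b], xg)
        return out

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        c = self.c
        rO = rhs[: c.P]
        rI = rhs[c.P :].reshape(c.m_I, c.n_parts)
        t = self._apply_Pinv(rI)
        xO = sla.cho_solve((self._cholS, True), rO - self._M_T(t))
        xI = self._apply_Pinv(rI - self._M(xO))
        return np.concatenate([xO, xI.ravel()])

    # ---- selected inverse ----------------------------------------------
    def _selected_inverse(self):
        if self._selected is not None:
            return self._selected
        c = self.c
        np_, P, m_I, m_O = c.n_parts, c.P, c.m_I, c.m_O
        Sinv = sla.cho_solve((self._cholS, True), np.eye(P))
        # U[k,a,j,b] = sum_A Pinv[k,a,A] V_{Ab}[k,j]
        U = np.einsum("kaA,Abkj->kajb", self._Pinv, self._V)
        # Wd[a][k,p] = sum_{j,b} U[k,a,j,b] Sinv[b*m_O + cols[k,j], p]
        Wd = np.zeros((np_, m_I, P))
        for b in range(np_):
            SR = Sinv[self._cols + b * m_O] if self._n_of else np.zeros((m_I, 0, P))
            # batched (a x j) @ (j x p) per unit level, BLAS-backed
            Wd += np.matmul(np.ascontiguousarray(U[:, :, :, b]), SR).transpose(1, 0, 2)
        # H^-1 II blocks: Pinv + (U S^-1 U')_kk
        WG = np.zeros((m_I, np_, self._J, np_))
        for b in range(np_):
            for a in range(np_):
                WG[:, a, :, b] = np.take_along_axis(
                    Wd[a], self._cols + b * m_O, axis=1
                ) if self._n_of else 0.0
        HinvII = self._Pinv + np.einsum("kajb,kAjb->kaA", WG, U)
        HinvII = 0.5 * (HinvII + HinvII.transpose(0, 2, 1))
        self._selected = (Sinv, Wd, HinvII)
        return self._selected

    def row_hat_blocks(self) -> np.ndarray:
        c = self.c
        Sinv, Wd, HinvII = self._selected_inverse()
        np_, m_O = c.n_parts, c.m_O
        n = c.n
        out = np.zeros((n, np_, np_))
        k = c.unit_codes
        oc = c.other_col  # (n, n_of)
        for a in range(np_):
            for b in range(a, np_):
                val = HinvII[k, a, b]
                if oc.shape[1]:
                    ca = oc + a * m_O
                    cb = oc + b * m_O
                    val = val + Sinv[ca[:, :, None], cb[:, None, :]].sum(axis=(1, 2))
                    # cross terms H^-1_IO = -Wd
                    val = val - np.take_along_axis(Wd[a][k], cb, axis=1).sum(axis=1)
                    val = val - np.take_along_axis(Wd[b][k], ca, axis=1).sum(axis=1)
                out[:, a, b] = val
                if b != a:
                    out[:, b, a] = val
        return out

    def diag_inv(self) -> np.ndarray:
        c = self.c
        Sinv, _, HinvII = self._selected_inverse()
        out = np.empty(c.dim)
        out[: c.P] = np.diag(Sinv)
        blk = out[c.P :].reshape(c.m_I, c.n_parts)
        for a in range(c.n_parts):
            blk[:, a] = HinvII[:, a, a]
        return out


def make_solver(coords: RECoords):
    return DenseSolver(coords) if coords.unit_factor is None else TwoLevelSolver(coords)
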
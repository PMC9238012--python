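"""Pedigree and genomic relationship matrices for single-step evaluation.

Covers the numerator relationship matrix A (inbreeding, sparse inverse by
Henderson's rules, the genotyped-animal block A22), the raw VanRaden
genomic matrix G_r, its inbreeding adjustment G_t compatible with A22
under selective genotyping, the blended invertible G, and the inverse of
the combined pedigree-genomic matrix

    H^-1 = A^-1 + [0 0; 0 (w*G_t + (1-w)*A22)^-1 - A22^-1]

with default blending weight w = 0.95.  Unknown-parent groups can be
carried as extra columns of A^-1 (Westell/Quaas-Pollak construction), in
which case animal solutions of the mixed-model equations are total
breeding values including the group means.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .pedigree import Pedigree


@dataclass
class RelMatrix:
    """A relationship matrix (dense or sparse) with its row/column ids.

    ``kind`` is one of ``A, A_inv, A22, A22_inv, G_r, G_t, G_blend, H_inv``.
    For ``A_inv``/``H_inv`` built with unknown-parent groups the trailing
    ids are the group labels.
    """

    ids: np.ndarray
    values: object  # ndarray or scipy sparse
    kind: str

    def dense(self) -> np.ndarray:
        v = self.values
        return v.toarray() if sp.issparse(v) else np.asarray(v)


def mendelian_variances(ped: Pedigree, F: np.ndarray) -> np.ndarray:
    """Variance of the Mendelian-sampling term of each animal.

    0.5 - 0.25(F_s + F_d) with both parents known, 0.75 - 0.25 F_p with
    one known parent, 1 for base animals.
    """
    s, d = ped.sire_idx, ped.dam_idx
    out = np.ones(ped.n)
    both = (s >= 0) & (d >= 0)
    out[both] = 0.5 - 0.25 * (F[s[both]] + F[d[both]])
    one_s = (s >= 0) & (d < 0)
    out[one_s] = 0.75 - 0.25 * F[s[one_s]]
    one_d = (s < 0) & (d >= 0)
    out[one_d] = 0.75 - 0.25 * F[d[one_d]]
    return out


def compute_inbreeding(ped: Pedigree) -> np.ndarray:
    """Pedigree inbreeding coefficients by Meuwissen & Luo's algorithm.

    For each animal the diagonal of A is accumulated from the Mendelian
    variances of its ancestors, A_ii = sum_j L_j^2 d_j, where L_j is the
    expected genetic contribution of ancestor j, so the cost is
    O(n * ancestors) without forming A.
    """
    n = ped.n
    s, d = ped.sire_idx, ped.dam_idx
    F = np.zeros(n)
    dvec = np.ones(n)  # filled progressively; d_j only needs F of parents of j
    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            dvec[i] = 0.5 - 0.25 * (F[si] + F[di])
        elif si >= 0:
            dvec[i] = 0.75 - 0.25 * F[si]
        elif di >= 0:
            dvec[i] = 0.75 - 0.25 * F[di]
        if si < 0 or di < 0:
            F[i] = 0.0  # base or half-founder animals are non-inbred
            continue
        coeff = {i: 1.0}
        heap = [-i]
        aii = 0.0
        while heap:
            k = -heapq.heappop(heap)
            ck = coeff.pop(k, 0.0)
            if ck == 0.0:
                continue
            aii += ck * ck * dvec[k]
            for p in (s[k], d[k]):
                if p >= 0:
                    if p not in coeff:
                        heapq.heappush(heap, -p)
                        coeff[p] = 0.0
                    coeff[p] += 0.5 * ck
        F[i] = aii - 1.0
    return F


def tabular_A(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method."""
    n = ped.n
    s, d = ped.sire_idx, ped.dam_idx
    A = np.zeros((n, n))
    for i in range(n):
        row = np.zeros(n)
        if s[i] >= 0:
            row += 0.5 * A[s[i]]
        if d[i] >= 0:
            row += 0.5 * A[d[i]]
        A[i, :i] = row[:i]
        A[:i, i] = row[:i]
        A[i, i] = 1.0 + (0.5 * A[s[i], d[i]] if s[i] >= 0 and d[i] >= 0 else 0.0)
    return A


def a_matvec(ped: Pedigree, X: np.ndarray, F: np.ndarray | None = None) -> np.ndarray:
    """Product A @ X without forming A (Colleau's indirect method).

    Uses A = T D T' with T the gene-flow operator: a backward sweep for
    T'X, a diagonal scaling by the Mendelian variances, and a forward
    sweep for T(.).  X may be a vector or an (n, m) matrix.
    """
    if F is None:
        F = compute_inbreeding(ped)
    dvec = mendelian_variances(ped, F)
    s, d = ped.sire_idx, ped.dam_idx
    X = np.asarray(X, dtype=float)
    squeeze = X.ndim == 1
    W = X.reshape(ped.n, -1).copy()
    for k in range(ped.n - 1, -1, -1):
        if s[k] >= 0:
            W[s[k]] += 0.5 * W[k]
        if d[k] >= 0:
            W[d[k]] += 0.5 * W[k]
    W *= dvec[:, None]
    for k in range(ped.n):
        acc = W[k]
        if s[k] >= 0:
            acc = acc + 0.5 * W[s[k]]
        if d[k] >= 0:
            acc = acc + 0.5 * W[d[k]]
        W[k] = acc
    return W[:, 0] if squeeze else W


def build_A22(
    ped: Pedigree, genotyped_ids, F: np.ndarray | None = None, with_inverse: bool = True
) -> tuple[RelMatrix, RelMatrix | None]:
    """Pedigree relationships among genotyped animals (and the inverse).

    This is the genotyped-row/column submatrix of the full tabular A —
    not A of a pruned pedigree — obtained by pushing unit vectors for
    the genotyped animals through the indirect A-product.
    """
    pos = ped.index_of(genotyped_ids)
    E = np.zeros((ped.n, len(pos)))
    E[pos, np.arange(len(pos))] = 1.0
    A22 = a_matvec(ped, E, F=F)[pos]
    A22 = 0.5 * (A22 + A22.T)
    ids = np.asarray(genotyped_ids)
    m = RelMatrix(ids, A22, "A22")
    if not with_inverse:
        return m, None
    try:
        inv = np.linalg.inv(A22)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(f"A22 is singular: {err}") from err
    return m, RelMatrix(ids, 0.5 * (inv + inv.T), "A22_inv")


def build_A_inverse(
    ped: Pedigree, F: np.ndarray | None = None, groups: bool = False
) -> RelMatrix:
    """Sparse A^-1 by Henderson's rules with inbreeding-adjusted
    Mendelian variances.

    With ``groups=True`` unknown parents are replaced by their
    unknown-parent-group columns, appended after the animals, giving the
    Quaas-Pollak transformed structure used to fit genetic groups.
    """
    if F is None:
        F = compute_inbreeding(ped)
    dvec = mendelian_variances(ped, F)
    n, g = ped.n, ped.n_groups
    dim = n + g if groups else n
    rows, cols, vals = [], [], []
    s, d, gi = ped.sire_idx, ped.dam_idx, ped.group_idx
    for i in range(n):
        alpha = 1.0 / dvec[i]
        parents = []
        for p in (s[i], d[i]):
            if p >= 0:
                parents.append(p)
            elif groups:
                parents.append(n + gi[i])
        rows.append(i); cols.append(i); vals.append(alpha)
        for p in parents:
            rows += [i, p]; cols += [p, i]; vals += [-0.5 * alpha] * 2
        for p in parents:
            for q in parents:
                rows.append(p); cols.append(q); vals.append(0.25 * alpha)
    Ainv = sp.csr_array((vals, (rows, cols)), shape=(dim, dim))
    ids = np.concatenate([ped.ids, np.asarray(ped.groups, dtype=object)]) if groups else ped.ids
    return RelMatrix(ids, Ainv, "A_inv")


def group_fractions(ped: Pedigree) -> np.ndarray:
    """Expected fraction of each animal's genome tracing to each
    unknown-parent group (the Q matrix of the group-covariate model)."""
    n, g = ped.n, ped.n_groups
    Q = np.zeros((n, g))
    for i in range(n):
        for p, w in ((ped.sire_idx[i], 0.5), (ped.dam_idx[i], 0.5)):
            if p >= 0:
                Q[i] += w * Q[p]
            else:
                Q[i, ped.group_idx[i]] += w
    return Q


# -- genomic matrices --------------------------------------------------


def build_Gr(calls: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Raw genomic relationship matrix, VanRaden's first method.

    ``calls`` is animals x SNPs allele counts with NaN for missing;
    missing calls are imputed at the population mean 2p before
    centering.  G_r = M M' / (2 * sum_j p_j (1 - p_j)).
    """
    p = np.asarray(freqs, dtype=float)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic: zero VanRaden denominator")
    M = np.asarray(calls, dtype=float)
    M = np.where(np.isnan(M), 2.0 * p, M) - 2.0 * p
    return (M @ M.T) / denom


def adjust_Gt(Gr: np.ndarray, f_bar_p: float) -> np.ndarray:
    """Rescale G_r to the A22 base: G_t = (1 - fbar_p) G_r + 2 fbar_p 11'.

    ``f_bar_p`` is the mean pedigree inbreeding coefficient of the
    genotyped animals; the affine map compensates for allele
    frequencies estimated from selectively genotyped animals.
    """
    if not 0.0 <= f_bar_p < 1.0:
        raise ValueError("f_bar_p must be in [0, 1)")
    return (1.0 - f_bar_p) * Gr + 2.0 * f_bar_p


def blend(Gt: np.ndarray, A22: np.ndarray, w: float = 0.95) -> np.ndarray:
    """Weighted blend w*G_t + (1-w)*A22 guaranteeing invertibility."""
    if Gt.shape != A22.shape:
        raise ValueError("G_t and A22 dimensions differ")
    return w * Gt + (1.0 - w) * A22


def build_H_inverse(
    A_inv: RelMatrix,
    genotyped_positions: np.ndarray,
    G_blend: np.ndarray,
    A22_inv: np.ndarray,
) -> RelMatrix:
    """H^-1 as sparse A^-1 plus the dense genotyped-block correction."""
    corr = np.linalg.inv(G_blend) - A22_inv
    corr = 0.5 * (corr + corr.T)
    pos = np.asarray(genotyped_positions, dtype=np.int64)
    dim = A_inv.values.shape[0]
    rows = np.repeat(pos, len(pos))
    cols = np.tile(pos, len(pos))
    C = sp.csr_array((corr.ravel(), (rows, cols)), shape=(dim, dim))
    return RelMatrix(A_inv.ids, (A_inv.values + C).tocsr(), "H_inv")


def write_triplets(m: RelMatrix, path) -> None:
    """Write a relationship matrix as an id-id-value TSV (upper triangle)."""
    v = m.values.tocoo() if sp.issparse(m.values) else sp.coo_array(np.asarray(m.values))
    keep = v.row <= v.col
    pd.DataFrame(
        {"id_i": m.ids[v.row[keep]], "id_j": m.ids[v.col[keep]], "value": v.data[keep]}
    ).to_csv(path, sep="\t", index=False)
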
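"""Relationship matrices for single-step evaluation.

Builds the pedigree numerator relationship matrix A (tabular method), its
sparse inverse (Henderson's rules with Meuwissen-Luo inbreeding), the
genotyped block A22, the VanRaden method-1 genomic relationship matrix G,
its blended/tuned version, and the single-step inverse

    H^-1 = A^-1 + [0, 0; 0, G_adj^-1 - A22^-1]

with the genomic correction added into the genotyped block.

Tuning rescales G so that its mean diagonal and mean off-diagonal match
those of A22 (aligning the genomic and pedigree base populations); blending
``(1 - alpha) G + alpha A22`` with a small alpha guarantees invertibility.
The BLUPF90-family convention of tuning first and blending second is the
default; the order is switchable because the two differ numerically.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve

from .data import GenotypePanel, Pedigree

TABULAR_LIMIT = 20_000  # dense-A guard; this package is desk-scale by design


# ---------------------------------------------------------------------------
# Pedigree matrices
# ---------------------------------------------------------------------------


def inbreeding_coefficients(pedigree: Pedigree) -> np.ndarray:
    """Per-animal inbreeding F by the Meuwissen-Luo algorithm.

    Walks each animal's ancestor list accumulating L coefficients so that
    ``a_ii = sum_j L_ij^2 d_j`` and ``F_i = a_ii - 1``, where ``d_j`` is the
    Mendelian sampling variance of ancestor j (unknown parents enter with the
    F = -1 convention).
    """
    sire, dam = pedigree.sire_idx, pedigree.dam_idx
    n = len(pedigree)
    F = np.zeros(n)
    D = np.zeros(n)

    def f_of(j: int) -> float:
        return -1.0 if j < 0 else F[j]

    for i in range(n):
        D[i] = 0.5 - 0.25 * (f_of(sire[i]) + f_of(dam[i]))
        if sire[i] < 0 or dam[i] < 0:
            F[i] = 0.0
            continue
        # accumulate L over ancestors, youngest first (max-heap on index)
        L: dict[int, float] = {i: 1.0}
        heap = [-i]
        a_ii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            lj = L.pop(j, 0.0)
            if lj == 0.0:
                continue
            a_ii += lj * lj * D[j]
            for p in (sire[j], dam[j]):
                if p >= 0:
                    if p not in L:
                        heapq.heappush(heap, -p)
                        L[p] = 0.0
                    L[p] += 0.5 * lj
        F[i] = a_ii - 1.0
    return F


def build_A_inverse(pedigree: Pedigree) -> sp.csr_matrix:
    """Sparse A^-1 by Henderson's rules with inbreeding.

    Nonzeros appear only among {animal, sire, dam} triples; the Mendelian
    sampling variance d_i uses the parents' Meuwissen-Luo inbreeding
    coefficients.
    """
    F = inbreeding_coefficients(pedigree)
    sire, dam = pedigree.sire_idx, pedigree.dam_idx
    n = len(pedigree)
    rows, cols, vals = [], [], []

    def add(r: int, c: int, v: float) -> None:
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        fs = -1.0 if sire[i] < 0 else F[sire[i]]
        fd = -1.0 if dam[i] < 0 else F[dam[i]]
        alpha = 1.0 / (0.5 - 0.25 * (fs + fd))
        add(i, i, alpha)
        parents = [p for p in (sire[i], dam[i]) if p >= 0]
        for p in parents:
            add(i, p, -alpha / 2.0)
            add(p, i, -alpha / 2.0)
        for p in parents:
            for q in parents:
                add(p, q, alpha / 4.0)
    A_inv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    A_inv.sum_duplicates()
    return A_inv


def tabular_A(pedigree: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method."""
    n = len(pedigree)
    if n > TABULAR_LIMIT:
        raise ValueError(
            f"pedigree has {n} animals; dense tabular A is guarded at "
            f"{TABULAR_LIMIT} (this package targets desk-scale problems)"
        )
    sire, dam = pedigree.sire_idx, pedigree.dam_idx
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        a_sd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
    return A


def build_A22(pedigree: Pedigree, genotyped_ids) -> np.ndarray:
    """Genotyped-by-genotyped block of tabular A (desk scale)."""
    idx = pedigree.indices(genotyped_ids)  # raises on missing animals
    A = tabular_A(pedigree)
    return A[np.ix_(idx, idx)]


# ---------------------------------------------------------------------------
# Genomic matrices
# ---------------------------------------------------------------------------


def build_G(
    panel: GenotypePanel, freq: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """VanRaden method-1 genomic relationship matrix.

    ``G = Z Z' q`` with ``Z = dosages - 2p`` and the weighting factor
    ``q = 1 / (2 sum_o p_o (1 - p_o))``. Frequencies default to the observed
    ones in the panel; pass ``freq`` to center with supplied (e.g. base
    population) frequencies.
    """
    p = panel.allele_freq if freq is None else np.asarray(freq, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("allele frequencies of 0 or 1 make G undefined; filter first")
    Z = panel.centered_matrix(p)
    q = 1.0 / (2.0 * np.sum(p * (1.0 - p)))
    G = (Z @ Z.T) * q
    return G, q


def tune_G(G_raw: np.ndarray, A22: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Rescale G so mean(diag) and mean(offdiag) equal those of A22.

    Solves the 2x2 linear system for (a, b) in ``a + b * G``.
    """
    n = G_raw.shape[0]
    diag_mask = np.eye(n, dtype=bool)
    mg_d, mg_o = G_raw[diag_mask].mean(), G_raw[~diag_mask].mean() if n > 1 else 0.0
    ma_d = A22[diag_mask].mean()
    ma_o = A22[~diag_mask].mean() if n > 1 else 0.0
    M = np.array([[1.0, mg_d], [1.0, mg_o]])
    if abs(np.linalg.det(M)) < 1e-12 * max(1.0, abs(mg_d)):
        raise ValueError("tuning system singular: G has equal mean diag/offdiag")
    a, b = np.linalg.solve(M, np.array([ma_d, ma_o]))
    return a + b * G_raw, (float(a), float(b))


def blend_and_tune_G(
    G_raw: np.ndarray,
    A22: np.ndarray,
    alpha: float = 0.05,
    tune: bool = True,
    order: str = "tune_then_blend",
) -> np.ndarray:
    """Blend ``(1 - alpha) G + alpha A22`` with optional mean tuning.

    ``order`` selects whether tuning happens before or after blending
    (default tune-then-blend, the BLUPF90-family convention).
    """
    if G_raw.shape != A22.shape:
        raise ValueError("G and A22 shapes differ")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if order not in ("tune_then_blend", "blend_then_tune"):
        raise ValueError(f"unknown order {order!r}")
    G = np.asarray(G_raw, dtype=float)
    if tune and order == "tune_then_blend":
        G, _ = tune_G(G, A22)
    G = (1.0 - alpha) * G + alpha * A22
    if tune and order == "blend_then_tune":
        G, _ = tune_G(G, A22)
    return G


def _chol_inverse(mat: np.ndarray, name: str) -> np.ndarray:
    try:
        c = cho_factor(mat)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{name} is not positive definite: {exc}") from exc
    return cho_solve(c, np.eye(mat.shape[0]))


def build_H_inverse(
    A_inv: sp.spmatrix,
    G_adj_inv: np.ndarray,
    A22_inv: np.ndarray,
    genotyped_index: np.ndarray,
) -> sp.csr_matrix:
    """H^-1 = A^-1 with (G_adj^-1 - A22^-1) added into the genotyped block."""
    n_g = len(genotyped_index)
    if G_adj_inv.shape != (n_g, n_g) or A22_inv.shape != (n_g, n_g):
        raise ValueError("genotyped index does not match genomic matrix dimensions")
    H_inv = sp.lil_matrix(A_inv.copy())
    delta = G_adj_inv - A22_inv
    ix = np.asarray(genotyped_index, dtype=np.int64)
    H_inv[np.ix_(ix, ix)] = H_inv[np.ix_(ix, ix)].toarray() + delta
    return H_inv.tocsr()


# ---------------------------------------------------------------------------
# Aggregate
# ---------------------------------------------------------------------------


@dataclass
class RelationshipSet:
    """All relationship matrices needed by the single-step pipeline."""

    A_inv: sp.csr_matrix
    A22: np.ndarray
    G_raw: np.ndarray
    G_adj: np.ndarray
    G_adj_inv: np.ndarray
    A22_inv: np.ndarray
    H_inv: sp.csr_matrix
    q: float
    alpha: float
    genotyped_ids: np.ndarray
    genotyped_index: np.ndarray  # pedigree positions of genotyped animals
    centering_freq: np.ndarray

    @classmethod
    def from_data(
        cls,
        pedigree: Pedigree,
        panel: GenotypePanel,
        alpha: float = 0.05,
        tune: bool = True,
        tune_order: str = "tune_then_blend",
        centering: str = "observed",
    ) -> "RelationshipSet":
        """Build every matrix from a pedigree and a filtered genotype panel.

        ``centering`` chooses the allele frequencies for VanRaden centering:
        "observed" (panel frequencies, the default reading) or "supplied"
        (``panel.founder_freq``, e.g. base-population frequencies).
        """
        if centering == "observed":
            freq = panel.allele_freq
        elif centering == "supplied":
            if panel.founder_freq is None:
                raise ValueError("centering='supplied' needs panel.founder_freq")
            freq = panel.founder_freq
        else:
            raise ValueError(f"unknown centering {centering!r}")

        A_inv = build_A_inverse(pedigree)
        A22 = build_A22(pedigree, panel.animal_ids)
        G_raw, q = build_G(panel, freq=freq)
        G_adj = blend_and_tune_G(G_raw, A22, alpha=alpha, tune=tune, order=tune_order)
        G_adj_inv = _chol_inverse(G_adj, "blended G")
        A22_inv = _chol_inverse(A22, "A22")
        gen_index = pedigree.indices(panel.animal_ids)
        H_inv = build_H_inverse(A_inv, G_adj_inv, A22_inv, gen_index)
        return cls(
            A_inv=A_inv,
            A22=A22,
            G_raw=G_raw,
            G_adj=G_adj,
            G_adj_inv=G_adj_inv,
            A22_inv=A22_inv,
            H_inv=H_inv,
            q=q,
            alpha=alpha,
            genotyped_ids=np.asarray(panel.animal_ids),
            genotyped_index=gen_index,
            centering_freq=np.asarray(freq, dtype=float),
        )

    def dump_matrixmarket(self, directory) -> None:
        """Debug dump of the sparse matrices in MatrixMarket format."""
        from pathlib import Path

        from scipy.io import mmwrite

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        mmwrite(directory / "A_inv.mtx", sp.coo_matrix(self.A_inv))
        mmwrite(directory / "H_inv.mtx", sp.coo_matrix(self.H_inv))
        mmwrite(directory / "G_adj.mtx", sp.coo_matrix(self.G_adj))
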
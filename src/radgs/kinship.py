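"""Pedigree and marker-based relationship matrices.

The numerator relationship matrix A follows the tabular method; the
genomic relationship matrix G follows the common allele-frequency-centered
cross-product construction G = X_c X_c' / k with k = sum_j 2 p_j (1 - p_j),
so that diag(G) averages ~1 in an unrelated Hardy-Weinberg population and
ridge-regression shrinkage matches G-BLUP exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import ValidationError


def numerator_relationship_matrix(pedigree: pd.DataFrame) -> np.ndarray:
    """Tabular-method A matrix.

    ``pedigree`` needs columns id, sire, dam; unknown parents coded -1 (or
    NaN).  Parents must precede their offspring.  A_ii = 1 + F_i and
    A_ij = 0.5 (A_i,sire(j) + A_i,dam(j)).
    """
    ids = pedigree["id"].to_numpy()
    if len(set(ids.tolist())) != len(ids):
        raise ValidationError("pedigree ids must be unique")
    index = {int(v): i for i, v in enumerate(ids)}

    def parent_row(col, i):
        v = pedigree[col].iloc[i]
        if pd.isna(v) or int(v) < 0:
            return -1
        v = int(v)
        if v not in index:
            raise ValidationError(f"unknown parent id {v}")
        j = index[v]
        if j >= i:
            raise ValidationError("parents must precede offspring in the pedigree")
        return j

    n = len(ids)
    A = np.zeros((n, n))
    for i in range(n):
        s = parent_row("sire", i)
        d = parent_row("dam", i)
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        for j in range(i):
            val = 0.0
            if s >= 0:
                val += 0.5 * A[j, s]
            if d >= 0:
                val += 0.5 * A[j, d]
            A[i, j] = A[j, i] = val
    return A


def allele_frequencies(X: np.ndarray) -> np.ndarray:
    """Alt-allele frequencies from a 0/1/2 dosage matrix (no missing)."""
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValidationError("genotype matrix contains missing values")
    return X.mean(axis=0) / 2.0


def genomic_relationship_matrix(
    X: np.ndarray, p: np.ndarray | None = None, return_scale: bool = False
):
    """VanRaden-style G = (X - 2p)(X - 2p)' / k, k = sum_j 2 p_j (1 - p_j)."""
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValidationError("genotype matrix contains missing values; impute first")
    if p is None:
        p = allele_frequencies(X)
    p = np.asarray(p, dtype=float)
    k = float(np.sum(2.0 * p * (1.0 - p)))
    if k <= 0:
        raise ValidationError("all markers monomorphic; G undefined")
    Xc = X - 2.0 * p
    G = (Xc @ Xc.T) / k
    G = 0.5 * (G + G.T)
    if return_scale:
        return G, k
    return G


def cross_relationship(
    X_new: np.ndarray, X_train: np.ndarray, p: np.ndarray, k: float
) -> np.ndarray:
    """Relationship block between new and training individuals on the
    training-frequency scale (rows: new, cols: train)."""
    Xc_new = np.asarray(X_new, dtype=float) - 2.0 * p
    Xc_tr = np.asarray(X_train, dtype=float) - 2.0 * p
    return (Xc_new @ Xc_tr.T) / k
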
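"""Spectral embedding of cell types in similarity space.

Cell types are compared either by their signature expression over the selected
gene subset ("gene space") or by their regional density profiles ("spatial
space").  Pairwise Pearson correlation R gives a distance ``d = 1 - R``;
similarity is the reciprocal of distance off the diagonal (min-max normalized
over off-diagonal entries), and the unnormalized graph Laplacian
``L = Delta - S`` is eigendecomposed.  For a connected similarity graph the
first eigenvector is constant with eigenvalue 0, so cell types are embedded on
the second and third eigenvectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Distances below this are clipped before taking reciprocals (1/d is
#: undefined at d = 0 for perfectly correlated profiles).
EPS_DISTANCE = 1e-6


def correlation_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise correlation distance ``d_ij = 1 - R_ij`` between rows.

    ``matrix`` is items x observations with at least 3 observation columns.
    Constant rows have undefined correlations; their entries are NaN and a
    warning is emitted.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 observations to correlate")
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=1)
    if (sd == 0).any():
        warnings.warn(f"{int((sd == 0).sum())} constant profiles give NaN distances")
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
    D = 1.0 - R
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=matrix.index, columns=matrix.index)


def similarity_from_distance(D_mat: pd.DataFrame,
                             eps: float = EPS_DISTANCE) -> pd.DataFrame:
    """Reciprocal-distance similarity, min-max normalized off the diagonal.

    ``s_ij = 1 / max(d_ij, eps)`` for ``i != j`` and 0 on the diagonal; the
    off-diagonal entries are then min-max normalized to [0, 1] (the diagonal
    stays 0).  If all off-diagonal distances are equal the normalization is
    degenerate and every off-diagonal similarity is set to 1 with a warning.
    """
    D = D_mat.to_numpy(dtype=float)
    if (D < 0).any():
        raise ValueError("distances must be nonnegative")
    n = D.shape[0]
    off = ~np.eye(n, dtype=bool)
    S = np.zeros_like(D)
    recip = 1.0 / np.maximum(D[off], eps)
    lo, hi = recip.min(), recip.max()
    if hi == lo:
        warnings.warn("all off-diagonal distances equal; similarities set to 1")
        S[off] = 1.0
    else:
        S[off] = (recip - lo) / (hi - lo)
    S = 0.5 * (S + S.T)  # symmetrize against floating-point asymmetry
    return pd.DataFrame(S, index=D_mat.index, columns=D_mat.columns)


@dataclass
class EmbeddingResult:
    similarity: pd.DataFrame
    laplacian: pd.DataFrame
    eigenvalues: np.ndarray            # ascending
    eigenvectors: pd.DataFrame         # items x eigenvector index (v1, v2, ...)

    @property
    def loadings(self) -> pd.DataFrame:
        """Per-item loadings on the first two nontrivial eigenvectors (v2, v3)."""
        return self.eigenvectors[["v2", "v3"]]


def _fix_sign(v: np.ndarray) -> np.ndarray:
    s = v.sum()
    if s < 0:
        return -v
    if s == 0:
        nz = np.flatnonzero(v)
        if nz.size and v[nz[0]] < 0:
            return -v
    return v


def embed(S: pd.DataFrame, atol: float = 1e-10) -> EmbeddingResult:
    """Eigendecomposition of the unnormalized Laplacian ``L = Delta - S``.

    ``S`` must be symmetric and nonnegative.  Eigenvalues are returned in
    ascending order; each eigenvector's sign is fixed by the nonnegative-sum
    rule (first nonzero entry positive on ties).
    """
    A = S.to_numpy(dtype=float)
    if not np.allclose(A, A.T, atol=1e-8):
        raise ValueError("similarity matrix must be symmetric")
    if (A < -atol).any():
        raise ValueError("similarity matrix must be nonnegative")
    L = np.diag(A.sum(axis=1)) - A
    eigvals, eigvecs = np.linalg.eigh(L)
    eigvecs = np.column_stack([_fix_sign(eigvecs[:, k])
                               for k in range(eigvecs.shape[1])])
    names = [f"v{k + 1}" for k in range(len(eigvals))]
    return EmbeddingResult(
        similarity=S,
        laplacian=pd.DataFrame(L, index=S.index, columns=S.columns),
        eigenvalues=eigvals,
        eigenvectors=pd.DataFrame(eigvecs, index=S.index, columns=names),
    )


def embed_profiles(matrix: pd.DataFrame) -> EmbeddingResult:
    """Convenience: correlation distance -> similarity -> Laplacian embedding."""
    return embed(similarity_from_distance(correlation_distance(matrix)))


def reference_distance(S: pd.DataFrame, reference: str) -> pd.Series:
    """Dissimilarity ``1 - S`` of every other item from a reference item."""
    if reference not in S.index:
        raise ValueError(f"unknown reference item {reference!r}")
    out = 1.0 - S.loc[reference].drop(reference)
    out.name = f"distance_from_{reference}"
    return out


def regress_embedding_vs_tau(predictor: pd.Series, response: pd.Series
                             ) -> dict[str, float]:
    """Simple OLS of per-type tau association on an embedding-derived predictor.

    Returns slope, intercept, R^2 and the standard F-test p-value.  Requires
    at least 3 items; a zero-variance predictor is reported as undefined
    (NaN slope/p).
    """
    common = predictor.index.intersection(response.index)
    if len(common) < 3:
        raise ValueError("need at least 3 items to regress")
    x = predictor.loc[common].to_numpy(dtype=float)
    y = response.loc[common].to_numpy(dtype=float)
    if x.std() == 0:
        warnings.warn("zero-variance predictor; regression undefined")
        return {"slope": np.nan, "intercept": np.nan, "r_squared": np.nan,
                "p": np.nan, "n": len(common)}
    fit = stats.linregress(x, y)
    return {"slope": float(fit.slope), "intercept": float(fit.intercept),
            "r_squared": float(fit.rvalue ** 2), "p": float(fit.pvalue),
            "n": len(common)}
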
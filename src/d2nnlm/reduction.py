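"""SVD rank reduction of the document--n-gram space.

The sparse document-term matrix X (transcripts x n-grams) is factored as
X = U S V^T and each fitted transcript is represented by its leading k
left-singular coordinates scaled by the singular values, U_k S_k — the
latent-semantic-analysis convention.  Held-out transcripts are projected
onto the same basis via X_new V_k.  Because the number of transcripts is
far below the vocabulary size in this regime, the admissible rank is
bounded by the number of fitted rows: with k = full rank the reduced
rows preserve all pairwise Euclidean geometry while collapsing thousands
of sparse columns to a few dozen dense coordinates.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin


def _dense(X) -> np.ndarray:
    if sp.issparse(X):
        return np.asarray(X.todense(), dtype=np.float64)
    return np.asarray(X, dtype=np.float64)


class SVDReducer(BaseEstimator, TransformerMixin):
    """Truncated SVD features with exact full-rank support (sklearn transformer).

    Parameters
    ----------
    k : int or "auto"
        Number of retained components.  ``"auto"`` (default) keeps the full
        admissible rank min(#fit rows, #columns) — the setting under which a
        corpus of m transcripts yields m features per instance.
    scale : {"singular", "unit"}
        ``"singular"`` (default) returns U_k S_k, the latent-semantic-analysis
        convention that preserves the Euclidean geometry of the fit rows at
        full rank.  ``"unit"`` returns the left-singular matrix U_k itself
        (held-out rows are mapped by X V_k S_k^{-1}); its entries are O(1),
        which is the convenient scale for feeding tanh networks.

    Attributes
    ----------
    components_ : (k, n_columns) right-singular basis V_k^T.
    singular_values_ : the k leading singular values, nonincreasing.
    embedding_ : (n_fit_rows, k) reduced coordinates of the fit rows.
    """

    def __init__(self, k: int | str = "auto", scale: str = "singular"):
        self.k = k
        self.scale = scale

    def _resolve_k(self, shape: tuple[int, int]) -> int:
        admissible = min(shape)
        if self.k == "auto":
            return admissible
        k = int(self.k)
        if not 1 <= k <= admissible:
            raise ValueError(
                f"k={k} outside admissible range [1, {admissible}] "
                f"for a {shape[0]}x{shape[1]} matrix")
        return k

    def fit(self, X, y=None) -> "SVDReducer":
        if self.scale not in ("singular", "unit"):
            raise ValueError("scale must be 'singular' or 'unit'")
        A = _dense(X)
        if A.ndim != 2 or A.size == 0:
            raise ValueError("X must be a nonempty 2-D matrix")
        k = self._resolve_k(A.shape)
        U, s, Vt = np.linalg.svd(A, full_matrices=False)
        self.n_features_in_ = A.shape[1]
        self.components_ = Vt[:k]
        self.singular_values_ = s[:k]
        self.embedding_ = U[:, :k] * s[:k] if self.scale == "singular" else U[:, :k]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "components_"):
            raise RuntimeError("SVDReducer is not fitted")
        A = _dense(X)
        if A.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {A.shape[1]} columns, reducer was fitted with "
                f"{self.n_features_in_}")
        proj = A @ self.components_.T
        if self.scale == "unit":
            # guard exact-zero singular values (rank-deficient fit matrix)
            s = np.where(self.singular_values_ > 0, self.singular_values_, 1.0)
            proj = proj / s
        return proj

    def fit_transform(self, X, y=None) -> np.ndarray:
        # exact left-singular coordinates for the fit rows (equals
        # transform(X) up to round-off, but uses U S directly)
        self.fit(X)
        return self.embedding_.copy()

    def reconstruct(self, reduced: np.ndarray) -> np.ndarray:
        """Map reduced coordinates back to the n-gram space (rank-k approximation)."""
        return np.asarray(reduced) @ self.components_


def svd_reduce(matrix, k: int | str = "auto"):
    """Reduce a document-term matrix; returns (features, singular_values, reducer).

    Thin functional wrapper over :class:`SVDReducer`.
    """
    red = SVDReducer(k=k)
    feats = red.fit_transform(matrix)
    return feats, red.singular_values_, red
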
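"""Global sensitivity: partial rank correlation (PRCC) and Spearman matrices.

PRCC of a parameter against a surrogate term is the Pearson correlation of
the residuals of both rank-transformed variables after linear regression on
the ranks of every *other* parameter — a monotone-invariant measure of a
parameter's influence controlling for all the rest.  The term-vs-term
Spearman matrix exposes trade-off structure between phenotype criteria.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

__all__ = ["SensitivityMatrix", "prcc", "spearman_terms", "plot_heatmap"]


@dataclass
class SensitivityMatrix:
    """Correlation-type sensitivity values with row/column labels."""

    values: pd.DataFrame  # rows: terms; cols: parameters (PRCC) or terms (Spearman)
    kind: str  # "prcc" | "spearman"
    n: int  # samples used (after listwise deletion)

    def to_csv(self, path) -> None:
        self.values.to_csv(path)

    def __getitem__(self, rowcol: tuple[str, str]) -> float:
        row, col = rowcol
        return float(self.values.loc[row, col])


def _as_frame(X, prefix: str) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return pd.DataFrame(X, columns=[f"{prefix}{i}" for i in range(X.shape[1])])


def _drop_incomplete(X: pd.DataFrame, Y: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    mask = np.isfinite(X.to_numpy()).all(axis=1) & np.isfinite(Y.to_numpy()).all(axis=1)
    dropped = int((~mask).sum())
    if dropped:
        warnings.warn(f"dropping {dropped} incomplete rows (failed simulations)")
    return X.loc[mask], Y.loc[mask]


def prcc(X, Y) -> SensitivityMatrix:
    """Partial rank correlation of every (parameter, term) pair.

    ``X``: samples x parameters; ``Y``: samples x terms.  Requires at least 3
    more samples than parameters.  Constant columns yield NaN with a warning.
    """
    X, Y = _as_frame(X, "x"), _as_frame(Y, "y")
    X, Y = _drop_incomplete(X, Y)
    n, p = X.shape
    if n < p + 3:
        raise ValueError(f"need at least {p + 3} samples for {p} parameters, have {n}")
    const_x = [c for c in X.columns if X[c].nunique() <= 1]
    const_y = [c for c in Y.columns if Y[c].nunique() <= 1]
    for c in const_x + const_y:
        warnings.warn(f"constant column {c!r}: PRCC undefined, reported as NaN")

    RX = np.column_stack([rankdata(X[c]) for c in X.columns])
    RY = np.column_stack([rankdata(Y[c]) for c in Y.columns])
    out = np.full((Y.shape[1], p), np.nan)
    ones = np.ones((n, 1))
    for j, xc in enumerate(X.columns):
        if xc in const_x:
            continue
        others = np.delete(RX, j, axis=1)
        Z = np.hstack([ones, others])
        # residualize rank(x_j) and every rank(y) on the other parameters' ranks
        coef_x, *_ = np.linalg.lstsq(Z, RX[:, j], rcond=None)
        rx = RX[:, j] - Z @ coef_x
        if np.allclose(rx, 0):
            raise np.linalg.LinAlgError(
                f"rank-deficient regression: parameter {xc!r} is collinear with the others"
            )
        for k, yc in enumerate(Y.columns):
            if yc in const_y:
                continue
            coef_y, *_ = np.linalg.lstsq(Z, RY[:, k], rcond=None)
            ry = RY[:, k] - Z @ coef_y
            denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
            if denom == 0:
                continue
            out[k, j] = float(np.dot(rx, ry) / denom)
    values = pd.DataFrame(out, index=list(Y.columns), columns=list(X.columns))
    return SensitivityMatrix(values=values, kind="prcc", n=n)


def spearman_terms(Y) -> SensitivityMatrix:
    """Pairwise Spearman correlation between surrogate terms.

    Symmetric with unit diagonal; average ranks for ties; constant columns
    reported as NaN with a warning.
    """
    Y = _as_frame(Y, "y")
    Y = Y.loc[np.isfinite(Y.to_numpy()).all(axis=1)]
    n, m = Y.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    const = [c for c in Y.columns if Y[c].nunique() <= 1]
    for c in const:
        warnings.warn(f"constant column {c!r}: Spearman undefined, reported as NaN")
    if m == 1:
        mat = np.array([[1.0]])
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mat, _ = spearmanr(Y.to_numpy())
        if np.ndim(mat) == 0:  # scipy returns a scalar for exactly 2 columns
            r = float(mat)
            mat = np.array([[1.0, r], [r, 1.0]])
    for i, c in enumerate(Y.columns):
        if c in const:
            mat[i, :] = np.nan
            mat[:, i] = np.nan
        else:
            mat[i, i] = 1.0
    values = pd.DataFrame(mat, index=list(Y.columns), columns=list(Y.columns))
    return SensitivityMatrix(values=values, kind="spearman", n=n)


def plot_heatmap(matrix: SensitivityMatrix, path=None, cmap: str = "RdBu_r"):
    """Render the matrix as a heatmap (PNG/SVG by file extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = matrix.values
    fig, ax = plt.subplots(
        figsize=(max(6, 0.3 * vals.shape[1] + 2), max(4, 0.3 * vals.shape[0] + 2))
    )
    im = ax.imshow(vals.to_numpy(), vmin=-1, vmax=1, cmap=cmap, aspect="auto")
    ax.set_xticks(range(vals.shape[1]), vals.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(vals.shape[0]), vals.index, fontsize=7)
    fig.colorbar(im, ax=ax, label=matrix.kind.upper())
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
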
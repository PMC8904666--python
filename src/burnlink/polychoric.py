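"""Two-step maximum-likelihood polychoric correlations.

Step 1 fixes each item's thresholds at inverse-normal transforms of its
marginal cumulative proportions; step 2 maximizes the bivariate-normal
contingency-table likelihood over the single correlation parameter.
Used by the unidimensionality screen (first/second eigenvalue ratio of the
pooled polychoric matrix).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import multivariate_normal, norm

_CLIP = 8.0  # effective infinity for normal quantiles


def _thresholds(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Observed ordered values and interior normal thresholds of one item."""
    values, counts = np.unique(codes, return_counts=True)
    cum = np.cumsum(counts)[:-1] / counts.sum()
    return values, norm.ppf(cum)


def _cell_probs(tau_x: np.ndarray, tau_y: np.ndarray, rho: float) -> np.ndarray:
    """Bivariate-normal rectangle probabilities over the category grid."""
    gx = np.concatenate([[-_CLIP], np.clip(tau_x, -_CLIP, _CLIP), [_CLIP]])
    gy = np.concatenate([[-_CLIP], np.clip(tau_y, -_CLIP, _CLIP), [_CLIP]])
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    bvn = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
    cdf = bvn.cdf(pts).reshape(xx.shape)
    cells = cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
    return np.clip(cells, 1e-12, None)


def polychoric_corr(x, y) -> float:
    """Polychoric correlation of two ordinal variables (pairwise complete).

    Raises ``FloatingPointError`` when the likelihood cannot be optimized
    (treated upstream as a non-converging pair).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 10:
        raise FloatingPointError("too few complete pairs for polychoric estimation")
    vx, tau_x = _thresholds(x)
    vy, tau_y = _thresholds(y)
    if len(vx) < 2 or len(vy) < 2:
        raise FloatingPointError("degenerate marginal distribution")
    ix = np.searchsorted(vx, x)
    iy = np.searchsorted(vy, y)
    counts = np.zeros((len(vx), len(vy)))
    np.add.at(counts, (ix, iy), 1.0)

    def nll(rho: float) -> float:
        return -float(np.sum(counts * np.log(_cell_probs(tau_x, tau_y, rho))))

    res = minimize_scalar(nll, bounds=(-0.995, 0.995), method="bounded",
                          options={"xatol": 1e-4})
    if not res.success:
        raise FloatingPointError("polychoric likelihood optimization failed")
    return float(res.x)


def polychoric_matrix(frame: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise polychoric correlation matrix of the item columns.

    A pair whose estimate fails to converge falls back to the Pearson
    correlation of the raw codes, recorded in the returned warning list.
    """
    cols = list(frame.columns)
    R = np.eye(len(cols))
    warnings: list[str] = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            try:
                r = polychoric_corr(frame[cols[i]], frame[cols[j]])
            except FloatingPointError as exc:
                r = float(frame[cols[i]].corr(frame[cols[j]]))
                warnings.append(
                    f"polychoric pair ({cols[i]}, {cols[j]}) dropped ({exc}); "
                    "Pearson fallback used"
                )
            R[i, j] = R[j, i] = r
    return pd.DataFrame(R, index=cols, columns=cols), warnings
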
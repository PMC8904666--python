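"""Graded response model (GRM) machinery.

Samejima's graded response model for an item with ``m`` ordered categories
is parameterized by a discrimination ``a > 0`` and strictly increasing
thresholds ``b_1 < ... < b_{m-1}``.  The boundary curves are logistic,

    P(X >= k | theta) = 1 / (1 + exp(-a (theta - b_k))),

and category probabilities are adjacent differences of the boundary curves.
No 1.7 scaling constant is applied; simulator, calibration and scoring all
share the logistic metric, and the reporting t-metric ``t = 50 + 10 theta``
is invariant to that convention.

This module provides category probabilities, marginal likelihood pieces,
expected-a-posteriori (EAP) scoring per response pattern and per summed
score (via the Lord-Wingersky recursion), the test characteristic curve and
the test information function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import InvalidParameterError, NoInformationError
from .scales import MISSING, ScaleDef


@dataclass(frozen=True)
class ItemParams:
    """GRM parameters of one item: discrimination ``a`` and thresholds ``b``."""

    item: str
    a: float
    b: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "a", float(self.a))
        object.__setattr__(self, "b", tuple(float(x) for x in self.b))
        if not np.isfinite(self.a) or self.a <= 0:
            raise InvalidParameterError(f"item {self.item!r}: a must be positive")
        if len(self.b) < 1:
            raise InvalidParameterError(f"item {self.item!r}: needs >= 1 threshold")
        if not all(np.isfinite(self.b)):
            raise InvalidParameterError(f"item {self.item!r}: thresholds must be finite")
        if any(x >= y for x, y in zip(self.b, self.b[1:])):
            raise InvalidParameterError(
                f"item {self.item!r}: thresholds must be strictly increasing"
            )

    @property
    def n_categories(self) -> int:
        return len(self.b) + 1


ParamSet = Mapping[str, ItemParams]


@dataclass(frozen=True)
class QuadratureGrid:
    """Fixed latent-trait quadrature nodes with base (unnormalized) spacing."""

    nodes: np.ndarray

    @classmethod
    def default(cls, n: int = 61, lo: float = -6.0, hi: float = 6.0) -> "QuadratureGrid":
        return cls(np.linspace(lo, hi, n))

    @classmethod
    def dense(cls, n: int = 2001, lo: float = -8.0, hi: float = 8.0) -> "QuadratureGrid":
        return cls(np.linspace(lo, hi, n))

    def __post_init__(self):
        nodes = np.asarray(self.nodes, dtype=float)
        if nodes.ndim != 1 or len(nodes) < 2 or np.any(np.diff(nodes) <= 0):
            raise InvalidParameterError("quadrature nodes must be strictly increasing")
        object.__setattr__(self, "nodes", nodes)


@dataclass(frozen=True)
class LatentDensity:
    """Normal latent-trait density N(mean, sd^2) on the anchor metric."""

    mean: float = 0.0
    sd: float = 1.0

    def __post_init__(self):
        if not np.isfinite(self.mean) or not (np.isfinite(self.sd) and self.sd > 0):
            raise InvalidParameterError("latent density needs finite mean and sd > 0")

    def weights(self, grid: QuadratureGrid) -> np.ndarray:
        """Normalized weights of the density at the grid nodes."""
        z = (grid.nodes - self.mean) / self.sd
        w = np.exp(-0.5 * z**2)
        return w / w.sum()


@dataclass(frozen=True)
class ScoredRespondent:
    """EAP trait estimate for one respondent, with its t-metric transform."""

    respondent_id: object
    theta: float
    se: float

    @property
    def t(self) -> float:
        return 50.0 + 10.0 * self.theta

    @property
    def se_t(self) -> float:
        return 10.0 * self.se


# ---------------------------------------------------------------------------
# category probabilities


def boundary_probs(params: ItemParams, theta) -> np.ndarray:
    """P(X >= k | theta) for k = 1..m-1; shape (..., m-1)."""
    theta = np.asarray(theta, dtype=float)
    b = np.asarray(params.b)
    return expit(params.a * (theta[..., None] - b))


def grm_category_probs(params: ItemParams, theta) -> np.ndarray:
    """Category probabilities P(X = k | theta), k = 0..m-1; shape (..., m).

    Probabilities are non-negative and sum to one; the boundary curves are
    monotone decreasing in the category index.
    """
    pstar = boundary_probs(params, theta)
    shape = pstar.shape[:-1]
    ones = np.ones(shape + (1,))
    zeros = np.zeros(shape + (1,))
    cum = np.concatenate([ones, pstar, zeros], axis=-1)
    probs = cum[..., :-1] - cum[..., 1:]
    return np.clip(probs, 0.0, 1.0)


def _prob_tables(params_list: Sequence[ItemParams], nodes: np.ndarray) -> list[np.ndarray]:
    """Per item: (m_j, Q) category-probability table at the nodes."""
    return [np.ascontiguousarray(grm_category_probs(p, nodes).T) for p in params_list]


def pattern_likelihoods(
    X: np.ndarray, params_list: Sequence[ItemParams], nodes: np.ndarray
) -> np.ndarray:
    """Likelihood of each response pattern at each node; shape (N, Q).

    ``X`` holds 0-based category indices, -1 for missing (skipped).
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.int64))
    if X.shape[1] != len(params_list):
        raise InvalidParameterError(
            f"pattern has {X.shape[1]} items but {len(params_list)} parameter records"
        )
    tables = _prob_tables(params_list, nodes)
    L = np.ones((X.shape[0], len(nodes)))
    for j, table in enumerate(tables):
        obs = X[:, j] != MISSING
        if np.any(X[obs, j] >= table.shape[0]):
            raise InvalidParameterError(
                f"response index out of range for item {params_list[j].item!r}"
            )
        L[obs] *= table[X[obs, j]]
    return L


def loglikelihood(
    X: np.ndarray,
    params_list: Sequence[ItemParams],
    density: LatentDensity,
    grid: QuadratureGrid,
) -> float:
    """Marginal log-likelihood of the response matrix.

    Missing responses are skipped item-wise; a respondent with no observed
    items contributes log(1) = 0 (their pattern likelihood is 1 at every
    node).
    """
    L = pattern_likelihoods(X, params_list, grid.nodes)
    w = density.weights(grid)
    marg = L @ w
    return float(np.sum(np.log(np.clip(marg, 1e-300, None))))


# ---------------------------------------------------------------------------
# EAP scoring


def eap_theta(
    pattern: np.ndarray,
    params_list: Sequence[ItemParams],
    density: LatentDensity,
    grid: QuadratureGrid,
) -> tuple[float, float]:
    """Posterior mean and SD of theta for one response pattern."""
    pattern = np.asarray(pattern, dtype=np.int64)
    if np.all(pattern == MISSING):
        raise NoInformationError("all responses missing; cannot score")
    theta, se = eap_theta_many(pattern[None, :], params_list, density, grid)
    return float(theta[0]), float(se[0])


def eap_theta_many(
    X: np.ndarray,
    params_list: Sequence[ItemParams],
    density: LatentDensity,
    grid: QuadratureGrid,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pattern-level EAP; returns (theta_hat, posterior sd)."""
    L = pattern_likelihoods(X, params_list, grid.nodes)
    post = L * density.weights(grid)
    norm = post.sum(axis=1, keepdims=True)
    post = post / norm
    theta = post @ grid.nodes
    second = post @ grid.nodes**2
    var = np.clip(second - theta**2, 0.0, None)
    return theta, np.sqrt(var)


# ---------------------------------------------------------------------------
# summed scores (Lord-Wingersky recursion)


def summed_score_likelihoods(
    params_list: Sequence[ItemParams],
    theta,
    lowest_codes: Sequence[int] | int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """P(raw total = s | theta) over the full raw range.

    Computed by the Lord-Wingersky recursion over items.  Returns
    ``(raw_scores, probs)`` where ``probs`` has shape (..., n_raw) matching
    the shape of ``theta``, and ``raw_scores`` includes the lowest-code
    offset (e.g. 1..5 for a single item coded 1-5).
    """
    theta = np.asarray(theta, dtype=float)
    scalar = theta.ndim == 0
    th = np.atleast_1d(theta)
    if np.isscalar(lowest_codes):
        lowest_codes = [int(lowest_codes)] * len(params_list)
    dist = np.ones((len(th), 1))
    for p in params_list:
        probs = grm_category_probs(p, th)  # (T, m)
        m = probs.shape[1]
        new = np.zeros((len(th), dist.shape[1] + m - 1))
        for k in range(m):
            new[:, k : k + dist.shape[1]] += dist * probs[:, k : k + 1]
        dist = new
    offset = int(sum(lowest_codes))
    raw = np.arange(dist.shape[1]) + offset
    if scalar:
        dist = dist[0]
    return raw, dist


def summed_score_eap(
    params_list: Sequence[ItemParams],
    density: LatentDensity,
    grid: QuadratureGrid,
    lowest_codes: Sequence[int] | int = 0,
) -> pd.DataFrame:
    """Summed-score EAP table: posterior mean/SD of theta given each raw score.

    Returns a DataFrame with columns ``raw``, ``theta``, ``se``,
    ``p_marginal`` (the marginal probability of the raw score under the
    density) and ``degenerate`` (True when that probability is at machine
    precision, in which case the row is flagged rather than dropped).
    """
    w = density.weights(grid)
    raw, S = summed_score_likelihoods(params_list, grid.nodes, lowest_codes)  # (Q, S)
    joint = S.T * w  # (n_raw, Q)
    marg = joint.sum(axis=1)
    degenerate = marg <= 1e-300
    safe = np.where(degenerate, 1.0, marg)
    post = joint / safe[:, None]
    theta = post @ grid.nodes
    var = np.clip(post @ grid.nodes**2 - theta**2, 0.0, None)
    return pd.DataFrame(
        {
            "raw": raw,
            "theta": theta,
            "se": np.sqrt(var),
            "p_marginal": marg,
            "degenerate": degenerate,
        }
    )


# ---------------------------------------------------------------------------
# test characteristic and information


def tcc(
    params_list: Sequence[ItemParams],
    theta,
    lowest_codes: Sequence[int] | int = 0,
) -> np.ndarray:
    """Test characteristic curve: expected raw total score at theta."""
    theta = np.asarray(theta, dtype=float)
    if np.isscalar(lowest_codes):
        lowest_codes = [int(lowest_codes)] * len(params_list)
    total = np.zeros(theta.shape)
    for p, low in zip(params_list, lowest_codes):
        probs = grm_category_probs(p, theta)
        scores = np.arange(p.n_categories) + low
        total = total + probs @ scores
    return total


def test_information(params_list: Sequence[ItemParams], theta) -> np.ndarray:
    """Fisher information of the item set at theta (additive over items).

    For the GRM, I(theta) = sum_j sum_k P'_jk(theta)^2 / P_jk(theta) with
    P'_jk the derivative of the category probability.
    """
    theta = np.asarray(theta, dtype=float)
    info = np.zeros(theta.shape)
    for p in params_list:
        pstar = boundary_probs(p, theta)  # (..., m-1)
        shape = pstar.shape[:-1]
        d = p.a * pstar * (1.0 - pstar)
        dfull = np.concatenate(
            [np.zeros(shape + (1,)), d, np.zeros(shape + (1,))], axis=-1
        )
        dprob = dfull[..., :-1] - dfull[..., 1:]  # P'_k
        probs = grm_category_probs(p, theta)
        info = info + np.sum(dprob**2 / np.clip(probs, 1e-300, None), axis=-1)
    return info


def params_for_scale(params: ParamSet, scale: ScaleDef) -> list[ItemParams]:
    """Parameter records for a scale's items, in scale order."""
    missing = [i for i in scale.item_ids if i not in params]
    if missing:
        raise InvalidParameterError(f"scale {scale.name!r}: no parameters for {missing}")
    return [params[i] for i in scale.item_ids]
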
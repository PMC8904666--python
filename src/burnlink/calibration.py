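"""Marginal maximum likelihood calibration of the graded response model.

An EM algorithm with fixed quadrature: the E-step computes each
respondent's posterior over the nodes and accumulates expected category
counts per item; the M-step maximizes the expected complete-data
log-likelihood item by item (Newton-type updates via L-BFGS on a
reparameterized surface that enforces threshold ordering,
``b_k = b_1 + sum_{l<=k} exp(gamma_l)``).

Fixed-parameter calibration: anchor items are held at supplied values and
the latent density's mean and SD are freed, so freely estimated (target)
items land on the anchor metric.  Without fixed items the density is pinned
to N(0, 1) for identification.

Missing responses are ignored in all likelihood terms (MAR treatment).
Empty response categories of free items are collapsed into the adjacent
category toward the middle of the scale by default, with the recode map
recorded in the result; ``on_empty_category="fail"`` raises instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from .errors import InvalidParameterError, SchemaError
from .irt import (
    ItemParams,
    LatentDensity,
    QuadratureGrid,
    grm_category_probs,
    loglikelihood,
    pattern_likelihoods,
)
from .scales import MISSING, ScaleDef


@dataclass
class CalibrationResult:
    """Outcome of one calibration run."""

    params: dict[str, ItemParams]          # all items (fixed echoed + free estimated)
    density: LatentDensity
    converged: bool
    n_cycles: int
    max_change: float
    loglik: float
    loglik_trace: list[float] = field(default_factory=list)
    free_items: tuple[str, ...] = ()
    collapse_maps: dict[str, dict[int, int]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def _pack(a: float, b: np.ndarray) -> np.ndarray:
    u = np.empty(1 + len(b))
    u[0] = np.log(a)
    u[1] = b[0]
    if len(b) > 1:
        u[2:] = np.log(np.diff(b))
    return u


def _unpack(u: np.ndarray) -> tuple[float, np.ndarray]:
    a = np.exp(u[0])
    b = np.empty(len(u) - 1)
    b[0] = u[1]
    if len(b) > 1:
        b[1:] = b[0] + np.cumsum(np.exp(u[2:]))
    return a, b


def _item_negQ(u: np.ndarray, r: np.ndarray, nodes: np.ndarray) -> tuple[float, np.ndarray]:
    """Negative expected complete-data loglik for one item, with gradient.

    ``r`` is the (m, Q) expected count table from the E-step.
    """
    a, b = _unpack(u)
    m = r.shape[0]
    z = a * (nodes[None, :] - b[:, None])           # (m-1, Q)
    pstar = 1.0 / (1.0 + np.exp(-z))
    cum = np.vstack([np.ones_like(nodes), pstar, np.zeros_like(nodes)])
    probs = np.clip(cum[:-1] - cum[1:], 1e-12, None)  # (m, Q)
    negQ = -float(np.sum(r * np.log(probs)))

    ratio = r / probs                                # (m, Q)
    v = pstar * (1.0 - pstar)                        # (m-1, Q)
    w = v * (nodes[None, :] - b[:, None])
    wfull = np.vstack([np.zeros_like(nodes), w, np.zeros_like(nodes)])
    # dP_k/da = w_k - w_{k+1}
    g_a = -float(np.sum(ratio * (wfull[:-1] - wfull[1:])))
    # dQ/db_j = -a * sum_q v_j (r_{j-1}/P_{j-1} - r_j/P_j)
    g_b = -a * np.sum(v * (ratio[:-1] - ratio[1:]), axis=1)  # (m-1,)

    grad = np.empty_like(u)
    grad[0] = g_a * a  # chain through log a
    grad[1] = g_b.sum()
    if m > 2:
        d = np.exp(u[2:])
        tail = np.cumsum(g_b[::-1])[::-1]  # sum_{k>=l} g_b[k]
        grad[2:] = d * tail[1:]
    return negQ, grad


def _start_values(X_col: np.ndarray, m: int) -> tuple[float, np.ndarray]:
    """a = 1; b from inverse-normal transforms of cumulative proportions."""
    obs = X_col[X_col != MISSING]
    b = np.zeros(m - 1)
    n = len(obs)
    for k in range(1, m):
        p_ge = np.mean(obs >= k) if n else 0.5
        p_ge = np.clip(p_ge, 1.0 / max(n, 2) / 2, 1 - 1.0 / max(n, 2) / 2)
        b[k - 1] = -norm.ppf(p_ge)
    b = np.clip(b, -3.0, 3.0)
    for k in range(1, m - 1):  # enforce strict ordering
        b[k] = max(b[k], b[k - 1] + 0.05)
    return 1.0, b


def _collapse_empty(
    X: np.ndarray, col: int, m: int, item: str, mode: str, warnings: list[str]
) -> tuple[int, dict[int, int]]:
    """Collapse unobserved categories of one item; returns new m and recode map."""
    obs = X[:, col][X[:, col] != MISSING]
    counts = np.bincount(obs, minlength=m)
    if np.all(counts > 0):
        return m, {}
    if mode == "fail":
        empty = list(np.flatnonzero(counts == 0))
        raise SchemaError(f"item {item!r}: empty categories {empty} (strict mode)")
    # merge each empty category into its neighbor toward the middle
    keep = np.flatnonzero(counts > 0)
    if len(keep) < 2:
        raise SchemaError(f"item {item!r}: fewer than 2 observed categories")
    recode_keep = {int(k): i for i, k in enumerate(keep)}
    recode = {}
    for k in range(m):
        if counts[k] > 0:
            recode[k] = recode_keep[k]
        else:
            lower, upper = keep[keep < k], keep[keep > k]
            if k < m / 2:
                nearest = upper.min() if len(upper) else lower.max()
            else:
                nearest = lower.max() if len(lower) else upper.min()
            recode[k] = recode_keep[int(nearest)]
    mask = X[:, col] != MISSING
    X[mask, col] = np.vectorize(recode.get)(X[mask, col])
    warnings.append(f"item {item!r}: collapsed empty categories, recode {recode}")
    return len(keep), recode


def calibrate(
    matrix: pd.DataFrame,
    scales: Sequence[ScaleDef],
    fixed: Mapping[str, ItemParams] | None = None,
    grid: QuadratureGrid | None = None,
    *,
    tol: float = 1e-4,
    max_cycles: int = 500,
    estimate_density: bool | None = None,
    on_empty_category: str = "collapse",
) -> CalibrationResult:
    """Calibrate GRM item parameters by MML-EM.

    Parameters
    ----------
    matrix : DataFrame
        Wide response matrix covering all items of ``scales``.
    scales : sequence of ScaleDef
        Scales whose items enter the calibration.
    fixed : mapping item id -> ItemParams, optional
        Anchor items held at these values (echoed unchanged in the result).
    estimate_density : bool, optional
        Free the latent mean/sd.  Defaults to True when ``fixed`` is
        non-empty (fixed-parameter calibration) and False otherwise
        (density pinned to N(0,1) for identification).
    """
    fixed = dict(fixed or {})
    grid = grid or QuadratureGrid.default()
    if estimate_density is None:
        estimate_density = bool(fixed)

    items: list[str] = []
    m_of: dict[str, int] = {}
    cols: list[np.ndarray] = []
    for sc in scales:
        idx = sc.to_indices(matrix)
        for j, item in enumerate(sc.item_ids):
            if item in m_of:
                continue
            items.append(item)
            m_of[item] = sc.n_categories[j]
            cols.append(idx[:, j])
    X = np.column_stack(cols)
    for item in fixed:
        if item not in m_of:
            raise SchemaError(f"fixed item {item!r} not among calibrated scales")

    warnings: list[str] = []
    collapse_maps: dict[str, dict[int, int]] = {}
    free_idx = [j for j, it in enumerate(items) if it not in fixed]
    for j in free_idx:
        it = items[j]
        new_m, recode = _collapse_empty(X, j, m_of[it], it, on_empty_category, warnings)
        if recode:
            collapse_maps[it] = recode
            m_of[it] = new_m

    n_zero = int(np.sum(np.all(X == MISSING, axis=1)))
    if n_zero:
        warnings.append(f"{n_zero} respondents with no observed items contribute nothing")

    # initialize
    current: dict[str, ItemParams] = {}
    for j, it in enumerate(items):
        if it in fixed:
            p = fixed[it]
            if p.n_categories != m_of[it]:
                raise SchemaError(
                    f"fixed item {it!r}: {p.n_categories} categories in parameters, "
                    f"{m_of[it]} in scale definition"
                )
            current[it] = p
        else:
            a0, b0 = _start_values(X[:, j], m_of[it])
            current[it] = ItemParams(it, a0, tuple(b0))
    density = LatentDensity(0.0, 1.0)

    nodes = grid.nodes
    converged = False
    max_change = np.inf
    trace: list[float] = []
    n_cycles = 0
    for cycle in range(1, max_cycles + 1):
        n_cycles = cycle
        plist = [current[it] for it in items]
        L = pattern_likelihoods(X, plist, nodes)
        w = density.weights(grid)
        post = L * w
        norm_c = post.sum(axis=1, keepdims=True)
        post = post / np.clip(norm_c, 1e-300, None)
        trace.append(float(np.sum(np.log(np.clip(L @ w, 1e-300, None)))))

        max_change = 0.0
        # M-step: free items
        for j in free_idx:
            it = items[j]
            mask = X[:, j] != MISSING
            r = np.zeros((m_of[it], len(nodes)))
            np.add.at(r, X[mask, j], post[mask])
            old = current[it]
            u0 = _pack(old.a, np.asarray(old.b))
            res = minimize(_item_negQ, u0, args=(r, nodes), jac=True, method="L-BFGS-B")
            a, b = _unpack(res.x)
            a = float(np.clip(a, 1e-6, 100.0))
            new = ItemParams(it, a, tuple(b))
            max_change = max(
                max_change,
                abs(new.a - old.a),
                float(np.max(np.abs(np.asarray(new.b) - np.asarray(old.b)))),
            )
            current[it] = new
        # M-step: density
        if estimate_density:
            tot = post.sum(axis=0)
            n_eff = tot.sum()
            mu = float(tot @ nodes / n_eff)
            var = float(tot @ nodes**2 / n_eff - mu**2)
            sd = float(np.sqrt(max(var, 1e-6)))
            max_change = max(max_change, abs(mu - density.mean), abs(sd - density.sd))
            density = LatentDensity(mu, sd)
        if max_change < tol:
            converged = True
            break

    if not converged:
        warnings.append(
            f"EM did not converge in {max_cycles} cycles (max change {max_change:.2e})"
        )
    final_ll = loglikelihood(X, [current[it] for it in items], density, grid)
    return CalibrationResult(
        params=current,
        density=density,
        converged=converged,
        n_cycles=n_cycles,
        max_change=float(max_change),
        loglik=final_ll,
        loglik_trace=trace,
        free_items=tuple(items[j] for j in free_idx),
        collapse_maps=collapse_maps,
        warnings=warnings,
    )
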
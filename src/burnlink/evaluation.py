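"""Linking accuracy, assumption checks, reliability and invariance.

Accuracy of a linking method is quantified by k-fold cross-validation: the
crosswalk is rebuilt on the training folds, held-out respondents' target
raw scores are translated through it ("predicted" anchor t-scores), their
anchor responses are scored directly under the fixed anchor parameters
("actual" t-scores), and the pooled out-of-fold pairs yield the
correlation, mean difference and SD of difference.  The method winning on
all three criteria across all item sets is selected; absent a dominator
the comparison is reported as indeterminate.

Conditional reliability at trait level theta is ``1 - 1/I(theta)`` (the
unit-population-variance convention matching t-metric reporting), floored
at zero; 0.70 and 0.90 are the conventional adequacy thresholds for group-
and individual-level assessment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import LinkingUndefinedError, SchemaError
from .irt import (
    ItemParams,
    LatentDensity,
    QuadratureGrid,
    eap_theta_many,
    params_for_scale,
    test_information,
)
from .linking import (
    Crosswalk,
    ItemSet,
    anchor_raw_to_t_table,
    equipercentile_link,
    filter_missingness,
    irt_link,
)
from .polychoric import polychoric_matrix


@dataclass
class LinkingAccuracy:
    """Pooled out-of-fold accuracy of one linking method on one item set."""

    item_set: str
    method: str
    r: float
    mean_diff: float          # predicted - actual, t-units
    sd_diff: float
    n: int
    n_folds_used: int = 0
    warnings: list[str] = field(default_factory=list)


@dataclass
class MethodSelection:
    status: str               # 'winner' | 'indeterminate' | 'uncontested'
    method: str | None
    report: pd.DataFrame


@dataclass
class AssumptionReport:
    item_set: str
    inter_scale_r: float
    eigenvalues: np.ndarray
    eigen_ratio: float        # lambda_1 / lambda_2
    prop_first: float
    passes_correlation: bool
    passes_unidimensionality: bool
    r_threshold: float
    ratio_threshold: float
    warnings: list[str] = field(default_factory=list)


@dataclass
class ReliabilityCurve:
    scale: str
    t: np.ndarray
    reliability: np.ndarray


@dataclass
class InvarianceReport:
    item_set: str
    method: str
    crosswalks: dict[object, Crosswalk]
    delta_t: pd.DataFrame     # raw, t per group, abs difference
    max_abs_delta: float
    mean_abs_delta: float
    flagged: bool
    margin: float


# ---------------------------------------------------------------------------
# crosswalk construction shared by CV, invariance and the pipeline


def build_crosswalk(
    item_set: ItemSet,
    method: str,
    grid: QuadratureGrid | None = None,
    *,
    presmooth_degree: int | None = None,
) -> tuple[Crosswalk, LatentDensity]:
    """Build one crosswalk; returns it with the latent density it used."""
    grid = grid or QuadratureGrid.default()
    reference = LatentDensity(0.0, 1.0)  # anchor reference population (t = 50 + 10 theta)
    if method == "irt":
        cw = irt_link(item_set, grid)
        return cw, reference
    if method == "equipercentile":
        filt = filter_missingness(item_set.matrix, [item_set.target, item_set.anchor])
        t_table = anchor_raw_to_t_table(
            item_set.anchor, item_set.anchor_params, reference, grid
        )
        cw = equipercentile_link(
            filt.included[f"{item_set.target.name}_raw"].to_numpy(),
            filt.included[f"{item_set.anchor.name}_raw"].to_numpy(),
            t_table,
            target_scale=item_set.target,
            anchor_scale=item_set.anchor,
            presmooth_degree=presmooth_degree,
        )
        return cw, reference
    raise SchemaError(f"unknown linking method {method!r}")


def _actual_anchor_t(
    matrix: pd.DataFrame, item_set: ItemSet, density: LatentDensity, grid: QuadratureGrid
) -> np.ndarray:
    """Pattern-level EAP t-scores from anchor responses under fixed params."""
    X = item_set.anchor.to_indices(matrix)
    plist = params_for_scale(item_set.anchor_params, item_set.anchor)
    theta, _ = eap_theta_many(X, plist, density, grid)
    return 50.0 + 10.0 * theta


def _stratified_folds(
    raw: np.ndarray, k: int, rng: np.random.Generator, n_strata: int = 5
) -> np.ndarray:
    """Fold labels stratified on raw-score quantile bins."""
    order = pd.Series(raw).rank(method="first").to_numpy()
    strata = np.minimum((order - 1) * n_strata // len(raw), n_strata - 1)
    fold = np.empty(len(raw), dtype=int)
    offset = 0
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        rng.shuffle(idx)
        fold[idx] = (np.arange(len(idx)) + offset) % k
        offset += len(idx)  # rotate so small strata spread across folds
    return fold


def kfold_cv(
    item_set: ItemSet,
    k: int = 5,
    method: str = "irt",
    seed: int = 0,
    grid: QuadratureGrid | None = None,
    *,
    stratify: bool = True,
) -> LinkingAccuracy:
    """K-fold cross-validated linking accuracy for one item set and method."""
    if k < 2:
        raise SchemaError("k must be >= 2")
    grid = grid or QuadratureGrid.default()
    filt = filter_missingness(item_set.matrix, [item_set.target, item_set.anchor])
    data = item_set.matrix.loc[filt.mask].reset_index(drop=True)
    target_raw = filt.included[f"{item_set.target.name}_raw"].to_numpy()
    n = len(data)
    if k > n:
        raise SchemaError(f"k = {k} exceeds the {n} retained respondents")
    rng = np.random.default_rng(seed)
    if stratify and k <= n // 2:
        fold = _stratified_folds(target_raw, k, rng)
    else:
        fold = rng.permutation(n) % k

    preds, actuals = [], []
    warnings: list[str] = []
    n_used = 0
    for f in range(k):
        test = fold == f
        train = ~test
        if not test.any():
            continue
        try:
            cw, density = build_crosswalk(
                item_set.with_matrix(data.loc[train].reset_index(drop=True)),
                method,
                grid,
            )
        except LinkingUndefinedError as exc:
            warnings.append(f"fold {f} flagged: {exc}")
            continue
        test_frame = data.loc[test].reset_index(drop=True)
        raw_test = target_raw[test]
        preds.append(cw.lookup(raw_test)["t"].to_numpy())
        actuals.append(_actual_anchor_t(test_frame, item_set, density, grid))
        n_used += 1
    if not preds:
        raise LinkingUndefinedError("no usable folds")
    if n_used < k:
        warnings.append(f"metrics computed on {n_used}/{k} folds")
    pred = np.concatenate(preds)
    act = np.concatenate(actuals)
    diff = pred - act
    return LinkingAccuracy(
        item_set=item_set.name,
        method=method,
        r=float(np.corrcoef(pred, act)[0, 1]),
        mean_diff=float(diff.mean()),
        sd_diff=float(diff.std(ddof=1)),
        n=int(len(diff)),
        n_folds_used=n_used,
        warnings=warnings,
    )


def select_method(accuracies: Iterable[LinkingAccuracy]) -> MethodSelection:
    """Pick the method dominating on r, |mean diff| and SD across item sets.

    Order of the input is irrelevant.  With a single method the result is
    flagged ``uncontested``; without a dominator it is ``indeterminate``
    and the ranked report carries the per-method metrics.
    """
    accs = list(accuracies)
    if not accs:
        raise SchemaError("no accuracy records supplied")
    rows = [
        {"item_set": a.item_set, "method": a.method, "r": a.r,
         "mean_diff": a.mean_diff, "sd_diff": a.sd_diff, "n": a.n}
        for a in accs
    ]
    report = pd.DataFrame(rows).sort_values(["item_set", "method"]).reset_index(drop=True)
    methods = sorted(report["method"].unique())
    if len(methods) == 1:
        return MethodSelection("uncontested", methods[0], report)

    def dominates(a: str, b: str) -> bool:
        for iset in report["item_set"].unique():
            ra = report[(report.item_set == iset) & (report.method == a)]
            rb = report[(report.item_set == iset) & (report.method == b)]
            if ra.empty or rb.empty:
                return False
            if not (
                ra.r.iloc[0] >= rb.r.iloc[0]
                and abs(ra.mean_diff.iloc[0]) <= abs(rb.mean_diff.iloc[0])
                and ra.sd_diff.iloc[0] <= rb.sd_diff.iloc[0]
            ):
                return False
        return True

    for m in methods:
        if all(dominates(m, other) for other in methods if other != m):
            return MethodSelection("winner", m, report)
    return MethodSelection("indeterminate", None, report)


def assumption_check(
    item_set: ItemSet,
    r_threshold: float = 0.75,
    ratio_threshold: float = 3.0,
) -> AssumptionReport:
    """Quantitative linking-assumption screen for one item set.

    Inter-scale Pearson r between (prorated) raw totals, and an
    essential-unidimensionality screen on the pooled target+anchor items:
    the ratio of the first to second eigenvalue of their polychoric
    correlation matrix (pass at >= 3 by default).
    """
    filt = filter_missingness(item_set.matrix, [item_set.target, item_set.anchor])
    tr = filt.included[f"{item_set.target.name}_raw"]
    ar = filt.included[f"{item_set.anchor.name}_raw"]
    inter_r = float(tr.corr(ar))

    items = list(item_set.target.item_ids) + list(item_set.anchor.item_ids)
    pooled = item_set.matrix.loc[filt.mask, items].apply(pd.to_numeric)
    R, warnings = polychoric_matrix(pooled)
    eig = np.sort(np.linalg.eigvalsh(R.to_numpy()))[::-1]
    ratio = float(eig[0] / eig[1]) if len(eig) > 1 and eig[1] > 0 else np.inf
    return AssumptionReport(
        item_set=item_set.name,
        inter_scale_r=inter_r,
        eigenvalues=eig,
        eigen_ratio=ratio,
        prop_first=float(eig[0] / eig.sum()),
        passes_correlation=inter_r >= r_threshold,
        passes_unidimensionality=ratio >= ratio_threshold,
        r_threshold=r_threshold,
        ratio_threshold=ratio_threshold,
        warnings=warnings,
    )


def reliability_curve(
    params_list: Sequence[ItemParams],
    t_grid: np.ndarray | None = None,
    scale_name: str = "",
) -> ReliabilityCurve:
    """Conditional reliability 1 - 1/I(theta) across the anchor t-metric."""
    if t_grid is None:
        t_grid = np.arange(20.0, 80.0 + 1e-9, 0.5)
    theta = (np.asarray(t_grid, dtype=float) - 50.0) / 10.0
    info = test_information(params_list, theta)
    with np.errstate(divide="ignore"):
        rel = 1.0 - 1.0 / info
    return ReliabilityCurve(scale_name, np.asarray(t_grid, float), np.clip(rel, 0.0, 1.0))


def reliable_range(
    curve: ReliabilityCurve, threshold: float
) -> list[tuple[float, float]]:
    """Maximal closed t-intervals (on the grid) with reliability >= threshold."""
    if not (0 < threshold < 1):
        raise SchemaError("threshold must lie in (0, 1)")
    ok = curve.reliability >= threshold
    intervals: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(ok):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            intervals.append((float(curve.t[start]), float(curve.t[i - 1])))
            start = None
    if start is not None:
        intervals.append((float(curve.t[start]), float(curve.t[-1])))
    return intervals


def subgroup_invariance(
    item_set: ItemSet,
    subgroup_col: str = "subgroup",
    method: str = "irt",
    grid: QuadratureGrid | None = None,
    *,
    min_group_n: int = 100,
    margin: float = 3.0,
) -> InvarianceReport:
    """Re-link within each subgroup and compare crosswalk t columns.

    Flags the item set when the maximum absolute row-wise t difference
    exceeds ``margin`` (default 3 t-units, a documented convention).
    """
    if subgroup_col not in item_set.matrix.columns:
        raise SchemaError(f"matrix has no column {subgroup_col!r}")
    labels = item_set.matrix[subgroup_col]
    groups = sorted(labels.dropna().unique())
    if len(groups) != 2:
        raise SchemaError(f"expected 2 subgroups, found {len(groups)}")
    sizes = {g: int((labels == g).sum()) for g in groups}
    small = {g: s for g, s in sizes.items() if s < min_group_n}
    if small:
        raise SchemaError(
            f"subgroup(s) below the {min_group_n}-respondent floor: {small}"
        )
    crosswalks: dict[object, Crosswalk] = {}
    for g in groups:
        sub = item_set.matrix.loc[labels == g].reset_index(drop=True)
        crosswalks[g], _ = build_crosswalk(item_set.with_matrix(sub), method, grid)
    a, b = groups
    merged = crosswalks[a].table.merge(
        crosswalks[b].table, on="raw", suffixes=(f"_{a}", f"_{b}")
    )
    merged["abs_delta_t"] = np.abs(merged[f"t_{a}"] - merged[f"t_{b}"])
    max_d = float(merged["abs_delta_t"].max())
    return InvarianceReport(
        item_set=item_set.name,
        method=method,
        crosswalks=crosswalks,
        delta_t=merged[["raw", f"t_{a}", f"t_{b}", "abs_delta_t"]],
        max_abs_delta=max_d,
        mean_abs_delta=float(merged["abs_delta_t"].mean()),
        flagged=max_d > margin,
        margin=margin,
    )
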
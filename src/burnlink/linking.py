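"""Crosswalk construction and use.

Two routes place a target scale's raw scores on the anchor metric:

* **IRT fixed-calibration linking** — target items are calibrated with the
  anchor items held at their published parameters (freeing the latent
  mean/SD), the target's summed-score EAP table converts each raw score to
  a t-score ``t = 50 + 10 * E[theta | raw]``, and the anchor's test
  characteristic curve converts that trait level to an expected anchor raw
  score.
* **Equipercentile linking** — target and anchor raw-score distributions
  from the same respondents are continuized with mid-point percentile
  ranks (Kolen-Brennan), each target raw score is mapped to the anchor raw
  score with the same percentile rank, and t-scores come from linear
  interpolation in the anchor's raw-to-t table.

A crosswalk translates into closest cut-point equivalencies and group-level
rates.  Published cut-points are raw-score rules (with a companion t-score
on the anchor metric), so cut-point matching defaults to distance on the
predicted anchor raw-score column, which is the rule that reproduces the
published equivalencies across all item sets; matching on the t column is
available via ``metric="t"``.

Per-respondent translated t-scores are produced only as intermediates for
group-level summaries (means, rates); they are not individual-level score
conversions.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationResult, calibrate
from .errors import (
    IncompatibleCrosswalkError,
    LinkingUndefinedError,
    SchemaError,
)
from .irt import (
    ItemParams,
    LatentDensity,
    QuadratureGrid,
    params_for_scale,
    summed_score_eap,
    tcc,
)
from .scales import ScaleDef


@dataclass
class ItemSet:
    """A target scale paired with its anchor scale on a shared sample."""

    name: str
    target: ScaleDef
    anchor: ScaleDef
    anchor_params: dict[str, ItemParams]
    matrix: pd.DataFrame

    def __post_init__(self):
        if self.target.name != self.anchor.name:
            overlap = set(self.target.item_ids) & set(self.anchor.item_ids)
            if overlap:
                raise SchemaError(
                    f"item set {self.name!r}: target and anchor share items {sorted(overlap)}"
                )
        missing = [i for i in self.anchor.item_ids if i not in self.anchor_params]
        if missing:
            raise SchemaError(f"item set {self.name!r}: no anchor parameters for {missing}")

    @property
    def is_self_link(self) -> bool:
        return self.target.name == self.anchor.name

    def with_matrix(self, matrix: pd.DataFrame) -> "ItemSet":
        return ItemSet(self.name, self.target, self.anchor, self.anchor_params, matrix)


@dataclass
class Crosswalk:
    """Raw-score lookup table from a target scale onto an anchor metric.

    ``table`` columns: ``raw`` (target raw total), ``t`` (predicted anchor
    t-score), ``se_t`` (its standard error; NaN for equipercentile rows),
    ``anchor_expected_raw`` (predicted anchor raw total).
    """

    table: pd.DataFrame
    method: str
    target: str
    anchor: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        required = {"raw", "t", "se_t", "anchor_expected_raw"}
        if not required.issubset(self.table.columns):
            raise SchemaError(f"crosswalk table needs columns {sorted(required)}")
        t = self.table["t"].to_numpy()
        r = self.table["anchor_expected_raw"].to_numpy()
        if np.any(np.diff(t) < -1e-9):
            raise SchemaError("crosswalk t column must be non-decreasing in raw score")
        if np.any(np.diff(r) < -1e-9):
            raise SchemaError("crosswalk anchor_expected_raw must be non-decreasing")
        self.table = self.table.reset_index(drop=True)

    @property
    def raw_scores(self) -> np.ndarray:
        return self.table["raw"].to_numpy()

    def lookup(self, raw_scores) -> pd.DataFrame:
        """Rows for the given raw scores; errors on values outside the table."""
        raw = np.asarray(raw_scores)
        known = set(self.table["raw"].tolist())
        bad = sorted({v for v in raw.tolist() if v not in known})
        if bad:
            raise SchemaError(
                f"raw scores {bad} have no row in the {self.target}->{self.anchor} crosswalk"
            )
        indexed = self.table.set_index("raw")
        return indexed.loc[raw].reset_index()

    def t_at(self, raw_score) -> float:
        return float(self.lookup([raw_score])["t"].iloc[0])


@dataclass(frozen=True)
class CutpointEquivalence:
    """Closest target raw cut for an anchor cut-point."""

    anchor: str
    target: str
    anchor_cut_raw: float | None
    anchor_cut_t: float | None
    target_raw_cut: int
    target_cut_t: float
    delta: float           # |distance| on the matching metric at the match
    metric: str            # 'anchor_raw' or 't'


# ---------------------------------------------------------------------------
# IRT linking


def irt_link(
    item_set: ItemSet,
    grid: QuadratureGrid | None = None,
    *,
    calibration: CalibrationResult | None = None,
    scoring_density: LatentDensity | None = None,
    **cal_options,
) -> Crosswalk:
    """Fixed-calibration IRT crosswalk for one item set.

    Calibration frees the latent mean/SD so target parameters land on the
    anchor metric, but the summed-score EAP table is computed under the
    anchor *reference* density (standard normal on the anchor metric, where
    t = 50 + 10 theta) so the crosswalk is a property of the item
    parameters alone, portable across populations.  Pass
    ``scoring_density`` to score under a different prior.

    A pre-computed ``calibration`` (covering target and anchor items) may be
    supplied to skip re-estimation.
    """
    grid = grid or QuadratureGrid.default()
    scoring_density = scoring_density or LatentDensity(0.0, 1.0)
    anchor_plist = params_for_scale(item_set.anchor_params, item_set.anchor)
    if calibration is None:
        scales = [item_set.target] if item_set.is_self_link else [
            item_set.target, item_set.anchor
        ]
        calibration = calibrate(
            item_set.matrix, scales, fixed=item_set.anchor_params, grid=grid,
            **cal_options,
        )
    target_plist = [calibration.params[i] for i in item_set.target.item_ids]
    if any(i in calibration.collapse_maps for i in item_set.target.item_ids):
        _warnings.warn(
            f"item set {item_set.name!r}: collapsed categories; crosswalk covers "
            "the collapsed raw range"
        )
    sse = summed_score_eap(
        target_plist, scoring_density, grid, item_set.target.lowest_code
    )
    theta = sse["theta"].to_numpy()
    table = pd.DataFrame(
        {
            "raw": sse["raw"].to_numpy(),
            "t": 50.0 + 10.0 * theta,
            "se_t": 10.0 * sse["se"].to_numpy(),
            "anchor_expected_raw": tcc(anchor_plist, theta, item_set.anchor.lowest_code),
        }
    )
    meta = {
        "method": "irt",
        "anchor_metric": item_set.anchor.name,
        "latent_mean": calibration.density.mean,
        "latent_sd": calibration.density.sd,
        "scoring_prior_mean": scoring_density.mean,
        "scoring_prior_sd": scoring_density.sd,
        "converged": calibration.converged,
        "n": int(len(item_set.matrix)),
    }
    if not calibration.converged:
        meta["flagged"] = "calibration did not converge"
        _warnings.warn(f"item set {item_set.name!r}: calibration did not converge")
    return Crosswalk(table, "irt", item_set.target.name, item_set.anchor.name, meta)


def anchor_raw_to_t_table(
    anchor: ScaleDef,
    anchor_params: Mapping[str, ItemParams],
    density: LatentDensity | None = None,
    grid: QuadratureGrid | None = None,
) -> pd.DataFrame:
    """The anchor's own raw -> t table (summed-score EAP on anchor items)."""
    grid = grid or QuadratureGrid.default()
    density = density or LatentDensity(0.0, 1.0)
    plist = params_for_scale(anchor_params, anchor)
    sse = summed_score_eap(plist, density, grid, anchor.lowest_code)
    return pd.DataFrame(
        {
            "raw": sse["raw"].to_numpy(),
            "t": 50.0 + 10.0 * sse["theta"].to_numpy(),
            "se_t": 10.0 * sse["se"].to_numpy(),
        }
    )


# ---------------------------------------------------------------------------
# equipercentile linking


def _freqs(scores: np.ndarray, support: np.ndarray) -> np.ndarray:
    counts = np.zeros(len(support))
    lookup = {int(s): i for i, s in enumerate(support)}
    for v in scores:
        if int(v) not in lookup:
            raise SchemaError(f"raw score {v} outside support [{support[0]}, {support[-1]}]")
        counts[lookup[int(v)]] += 1
    return counts


def loglinear_presmooth(counts: np.ndarray, support: np.ndarray, degree: int) -> np.ndarray:
    """Log-linear (polynomial Poisson) presmoothing of a score frequency table."""
    import statsmodels.api as sm

    x = (support - support.mean()) / max(support.std(), 1.0)
    design = np.column_stack([x**d for d in range(degree + 1)])
    model = sm.GLM(counts, design, family=sm.families.Poisson())
    fitted = model.fit().mu
    return fitted * counts.sum() / fitted.sum()


def _percentile_ranks(counts: np.ndarray) -> np.ndarray:
    """Mid-point percentile ranks (0-100) at each support value."""
    n = counts.sum()
    rel = counts / n
    below = np.concatenate([[0.0], np.cumsum(rel)[:-1]])
    return 100.0 * (below + 0.5 * rel)


def _inv_continuized_cdf(p: float, support: np.ndarray, cdf: np.ndarray) -> float:
    """Inverse of the piecewise-linear continuized CDF.

    Flat segments (zero-frequency scores) invert to the midpoint of the
    flat span.
    """
    xs = np.concatenate([[support[0] - 0.5], support + 0.5])
    gs = np.concatenate([[0.0], cdf])
    if p <= 0:
        return float(xs[0])
    if p >= 1:
        return float(xs[-1])
    i = int(np.searchsorted(gs, p, side="left"))
    if gs[i] > p:
        frac = (p - gs[i - 1]) / (gs[i] - gs[i - 1])
        return float(xs[i - 1] + frac * (xs[i] - xs[i - 1]))
    j = i
    while j + 1 < len(gs) and gs[j + 1] == p:
        j += 1
    return float((xs[i] + xs[j]) / 2.0)


def equipercentile_link(
    target_raw: np.ndarray,
    anchor_raw: np.ndarray,
    anchor_t_table: pd.DataFrame,
    target_scale: ScaleDef | None = None,
    anchor_scale: ScaleDef | None = None,
    *,
    presmooth_degree: int | None = None,
    target_name: str = "target",
    anchor_name: str = "anchor",
) -> Crosswalk:
    """Equipercentile crosswalk from paired raw-score vectors.

    ``anchor_t_table`` must contain columns ``raw`` and ``t`` (the anchor's
    raw -> t conversion); t-scores for non-integer equated anchor scores are
    linearly interpolated.
    """
    target_raw = np.asarray(target_raw, dtype=float)
    anchor_raw = np.asarray(anchor_raw, dtype=float)
    if len(target_raw) != len(anchor_raw) or len(target_raw) == 0:
        raise LinkingUndefinedError("need paired, non-empty raw-score vectors")
    if np.ptp(target_raw) == 0 or np.ptp(anchor_raw) == 0:
        raise LinkingUndefinedError("degenerate (constant) score distribution")

    if target_scale is not None:
        x_support = target_scale.raw_scores
        target_name = target_scale.name
    else:
        x_support = np.arange(int(target_raw.min()), int(target_raw.max()) + 1)
    if anchor_scale is not None:
        y_support = anchor_scale.raw_scores
        anchor_name = anchor_scale.name
    else:
        y_support = np.arange(int(anchor_raw.min()), int(anchor_raw.max()) + 1)

    x_counts = _freqs(target_raw, x_support)
    y_counts = _freqs(anchor_raw, y_support)
    if presmooth_degree is not None:
        x_counts = loglinear_presmooth(x_counts, x_support, presmooth_degree)
        y_counts = loglinear_presmooth(y_counts, y_support, presmooth_degree)

    pr_x = _percentile_ranks(x_counts)
    y_cdf = np.cumsum(y_counts) / y_counts.sum()
    e_y = np.array(
        [_inv_continuized_cdf(p / 100.0, y_support, y_cdf) for p in pr_x]
    )
    e_y = np.maximum.accumulate(e_y)  # guard against float-level inversions

    tab = anchor_t_table.sort_values("raw")
    t = np.interp(e_y, tab["raw"].to_numpy(), tab["t"].to_numpy())
    table = pd.DataFrame(
        {"raw": x_support, "t": t, "se_t": np.nan, "anchor_expected_raw": e_y}
    )
    meta = {
        "method": "equipercentile",
        "anchor_metric": anchor_name,
        "n": int(len(target_raw)),
        "presmooth_degree": presmooth_degree,
    }
    return Crosswalk(table, "equipercentile", target_name, anchor_name, meta)


# ---------------------------------------------------------------------------
# cut-points and rates


def closest_cutpoint(
    crosswalk: Crosswalk,
    anchor_cut_t: float | None = None,
    anchor_cut_raw: float | None = None,
    metric: str | None = None,
) -> CutpointEquivalence:
    """Target raw score whose predicted anchor score is closest to a cut.

    Published cut-points are raw-score rules, so when ``anchor_cut_raw`` is
    given the match minimizes distance on the predicted anchor raw-score
    column (``metric='anchor_raw'``); with only ``anchor_cut_t`` the match
    is on the t column.  Ties break toward the lower raw score.
    """
    if len(crosswalk.table) == 0:
        raise SchemaError("empty crosswalk")
    if anchor_cut_t is None and anchor_cut_raw is None:
        raise SchemaError("supply anchor_cut_t and/or anchor_cut_raw")
    if metric is None:
        metric = "anchor_raw" if anchor_cut_raw is not None else "t"
    if metric == "anchor_raw":
        dist = np.abs(crosswalk.table["anchor_expected_raw"].to_numpy() - anchor_cut_raw)
    elif metric == "t":
        dist = np.abs(crosswalk.table["t"].to_numpy() - anchor_cut_t)
    else:
        raise SchemaError(f"unknown matching metric {metric!r}")
    i = int(np.argmin(dist))  # argmin returns the first (lowest-raw) minimum
    row = crosswalk.table.iloc[i]
    return CutpointEquivalence(
        anchor=crosswalk.anchor,
        target=crosswalk.target,
        anchor_cut_raw=anchor_cut_raw,
        anchor_cut_t=anchor_cut_t,
        target_raw_cut=int(row["raw"]),
        target_cut_t=float(row["t"]),
        delta=float(dist[i]),
        metric=metric,
    )


def cross_target_cutpoint(
    crosswalk_a: Crosswalk,
    raw_cut_a: int,
    crosswalk_b: Crosswalk,
    metric: str = "anchor_raw",
) -> CutpointEquivalence:
    """Map a raw cut on target A to the closest raw cut on target B.

    Both crosswalks must share the same anchor metric; comparing tables
    built against different anchors raises
    :class:`IncompatibleCrosswalkError`.
    """
    if crosswalk_a.anchor != crosswalk_b.anchor:
        raise IncompatibleCrosswalkError(
            f"crosswalks are on different anchor metrics "
            f"({crosswalk_a.anchor!r} vs {crosswalk_b.anchor!r}) and cannot be compared"
        )
    row = crosswalk_a.lookup([raw_cut_a]).iloc[0]
    return closest_cutpoint(
        crosswalk_b,
        anchor_cut_t=float(row["t"]),
        anchor_cut_raw=float(row["anchor_expected_raw"]),
        metric=metric,
    )


@dataclass
class GroupSubstitution:
    """Group-level summary of crosswalk-substituted t-scores."""

    t_scores: np.ndarray
    proportion_at_or_above: float
    mean_t: float
    n: int


def apply_crosswalk(
    raw_scores,
    crosswalk: Crosswalk,
    anchor_cut_t: float,
) -> GroupSubstitution:
    """Substitute raw scores with crosswalk t-scores; summarize at group level.

    The per-respondent t-scores are intermediates for the group proportion
    and mean, not individual-level conversions.
    """
    raw = np.asarray(raw_scores)
    if raw.size == 0:
        raise SchemaError("empty input: no raw scores to translate")
    rows = crosswalk.lookup(raw)
    t = rows["t"].to_numpy()
    return GroupSubstitution(
        t_scores=t,
        proportion_at_or_above=float(np.mean(t >= anchor_cut_t)),
        mean_t=float(np.mean(t)),
        n=int(raw.size),
    )


def rates_from_frequency_table(
    freq: Mapping[int, float] | pd.DataFrame,
    crosswalk: Crosswalk,
    anchor_cut_t: float,
) -> float:
    """Proportion at or above an anchor cut from an aggregated raw-score table."""
    if isinstance(freq, pd.DataFrame):
        freq = dict(zip(freq["raw"], freq["count"]))
    raws = np.array(sorted(freq))
    counts = np.array([freq[r] for r in raws], dtype=float)
    if np.any(counts < 0):
        raise SchemaError("negative counts in frequency table")
    total = counts.sum()
    if total == 0:
        raise LinkingUndefinedError("zero total count: rate undefined")
    t = crosswalk.lookup(raws)["t"].to_numpy()
    return float(counts[t >= anchor_cut_t].sum() / total)


# ---------------------------------------------------------------------------
# inclusion rule


@dataclass
class MissingnessFilter:
    """Result of the <=1-missing-item inclusion rule."""

    included: pd.DataFrame       # passthrough columns + one raw-total column per scale
    mask: np.ndarray             # True for retained rows of the input matrix
    n_excluded: int


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def filter_missingness(
    matrix: pd.DataFrame,
    scales: Sequence[ScaleDef],
) -> MissingnessFilter:
    """Keep respondents with at most one missing item per scale, on every scale.

    Raw totals for a retained respondent missing one item are prorated:
    round-half-up of (mean over observed items x item count).  A scale with
    no observed items excludes the respondent regardless.
    """
    n = len(matrix)
    keep = np.ones(n, dtype=bool)
    totals = {}
    for sc in scales:
        idx = sc.to_indices(matrix).astype(float)
        idx[idx < 0] = np.nan
        codes = idx + sc.lowest_code
        n_missing = np.isnan(codes).sum(axis=1)
        n_obs = sc.n_items - n_missing
        keep &= (n_missing <= 1) & (n_obs >= 1)
        with np.errstate(invalid="ignore"):
            mean_obs = np.nansum(codes, axis=1) / np.where(n_obs > 0, n_obs, np.nan)
        totals[sc.name] = _round_half_up(mean_obs * sc.n_items)
    passthrough = [c for c in matrix.columns
                   if c not in {i for sc in scales for i in sc.item_ids}]
    out = matrix.loc[keep, passthrough].copy()
    for name, tot in totals.items():
        out[f"{name}_raw"] = tot[keep].astype(int)
    return MissingnessFilter(
        included=out.reset_index(drop=True),
        mask=keep,
        n_excluded=int(n - keep.sum()),
    )
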
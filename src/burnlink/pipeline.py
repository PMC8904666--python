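"""End-to-end linking pipeline over configured item sets.

Stages: missingness filtering -> assumption checks -> crosswalks by each
configured method -> k-fold cross-validated accuracy -> method selection ->
full-sample crosswalks from the selected method -> cut-point equivalencies
-> conditional reliability curves.  Every artifact is CSV or JSON, every
stochastic stage records its seed, and a structured run log (text plus a
JSON sidecar) collects timestamps and warnings.  A stage failure raises
:class:`~burnlink.errors.PipelineError` naming the stage; artifacts written
by earlier stages are preserved.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import PipelineError, SchemaError
from .evaluation import (
    assumption_check,
    build_crosswalk,
    kfold_cv,
    reliability_curve,
    select_method,
)
from .irt import ItemParams, QuadratureGrid, params_for_scale
from .linking import ItemSet, closest_cutpoint, filter_missingness
from .io import write_crosswalk, write_reliability_curves
from .scales import ScaleDef


@dataclass
class ItemSetConfig:
    name: str
    target: str
    anchor: str
    anchor_cut_raw: float | None = None
    anchor_cut_t: float | None = None


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    scales: dict[str, ScaleDef]
    anchor_params: dict[str, ItemParams]
    item_sets: list[ItemSetConfig]
    methods: tuple[str, ...] = ("irt", "equipercentile")
    k_folds: int = 5
    seed: int = 0
    out_dir: str | Path = "results/pipeline"
    quadrature_nodes: int = 61

    def __post_init__(self):
        if self.seed is None:
            raise SchemaError("a seed is mandatory for the cross-validation stage")
        for isc in self.item_sets:
            for name in (isc.target, isc.anchor):
                if name not in self.scales:
                    raise SchemaError(f"item set {isc.name!r} references "
                                      f"undefined scale {name!r}")

    @classmethod
    def from_yaml(cls, path, scales: dict[str, ScaleDef],
                  anchor_params: dict[str, ItemParams]) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        item_sets = [ItemSetConfig(**d) for d in raw.pop("item_sets")]
        return cls(scales=scales, anchor_params=anchor_params,
                   item_sets=item_sets, **raw)


@dataclass
class RunLog:
    records: list[dict] = field(default_factory=list)
    seeds: dict[str, int] = field(default_factory=dict)

    def add(self, stage: str, **info) -> None:
        self.records.append({"stage": stage, "time": time.time(), **info})

    def warn(self, stage: str, message: str) -> None:
        self.add(stage, warning=message)

    @property
    def warnings(self) -> list[str]:
        return [r["warning"] for r in self.records if "warning" in r]

    def write(self, out_dir: Path) -> None:
        (out_dir / "run_log.json").write_text(
            json.dumps({"records": self.records, "seeds": self.seeds},
                       indent=1, default=str)
        )
        lines = [
            f"[{time.strftime('%H:%M:%S', time.localtime(r['time']))}] "
            + r["stage"]
            + ("" if "warning" not in r else f" WARNING: {r['warning']}")
            for r in self.records
        ]
        (out_dir / "run_log.txt").write_text("\n".join(lines) + "\n")


@dataclass
class PipelineResult:
    selected_method: str | None
    selection_status: str
    crosswalks: dict[str, object]
    accuracies: list
    assumptions: list
    cutpoints: pd.DataFrame
    log: RunLog
    out_dir: Path


def run_pipeline(config: RunConfig, matrix: pd.DataFrame) -> PipelineResult:
    """Run the full linking pipeline on a wide response matrix."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = RunLog()
    log.seeds["cv"] = config.seed
    grid = QuadratureGrid.default(config.quadrature_nodes)

    item_sets = []
    for isc in config.item_sets:
        target, anchor = config.scales[isc.target], config.scales[isc.anchor]
        item_sets.append(
            ItemSet(
                isc.name, target, anchor,
                {i: config.anchor_params[i] for i in anchor.item_ids},
                matrix,
            )
        )

    def stage(name, fn, *args, **kwargs):
        log.add(name)
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            log.warn(name, str(exc))
            log.write(out_dir)
            raise PipelineError(name, str(exc)) from exc

    # 1. inclusion rule
    def _filter():
        out = {}
        for iset in item_sets:
            filt = filter_missingness(matrix, [iset.target, iset.anchor])
            out[iset.name] = filt
            log.add("filter", item_set=iset.name, retained=int(filt.mask.sum()),
                    excluded=filt.n_excluded)
        return out

    stage("filter", _filter)

    # 2. assumption checks
    def _assumptions():
        reports = []
        for iset in item_sets:
            rep = assumption_check(iset)
            reports.append(rep)
            for w in rep.warnings:
                log.warn("assumptions", w)
        (out_dir / "assumptions.json").write_text(json.dumps(
            [
                {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                 for k, v in dataclasses.asdict(r).items()}
                for r in reports
            ], indent=1,
        ))
        return reports

    assumptions = stage("assumptions", _assumptions)

    # 3. cross-validated accuracy per method (skipped with a single method)
    def _cv():
        accs = []
        for iset in item_sets:
            for method in config.methods:
                acc = kfold_cv(iset, k=config.k_folds, method=method,
                               seed=config.seed, grid=grid)
                accs.append(acc)
                for w in acc.warnings:
                    log.warn("cv", f"{iset.name}/{method}: {w}")
        return accs

    accuracies = stage("cv", _cv) if len(config.methods) > 1 else []

    # 4. method selection
    if accuracies:
        selection = stage("select_method", select_method, accuracies)
        selection.report.to_csv(out_dir / "cv_accuracy.csv", index=False)
        selected = selection.method or config.methods[0]
        status = selection.status
        if selection.status == "indeterminate":
            log.warn("select_method", "no dominating method; defaulting to "
                     f"{selected!r} for crosswalk construction")
    else:
        selected, status = config.methods[0], "uncontested"
        log.add("select_method", note=f"single method {selected!r} (uncontested)")

    # 5. full-sample crosswalks with the selected method
    def _crosswalks():
        out = {}
        for iset in item_sets:
            cw, _ = build_crosswalk(iset, selected, grid)
            out[iset.name] = cw
            write_crosswalk(cw, out_dir / f"crosswalk_{iset.name}.csv")
        return out

    crosswalks = stage("crosswalks", _crosswalks)

    # 6. cut-point equivalencies
    def _cutpoints():
        rows = []
        for isc, iset in zip(config.item_sets, item_sets):
            if isc.anchor_cut_raw is None and isc.anchor_cut_t is None:
                continue
            eq = closest_cutpoint(crosswalks[isc.name],
                                  anchor_cut_t=isc.anchor_cut_t,
                                  anchor_cut_raw=isc.anchor_cut_raw)
            rows.append(dataclasses.asdict(eq))
        frame = pd.DataFrame(rows)
        frame.to_csv(out_dir / "cutpoints.csv", index=False)
        return frame

    cutpoints = stage("cutpoints", _cutpoints)

    # 7. conditional reliability curves on each anchor metric
    def _reliability():
        curves = []
        for iset in item_sets:
            anchor_plist = params_for_scale(iset.anchor_params, iset.anchor)
            curves.append(reliability_curve(anchor_plist, scale_name=iset.anchor.name))
            if selected == "irt":
                cw = crosswalks[iset.name]
                # curves for target scales need their calibrated parameters;
                # rebuild from the linking calibration
                from .calibration import calibrate

                cal = calibrate(matrix, [iset.target, iset.anchor],
                                fixed=iset.anchor_params, grid=grid)
                target_plist = [cal.params[i] for i in iset.target.item_ids]
                curves.append(
                    reliability_curve(
                        target_plist,
                        scale_name=f"{iset.target.name} (on {iset.anchor.name})",
                    )
                )
        write_reliability_curves(curves, out_dir / "reliability_curves.csv")
        return curves

    stage("reliability", _reliability)

    log.add("done")
    log.write(out_dir)
    return PipelineResult(
        selected_method=selected,
        selection_status=status,
        crosswalks=crosswalks,
        accuracies=accuracies,
        assumptions=assumptions,
        cutpoints=cutpoints,
        log=log,
        out_dir=out_dir,
    )
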
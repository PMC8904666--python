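"""File formats: response matrices, item parameters, crosswalks, packaged data.

Responses travel as CSV with a header row of item ids (plus optional
``respondent_id`` / ``subgroup`` columns); an empty cell is a missing
response.  Item parameters are JSON (a list of ``{"item", "a", "b": [...]}``
records) or CSV.  Crosswalks are CSV with ``# key: value`` metadata comment
lines followed by ``raw,t,se_t,anchor_expected_raw`` columns; monotonicity
of the t column is validated on read.

The package ships the published burnout crosswalk tables (PFI-WE and MZSIB
onto the MBI-EE metric, PFI-ID onto the MBI-DP metric) and the published
anchor cut-points as reference data for worked examples.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError
from .irt import ItemParams
from .linking import Crosswalk
from .scales import ScaleDef

_REFERENCE_CROSSWALKS = {
    "pfi_we_to_mbi_ee": "crosswalk_pfi_we_to_mbi_ee.csv",
    "pfi_id_to_mbi_dp": "crosswalk_pfi_id_to_mbi_dp.csv",
    "mzsib_to_mbi_ee": "crosswalk_mzsib_to_mbi_ee.csv",
}


# ---------------------------------------------------------------------------
# response matrices


def write_responses(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, index=False)


def read_responses(path, scales: Sequence[ScaleDef]) -> pd.DataFrame:
    """Read and validate a wide response CSV against the scale definitions.

    Unknown columns other than ``respondent_id`` and ``subgroup`` raise a
    schema error; codes are validated cell-by-cell (the error names the
    offending row and item).
    """
    frame = pd.read_csv(path, skip_blank_lines=False)
    known = {i for sc in scales for i in sc.item_ids} | {"respondent_id", "subgroup"}
    unknown = [c for c in frame.columns if c not in known]
    if unknown:
        raise SchemaError(f"unknown item columns {unknown}")
    for sc in scales:
        sc.to_indices(frame)  # validation only; raises with cell coordinates
    return frame


# ---------------------------------------------------------------------------
# item parameters


def write_item_params(params: Mapping[str, ItemParams], path) -> None:
    path = Path(path)
    records = [
        {"item": p.item, "a": p.a, "b": list(p.b)} for p in params.values()
    ]
    if path.suffix == ".json":
        path.write_text(json.dumps(records, indent=1) + "\n")
    else:
        rows = [
            {"item": r["item"], "a": r["a"],
             **{f"b{k + 1}": v for k, v in enumerate(r["b"])}}
            for r in records
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def read_item_params(path) -> dict[str, ItemParams]:
    path = Path(path)
    if path.suffix == ".json":
        records = json.loads(path.read_text())
        return {r["item"]: ItemParams(r["item"], r["a"], tuple(r["b"])) for r in records}
    frame = pd.read_csv(path)
    out = {}
    bcols = sorted((c for c in frame.columns if c.startswith("b")),
                   key=lambda c: int(c[1:]))
    for _, row in frame.iterrows():
        b = [row[c] for c in bcols if pd.notna(row[c])]
        out[row["item"]] = ItemParams(row["item"], row["a"], tuple(b))
    return out


# ---------------------------------------------------------------------------
# crosswalks


def write_crosswalk(crosswalk: Crosswalk, path) -> None:
    path = Path(path)
    lines = [f"# method: {crosswalk.method}",
             f"# anchor_metric: {crosswalk.anchor}",
             f"# target: {crosswalk.target}"]
    for key, value in crosswalk.metadata.items():
        if key in ("method", "anchor_metric", "target"):
            continue
        lines.append(f"# {key}: {value}")
    body = crosswalk.table.to_csv(index=False)
    path.write_text("\n".join(lines) + "\n" + body)


def read_crosswalk(path) -> Crosswalk:
    """Read a crosswalk CSV; validates t-column monotonicity on read."""
    path = Path(path)
    meta: dict[str, str] = {}
    lines = path.read_text().splitlines()
    n_meta = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n_meta += 1
        key, _, value = line.lstrip("# ").partition(":")
        meta[key.strip()] = value.strip()
    table = pd.read_csv(path, skiprows=n_meta)
    return Crosswalk(
        table=table,
        method=meta.get("method", "unknown"),
        target=meta.get("target", "target"),
        anchor=meta.get("anchor_metric", "anchor"),
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# packaged reference data


def load_reference_crosswalk(name: str) -> Crosswalk:
    """One of the published crosswalks: ``pfi_we_to_mbi_ee``,
    ``pfi_id_to_mbi_dp`` or ``mzsib_to_mbi_ee``."""
    if name not in _REFERENCE_CROSSWALKS:
        raise SchemaError(
            f"unknown reference crosswalk {name!r}; "
            f"available: {sorted(_REFERENCE_CROSSWALKS)}"
        )
    ref = resources.files("burnlink.data") / _REFERENCE_CROSSWALKS[name]
    with resources.as_file(ref) as p:
        return read_crosswalk(p)


def load_anchor_cutpoints() -> dict[str, dict[str, float | None]]:
    """Published raw-score cut-points (with anchor t-scores where defined)."""
    ref = resources.files("burnlink.data") / "anchor_cutpoints.json"
    return json.loads(ref.read_text())


# ---------------------------------------------------------------------------
# reliability curves and frequency tables


def write_reliability_curves(curves, path) -> None:
    frames = [
        pd.DataFrame({"t": c.t, "scale": c.scale, "reliability": c.reliability})
        for c in curves
    ]
    pd.concat(frames).to_csv(path, index=False)


def read_frequency_table(path) -> dict[int, float]:
    frame = pd.read_csv(path)
    if not {"raw", "count"}.issubset(frame.columns):
        raise SchemaError("frequency table needs 'raw' and 'count' columns")
    return dict(zip(frame["raw"].astype(int), frame["count"].astype(float)))
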
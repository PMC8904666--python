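"""Scale definitions for ordinal summed-score instruments.

A :class:`ScaleDef` names the items of one subscale, the number of response
categories per item and the lowest integer code, from which the achievable
raw (total) score range follows.  The five built-in definitions mirror the
common burnout instruments this package links: the Maslach Burnout Inventory
Emotional Exhaustion (9 items, codes 0-6) and Depersonalization (5 items,
codes 0-6) anchor subscales, the Professional Fulfillment Index Work
Exhaustion (4 items, codes 0-4) and Interpersonal Disengagement (6 items,
codes 0-4) target subscales, and the single-item Mini-Z burnout screen
(codes 1-5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError

MISSING = -1  # internal 0-based category index for a missing response


@dataclass(frozen=True)
class ScaleDef:
    """Definition of one summed-score scale.

    Parameters
    ----------
    name : str
        Scale identifier (e.g. ``"MBI-EE"``).
    item_ids : sequence of str
        Ordered item column names.
    n_categories : int or sequence of int
        Number of ordered response categories, per item.
    lowest_code : int
        Integer code of the lowest category (0 for MBI/PFI-style items,
        1 for the Mini-Z single item).
    role : str
        ``"anchor"`` or ``"target"``.
    """

    name: str
    item_ids: tuple[str, ...]
    n_categories: tuple[int, ...]
    lowest_code: int = 0
    role: str = "target"

    def __init__(self, name, item_ids, n_categories, lowest_code=0, role="target"):
        item_ids = tuple(item_ids)
        if np.isscalar(n_categories):
            n_categories = tuple([int(n_categories)] * len(item_ids))
        else:
            n_categories = tuple(int(m) for m in n_categories)
        if len(item_ids) == 0:
            raise SchemaError(f"scale {name!r} has no items")
        if len(n_categories) != len(item_ids):
            raise SchemaError(f"scale {name!r}: one category count per item required")
        if any(m < 2 for m in n_categories):
            raise SchemaError(f"scale {name!r}: every item needs >= 2 categories")
        if role not in ("anchor", "target"):
            raise SchemaError(f"scale {name!r}: role must be 'anchor' or 'target'")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "item_ids", item_ids)
        object.__setattr__(self, "n_categories", n_categories)
        object.__setattr__(self, "lowest_code", int(lowest_code))
        object.__setattr__(self, "role", role)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @property
    def min_raw(self) -> int:
        return self.n_items * self.lowest_code

    @property
    def max_raw(self) -> int:
        return sum(m - 1 for m in self.n_categories) + self.n_items * self.lowest_code

    @property
    def raw_scores(self) -> np.ndarray:
        """All achievable raw total scores (contiguous integers)."""
        return np.arange(self.min_raw, self.max_raw + 1)

    def code_range(self, item_id: str) -> tuple[int, int]:
        j = self.item_ids.index(item_id)
        return self.lowest_code, self.lowest_code + self.n_categories[j] - 1

    def to_indices(self, frame: pd.DataFrame) -> np.ndarray:
        """Convert item columns to 0-based category indices (-1 = missing).

        Raises :class:`SchemaError` naming the offending cell for codes
        outside the item's range or non-integer values.
        """
        missing_cols = [c for c in self.item_ids if c not in frame.columns]
        if missing_cols:
            raise SchemaError(f"scale {self.name!r}: missing item columns {missing_cols}")
        out = np.full((len(frame), self.n_items), MISSING, dtype=np.int64)
        for j, item in enumerate(self.item_ids):
            col = pd.to_numeric(frame[item], errors="coerce")
            raw = frame[item]
            bad_parse = col.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
            if bad_parse.any():
                i = int(np.flatnonzero(bad_parse.to_numpy())[0])
                raise SchemaError(
                    f"non-numeric code {raw.iloc[i]!r} at row {i}, item {item!r}"
                )
            vals = col.to_numpy(dtype=float)
            obs = ~np.isnan(vals)
            if np.any(vals[obs] != np.round(vals[obs])):
                i = int(np.flatnonzero(obs & (vals != np.round(vals)))[0])
                raise SchemaError(f"non-integer code {vals[i]} at row {i}, item {item!r}")
            lo, hi = self.lowest_code, self.lowest_code + self.n_categories[j] - 1
            bad = obs & ((vals < lo) | (vals > hi))
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise SchemaError(
                    f"code {int(vals[i])} out of range [{lo}, {hi}] "
                    f"at row {i}, item {item!r}"
                )
            out[obs, j] = vals[obs].astype(np.int64) - self.lowest_code
        return out


def mbi_ee() -> ScaleDef:
    return ScaleDef("MBI-EE", [f"mbi_ee_{i}" for i in range(1, 10)], 7, 0, "anchor")


def mbi_dp() -> ScaleDef:
    return ScaleDef("MBI-DP", [f"mbi_dp_{i}" for i in range(1, 6)], 7, 0, "anchor")


def pfi_we() -> ScaleDef:
    return ScaleDef("PFI-WE", [f"pfi_we_{i}" for i in range(1, 5)], 5, 0, "target")


def pfi_id() -> ScaleDef:
    return ScaleDef("PFI-ID", [f"pfi_id_{i}" for i in range(1, 7)], 5, 0, "target")


def mzsib() -> ScaleDef:
    return ScaleDef("MZSIB", ["mzsib_1"], 5, 1, "target")


def study_scales() -> dict[str, ScaleDef]:
    """The five scales of the physician-burnout linking design."""
    defs = [mbi_ee(), mbi_dp(), pfi_we(), pfi_id(), mzsib()]
    return {s.name: s for s in defs}
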